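"""File I/O: images, tabular data, recipe files and run configuration.

Formats handled: grayscale TIFF (8/16-bit) and PNG images with a
mandatory pixel size; strict-header CSV tables (``r_nm,intensity`` for
profiles, ``lag_s,g2`` for correlograms, ``zeta_mV`` for replicates,
``w_water,w_methanol,w_chloroform`` for binodal assets); YAML/JSON
recipe files; YAML/JSON run configuration with unknown keys rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .formulation import Reagent, ReagentRole, RecipeLine

__all__ = [
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
    "read_recipe",
    "RunConfig",
]

TABLE_SCHEMAS = {
    "profile": ["r_nm", "intensity"],
    "correlogram": ["lag_s", "g2"],
    "zeta": ["zeta_mV"],
    "binodal": ["w_water", "w_methanol", "w_chloroform"],
}


def read_image(path, pixel_size_nm: float) -> tuple[np.ndarray, dict]:
    """Read a grayscale 8/16-bit TIFF or PNG with its pixel size.

    Color images and unsupported bit depths raise; the pixel size is
    mandatory and recorded in the returned metadata.
    """
    if pixel_size_nm is None or not pixel_size_nm > 0:
        raise ValueError("pixel_size_nm is mandatory and must be > 0")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel grayscale image, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported bit depth {arr.dtype}; expected 8- or 16-bit")
    meta = {
        "path": str(path),
        "pixel_size_nm": pixel_size_nm,
        "shape": arr.shape,
        "dtype": str(arr.dtype),
    }
    return arr.astype(float), meta


def write_image(path, image: np.ndarray) -> None:
    """Write an 8/16-bit grayscale image as TIFF or PNG by extension."""
    path = Path(path)
    if image.dtype not in (np.uint8, np.uint16):
        raise ValueError("image must be uint8 or uint16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    elif path.suffix.lower() == ".png":
        Image.fromarray(image).save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV with strict header validation against a named schema."""
    if schema not in TABLE_SCHEMAS:
        raise KeyError(f"unknown table schema {schema!r}; choose from {sorted(TABLE_SCHEMAS)}")
    expected = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"{path}: table contains no rows")
    return df


def write_table(path, df: pd.DataFrame, schema: str) -> None:
    """Write a CSV after validating the frame against a named schema."""
    expected = TABLE_SCHEMAS[schema]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    df.to_csv(path, index=False)


def read_recipe(path) -> dict:
    """Read a YAML/JSON recipe file into reagents, lines and protocol fields.

    Returns a dict with ``lines`` (list of :class:`RecipeLine`),
    ``reagents`` and the pass-through protocol fields used by
    :func:`lipoplex.formulation.recipe_report`.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict) or "reagents" not in raw or "lines" not in raw:
        raise ValueError(f"{path}: recipe must define 'reagents' and 'lines'")
    reagents: dict[str, Reagent] = {}
    for name, spec in raw["reagents"].items():
        reagents[name] = Reagent(
            name=name,
            molar_mass=float(spec["molar_mass"]),
            role=ReagentRole(spec["role"]),
            stock_concentration=spec.get("stock_concentration"),
        )
    lines = []
    for entry in raw["lines"]:
        reagent = reagents[entry["reagent"]]
        lines.append(
            RecipeLine(
                reagent=reagent,
                mass_ug=entry.get("mass_ug"),
                volume_uL=entry.get("volume_uL"),
            )
        )
    out = {"reagents": reagents, "lines": lines}
    for key in (
        "payload_monomer_umol",
        "counterion_umol",
        "payload_nmol",
        "final_volume_uL",
        "target_percent",
    ):
        if key in raw:
            out[key] = raw[key]
    return out


_CONFIG_KEYS = {
    "temperature_K",
    "component_permittivities",
    "binodal_path",
    "neutrality_band_mV",
    "class_thresholds",
    "fit_threshold",
    "instrument",
    "output_dir",
    "verbosity",
    "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        return cls(values=raw or {})

    def get(self, key, default=None):
        return self.values.get(key, default)
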
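"""Seeded synthetic-instrument generators with ground-truth records.

No raw micrographs, correlograms or electrophoretic traces are
distributed with the study this package models, so every instrument
input is emulated here: radially symmetric multilamellar TEM images
(Poisson + Gaussian detector noise), DLS intensity autocorrelation
traces, replicate zeta-potential series and the synthesis recipe file.
Each generator is a pure function of an explicit spec plus a mandatory
seed and returns a :class:`GroundTruthRecord` carrying the full
parameter set and a content hash, so re-running the same spec
reproduces the artifact bit for bit.

Named presets carry the study's printed characterization values
(lamellar fit parameters for particle types A1/A2/B; mean sizes and
polydispersity for the pellet, supernatant and clodronate fractions;
replicate zeta statistics).  Parameters the study does not print (e.g.
the A2 dilation magnitude, amplitudes, noise scales) are package
choices tagged ``synthetic_choice`` in the record.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dls import (
    CorrelogramTrace,
    SizeDistribution,
    diffusion_from_diameter,
    scattering_vector,
    simulate_g2,
)
from .physchem import SolventMedium, WATER
from .tem import LamellarModel, evaluate_model

__all__ = [
    "GroundTruthRecord",
    "SyntheticImageSpec",
    "make_lamellar_image",
    "make_noisy_profile",
    "make_dls_dataset",
    "make_zeta_replicates",
    "make_recipe_fixture",
    "lamellar_preset",
    "dls_preset",
    "zeta_preset",
    "poisson_scale_for_snr",
    "lognormal_size_distribution",
    "LAMELLAR_PRESETS",
    "DLS_PRESETS",
    "ZETA_PRESETS",
]


# ---------------------------------------------------------------------------
# ground truth bookkeeping

@dataclass(frozen=True)
class GroundTruthRecord:
    """What a generator actually did: name, parameters, seed, hash."""

    generator: str
    parameters: dict
    seed: int
    content_hash: str
    synthetic_choices: tuple[str, ...] = field(default=())


def _hash_array(arr: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(str(arr.dtype).encode())
    h.update(str(arr.shape).encode())
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def _hash_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


# ---------------------------------------------------------------------------
# lamellar TEM presets (printed fit parameters; gaps are synthetic choices)

_LAMELLAR_PRESET_TABLE = {
    # label: (S0, k 1/nm, D nm, delta 1/nm, alpha, B)
    "A1": (1.0, 0.0, 5.4, 0.0, 8.0, 0.1),
    "A2": (1.0, 0.05, 7.3, 0.1 / 7.3, 4.0, 0.1),
    "B": (1.0, 0.0, 5.2, 0.0, 1.0, 0.1),
}

_LAMELLAR_SYNTHETIC_CHOICES = {
    "A1": ("amplitude_S0", "baseline_B"),
    "A2": ("amplitude_S0", "baseline_B", "dilation_delta", "compaction_alpha"),
    "B": ("amplitude_S0", "baseline_B"),
}

LAMELLAR_PRESETS = tuple(_LAMELLAR_PRESET_TABLE)


def lamellar_preset(name: str) -> LamellarModel:
    """Lamellar model for particle type ``A1``, ``A2`` or ``B``."""
    if name not in _LAMELLAR_PRESET_TABLE:
        raise KeyError(f"unknown lamellar preset {name!r}; choose from {LAMELLAR_PRESETS}")
    return LamellarModel(*_LAMELLAR_PRESET_TABLE[name])


def lamellar_preset_synthetic_choices(name: str) -> tuple[str, ...]:
    return _LAMELLAR_SYNTHETIC_CHOICES[name]


def poisson_scale_for_snr(
    model: LamellarModel,
    snr: float,
    gaussian_sigma: float = 0.0,
    r_max_nm: float = 50.0,
) -> float:
    """Poisson count scale giving a target peak signal-to-noise ratio.

    SNR is defined as the peak clean model intensity over the total
    noise standard deviation at that peak, ``sqrt(peak/scale +
    gaussian_sigma**2)``.
    """
    if not snr > 0:
        raise ValueError("snr must be > 0")
    r = np.linspace(0.0, r_max_nm, 2048)
    peak = float(evaluate_model(model, r).max())
    var_needed = (peak / snr) ** 2 - gaussian_sigma**2
    if var_needed <= 0:
        raise ValueError("gaussian noise alone already exceeds the requested SNR")
    return peak / var_needed


# ---------------------------------------------------------------------------
# synthetic TEM image

@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for a radially symmetric multilamellar particle image."""

    size_px: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 0.5
    center_px: tuple[float, float] | None = None  # defaults to image centre
    outer_radius_nm: float = 55.0
    model: LamellarModel = None  # type: ignore[assignment]
    corona_start_radius_nm: float | None = None
    corona_model: LamellarModel | None = None
    poisson_scale: float = 0.0  # counts per intensity unit; 0 disables
    gaussian_sigma: float = 0.0  # a.u.
    seed: int = 0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.model is None:
            raise ValueError("an interior lamellar model is required")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        half_field_nm = min(self.size_px) / 2.0 * self.pixel_size_nm
        if self.outer_radius_nm > half_field_nm:
            raise ValueError(
                f"outer radius {self.outer_radius_nm} nm exceeds half the field "
                f"({half_field_nm} nm)"
            )
        if self.poisson_scale < 0 or self.gaussian_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        if (self.corona_start_radius_nm is None) != (self.corona_model is None):
            raise ValueError("corona requires both a start radius and a model")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


def clean_intensity_field(spec: SyntheticImageSpec) -> np.ndarray:
    """Noise-free model intensity field of the spec, in model units."""
    nrow, ncol = spec.size_px
    # default centre on a pixel centre so axis-aligned radial profiles
    # sample the field exactly at pixel positions
    center = spec.center_px or (nrow // 2, ncol // 2)
    rows = np.arange(nrow)[:, None] - center[0]
    cols = np.arange(ncol)[None, :] - center[1]
    r_nm = np.hypot(rows, cols) * spec.pixel_size_nm
    field = np.full(r_nm.shape, spec.model.baseline_B, dtype=float)
    inside = r_nm <= spec.outer_radius_nm
    field[inside] = evaluate_model(spec.model, r_nm[inside])
    if spec.corona_model is not None:
        corona = inside & (r_nm >= spec.corona_start_radius_nm)
        field[corona] = evaluate_model(spec.corona_model, r_nm[corona])
    return field


def make_lamellar_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, GroundTruthRecord]:
    """Render a synthetic particle image with Poisson then Gaussian noise.

    The noise-free model peak is mapped to 60% of the output dynamic
    range (headroom for noise); the result is quantised to the spec's
    bit depth.  Deterministic per seed.
    """
    field = clean_intensity_field(spec)
    rng = np.random.default_rng(spec.seed)
    noisy = field
    if spec.poisson_scale > 0:
        noisy = rng.poisson(np.clip(field, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.gaussian_sigma, size=field.shape)
    noisy = np.clip(noisy, 0.0, None)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    dyn_max = np.iinfo(dtype).max
    scale = 0.6 * dyn_max / max(float(field.max()), 1e-12)
    image = np.clip(np.round(noisy * scale), 0, dyn_max).astype(dtype)
    record = GroundTruthRecord(
        generator="make_lamellar_image",
        parameters={
            "size_px": list(spec.size_px),
            "pixel_size_nm": spec.pixel_size_nm,
            "outer_radius_nm": spec.outer_radius_nm,
            "model": spec.model.__dict__,
            "corona_start_radius_nm": spec.corona_start_radius_nm,
            "corona_model": None
            if spec.corona_model is None
            else spec.corona_model.__dict__,
            "poisson_scale": spec.poisson_scale,
            "gaussian_sigma": spec.gaussian_sigma,
            "intensity_scale": scale,
            "bit_depth": spec.bit_depth,
        },
        seed=spec.seed,
        content_hash=_hash_array(image),
        synthetic_choices=("construction", "noise", "geometry"),
    )
    return image, record


def make_noisy_profile(
    model: LamellarModel,
    r_nm: np.ndarray,
    poisson_scale: float = 0.0,
    gaussian_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthRecord]:
    """1-D counterpart of the image generator: a noisy radial profile.

    Applies the same Poisson-then-Gaussian detector model directly to
    the model intensities on the given radius grid.
    """
    r_nm = np.asarray(r_nm, dtype=float)
    clean = evaluate_model(model, r_nm)
    rng = np.random.default_rng(seed)
    noisy = clean
    if poisson_scale > 0:
        noisy = rng.poisson(np.clip(clean, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sigma > 0:
        noisy = noisy + rng.normal(0.0, gaussian_sigma, size=clean.shape)
    noisy = np.clip(noisy, 0.0, None)
    record = GroundTruthRecord(
        generator="make_noisy_profile",
        parameters={
            "model": model.__dict__,
            "r_min_nm": float(r_nm[0]),
            "r_max_nm": float(r_nm[-1]),
            "n_points": int(r_nm.size),
            "poisson_scale": poisson_scale,
            "gaussian_sigma": gaussian_sigma,
        },
        seed=seed,
        content_hash=_hash_array(noisy),
        synthetic_choices=("noise",),
    )
    return noisy, record


# ---------------------------------------------------------------------------
# DLS

# label: (intensity-mean hydrodynamic diameter nm, PDI = 1 + mu2/mu1^2)
_DLS_PRESET_TABLE = {
    "pellet": (172.0, 1.18),
    "supernatant": (193.0, 1.22),
    "clodronate": (400.0, 1.50),
}

DLS_PRESETS = tuple(_DLS_PRESET_TABLE)


def dls_preset(name: str) -> tuple[float, float]:
    if name not in _DLS_PRESET_TABLE:
        raise KeyError(f"unknown DLS preset {name!r}; choose from {DLS_PRESETS}")
    return _DLS_PRESET_TABLE[name]


def lognormal_size_distribution(
    mean_diameter_nm: float,
    pdi: float,
    n_nodes: int = 15,
    medium: SolventMedium = WATER,
) -> SizeDistribution:
    """Discrete log-normal diffusivity mixture with prescribed mean and PDI.

    The log-normal width is set so the intensity-weighted relative
    variance of the diffusivity equals ``pdi - 1``, and the median is
    placed so the intensity-weighted mean diffusivity corresponds to
    ``mean_diameter_nm`` through Stokes-Einstein.  Gauss-Hermite
    quadrature nodes give an exactly normalised discrete mixture.
    """
    if pdi < 1:
        raise ValueError("pdi must be >= 1 under the 1 + mu2/mu1^2 convention")
    if pdi == 1.0:
        return SizeDistribution.from_diameters([mean_diameter_nm], medium=medium)
    sigma = math.sqrt(math.log(pdi))
    d_median = mean_diameter_nm * math.exp(sigma**2 / 2.0)
    z, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    diameters = d_median * np.exp(sigma * z)
    weights = w / w.sum()
    diffs = tuple(diffusion_from_diameter(d, medium) for d in diameters)
    return SizeDistribution(tuple(weights), diffs)


def make_dls_dataset(
    true_diameters_nm: Sequence[float] | str,
    weights: Sequence[float] | None = None,
    pdi: float | None = None,
    lags_s: np.ndarray | None = None,
    beta: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    medium: SolventMedium = WATER,
    wavelength_nm: float = 633.0,
    refractive_index: float = 1.33,
    angle_deg: float = 90.0,
) -> tuple[CorrelogramTrace, GroundTruthRecord]:
    """Synthesize a g2 correlogram for given sizes or a named preset.

    Pass a preset name (``pellet``/``supernatant``/``clodronate``) to
    use the study's mean size and polydispersity, or explicit diameters
    with optional weights (set ``pdi`` to spread a single diameter into
    a log-normal mixture).  Lags default to a logarithmic grid covering
    the decay.
    """
    preset_name = None
    if isinstance(true_diameters_nm, str):
        preset_name = true_diameters_nm
        mean_d, preset_pdi = dls_preset(preset_name)
        pdi = preset_pdi if pdi is None else pdi
        dist = lognormal_size_distribution(mean_d, pdi, medium=medium)
    elif pdi is not None and len(true_diameters_nm) == 1:
        dist = lognormal_size_distribution(true_diameters_nm[0], pdi, medium=medium)
    else:
        dist = SizeDistribution.from_diameters(true_diameters_nm, weights, medium=medium)
    q = scattering_vector(wavelength_nm, refractive_index, angle_deg)
    if lags_s is None:
        gamma = dist.mean_diffusion() * q**2
        lags_s = np.geomspace(1e-3 / gamma, 5.0 / gamma, 200)
    trace = simulate_g2(dist, q, lags_s, beta=beta, noise_sigma=noise_sigma,
                        seed=seed, medium=medium)
    record = GroundTruthRecord(
        generator="make_dls_dataset",
        parameters={
            "preset": preset_name,
            "weights": list(dist.weights),
            "diffusion_coefficients_m2_s": list(dist.diffusion_coefficients),
            "mean_diffusion_m2_s": dist.mean_diffusion(),
            "pdi_target": pdi,
            "q_1_m": q,
            "beta": beta,
            "noise_sigma": noise_sigma,
            "n_lags": int(np.asarray(lags_s).size),
        },
        seed=seed,
        content_hash=_hash_array(trace.g2),
        synthetic_choices=("lag_grid", "noise", "lognormal_shape"),
    )
    return trace, record


# ---------------------------------------------------------------------------
# zeta replicates

# label: (true zeta mV, replicate sigma mV, n replicates)
_ZETA_PRESET_TABLE = {
    "pellet": (0.0, 3.0, 5),
    "supernatant": (44.0, 3.0, 5),
    "clodronate": (-42.0, 15.0, 3),
}

ZETA_PRESETS = tuple(_ZETA_PRESET_TABLE)


def zeta_preset(name: str) -> tuple[float, float, int]:
    if name not in _ZETA_PRESET_TABLE:
        raise KeyError(f"unknown zeta preset {name!r}; choose from {ZETA_PRESETS}")
    return _ZETA_PRESET_TABLE[name]


def make_zeta_replicates(
    true_zeta_mV: float,
    instrument_sigma_mV: float,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthRecord]:
    """Replicate zeta measurements: true value plus Gaussian instrument noise."""
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    if instrument_sigma_mV < 0:
        raise ValueError("instrument sigma must be >= 0")
    rng = np.random.default_rng(seed)
    values = true_zeta_mV + rng.normal(0.0, instrument_sigma_mV, size=n)
    record = GroundTruthRecord(
        generator="make_zeta_replicates",
        parameters={
            "true_zeta_mV": true_zeta_mV,
            "instrument_sigma_mV": instrument_sigma_mV,
            "n": n,
        },
        seed=seed,
        content_hash=_hash_array(values),
        synthetic_choices=("noise",),
    )
    return values, record


# ---------------------------------------------------------------------------
# recipe fixture

RECIPE_FIXTURE: dict = {
    "reagents": {
        "POPC": {"molar_mass": 760.1, "role": "stabilizer", "stock_concentration": 10.0},
        "Chol": {"molar_mass": 386.7, "role": "helper", "stock_concentration": 10.0},
        "DSPE-PEG": {"molar_mass": 2810.0, "role": "adhesion", "stock_concentration": 10.0},
        "DSPE-PEG-MAN": {"molar_mass": 3000.0, "role": "targeting", "stock_concentration": 10.0},
        "DChol": {"molar_mass": 537.3, "role": "cationic_lipid", "stock_concentration": 18.0},
    },
    "lines": [
        {"reagent": "POPC", "mass_ug": 520.0},
        {"reagent": "Chol", "mass_ug": 130.0},
        {"reagent": "DSPE-PEG", "mass_ug": 40.0},
        {"reagent": "DSPE-PEG-MAN", "mass_ug": 310.0},
    ],
    "payload_monomer_umol": 1.3,
    "counterion_umol": 3.0,
    "payload_nmol": 40.0,
    "final_volume_uL": 250.0,
    "target_percent": {"POPC": 60.0, "Chol": 30.0, "DSPE-PEG": 1.0, "DSPE-PEG-MAN": 9.0},
}


def make_recipe_fixture(path=None) -> tuple[str, GroundTruthRecord]:
    """Emit the protocol's lipid-film recipe as YAML text (optionally to a file).

    The quantities are the protocol's printed masses and stated payload
    accounting (including its printed monomer total, preserved as data
    rather than recomputed).
    """
    import yaml

    text = yaml.safe_dump(RECIPE_FIXTURE, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    record = GroundTruthRecord(
        generator="make_recipe_fixture",
        parameters={"n_lines": len(RECIPE_FIXTURE["lines"])},
        seed=0,
        content_hash=_hash_text(text),
    )
    return text, record


def record_to_json(record: GroundTruthRecord) -> str:
    """Serialise a ground-truth record as stable JSON."""
    return json.dumps(
        {
            "generator": record.generator,
            "parameters": record.parameters,
            "seed": record.seed,
            "content_hash": record.content_hash,
            "synthetic_choices": list(record.synthetic_choices),
        },
        sort_keys=True,
        indent=2,
    )
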
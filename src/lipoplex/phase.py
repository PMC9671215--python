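"""Ternary Bligh-Dyer solvent arithmetic.

Composition bookkeeping for water/methanol/chloroform mixtures: exact
volume<->weight basis conversion, ideal volume-additive mixing for
protocol step ledgers, monophasic/biphasic classification against a
binodal boundary, and the lever rule along user-supplied tie-lines.

The weight-basis conversion follows ``w_i = phi_i rho_i / sum_j phi_j
rho_j`` with solvent densities 1.0 / 0.8 / 1.5 g/cm^3 for water,
methanol and chloroform.  Mixing is ideal (volume-additive); excess
volumes are ignored.

The shipped binodal asset is a synthetic piecewise-linear digitization
of the classic Bligh-Dyer one-phase/two-phase boundary, constrained to
pass through the critical composition (30% water, 15% methanol, 55%
chloroform, w/w) and validated against the two protocol compositions it
must classify (the monophasic complexation mixture and the biphasic
compaction mixture).  It is a replaceable CSV, not a measured curve.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Basis",
    "TernaryComposition",
    "DensitySet",
    "BinodalModel",
    "MixtureLedger",
    "PhaseLabel",
    "convert_basis",
    "mix",
    "classify_phase",
    "lever_rule",
    "load_default_binodal",
]

_SUM_TOL = 1e-6


class Basis(str, enum.Enum):
    VOLUME = "volume"
    WEIGHT = "weight"


class PhaseLabel(str, enum.Enum):
    MONOPHASIC = "monophasic"
    BIPHASIC = "biphasic"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class DensitySet:
    """Solvent densities in g/cm^3."""

    water: float = 1.0
    methanol: float = 0.8
    chloroform: float = 1.5

    def __post_init__(self) -> None:
        for name in ("water", "methanol", "chloroform"):
            if not getattr(self, name) > 0:
                raise ValueError(f"density of {name} must be > 0")


DEFAULT_DENSITIES = DensitySet()


@dataclass(frozen=True)
class TernaryComposition:
    """Water/methanol/chloroform composition in percent, with basis.

    Components must be non-negative and sum to 100 (tolerance 1e-6).
    """

    water: float
    methanol: float
    chloroform: float
    basis: Basis = Basis.VOLUME

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", Basis(self.basis))
        for name in ("water", "methanol", "chloroform"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} fraction must be >= 0")
        total = self.water + self.methanol + self.chloroform
        if abs(total - 100.0) > _SUM_TOL:
            raise ValueError(f"components must sum to 100, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.water, self.methanol, self.chloroform], dtype=float)

    def as_basis(
        self, target: Basis | str, densities: DensitySet = DEFAULT_DENSITIES
    ) -> "TernaryComposition":
        return convert_basis(self, densities, target)


def convert_basis(
    comp: TernaryComposition,
    densities: DensitySet = DEFAULT_DENSITIES,
    target: Basis | str = Basis.WEIGHT,
) -> TernaryComposition:
    """Exact algebraic conversion between volume and weight basis.

    v/v -> w/w multiplies each fraction by its density and renormalises;
    w/w -> v/v divides.  The round trip is the identity to floating
    precision.
    """
    target = Basis(target)
    if comp.basis == target:
        return comp
    rho = np.array([densities.water, densities.methanol, densities.chloroform])
    x = comp.as_array()
    if target is Basis.WEIGHT:
        y = x * rho
    else:
        y = x / rho
    y = 100.0 * y / y.sum()
    return TernaryComposition(y[0], y[1], y[2], basis=target)


@dataclass(frozen=True)
class MixtureLedger:
    """Ordered solvent additions: (volume uL, volume-basis composition)."""

    additions: tuple[tuple[float, TernaryComposition], ...]

    def __post_init__(self) -> None:
        for vol, comp in self.additions:
            if not vol > 0:
                raise ValueError(f"addition volumes must be > 0, got {vol}")
            if comp.basis is not Basis.VOLUME:
                raise ValueError("ledger compositions must be volume-basis")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[float, TernaryComposition]]
    ) -> "MixtureLedger":
        return cls(tuple(pairs))

    @property
    def total_volume(self) -> float:
        return sum(v for v, _ in self.additions)


PURE_WATER = TernaryComposition(100, 0, 0)
PURE_METHANOL = TernaryComposition(0, 100, 0)
PURE_CHLOROFORM = TernaryComposition(0, 0, 100)


def mix(ledger: MixtureLedger) -> TernaryComposition:
    """Pool a ledger of additions assuming ideal (volume-additive) mixing."""
    if not ledger.additions:
        raise ValueError("cannot mix an empty ledger")
    totals = np.zeros(3)
    for vol, comp in ledger.additions:
        totals += vol * comp.as_array() / 100.0
    fracs = 100.0 * totals / totals.sum()
    return TernaryComposition(fracs[0], fracs[1], fracs[2], basis=Basis.VOLUME)


@dataclass(frozen=True)
class BinodalModel:
    """Piecewise-linear one-phase/two-phase boundary in weight basis.

    The boundary is stored as ordered compositions along the curve from
    the water-rich end to the chloroform-rich end.  Internally it is
    parameterised by the chloroform share of the (water + chloroform)
    sub-binary, ``x = w_chcl3 / (w_water + w_chcl3)``, against the
    methanol height ``h = w_meoh``; mixtures below the curve (methanol-
    poor) are biphasic, above it monophasic.
    """

    points: tuple[TernaryComposition, ...]
    boundary_tolerance: float = 0.5  # percent methanol

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("binodal needs at least 3 points")
        for p in self.points:
            if p.basis is not Basis.WEIGHT:
                raise ValueError("binodal points must be weight-basis")
        x, h = self._xh()
        if not np.all(np.diff(x) > 0):
            raise ValueError("binodal points must be ordered by chloroform share")

    def _xh(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.array([p.as_array() for p in self.points])
        wc = arr[:, 0] + arr[:, 2]
        if np.any(wc <= 0):
            raise ValueError("binodal points cannot lie at the methanol vertex")
        return arr[:, 2] / wc, arr[:, 1]

    def methanol_height(self, x: float) -> float | None:
        """Binodal methanol %% at chloroform share ``x``; None outside range."""
        xs, hs = self._xh()
        if x < xs[0] or x > xs[-1]:
            return None
        return float(np.interp(x, xs, hs))


def load_default_binodal(path: str | Path | None = None) -> BinodalModel:
    """Load the binodal polyline from CSV (`w_water,w_methanol,w_chloroform`)."""
    if path is None:
        ref = resources.files("lipoplex") / "data" / "bd_binodal.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    expected = ["w_water", "w_methanol", "w_chloroform"]
    if list(df.columns) != expected:
        raise ValueError(f"binodal CSV must have columns {expected}, got {list(df.columns)}")
    pts = tuple(
        TernaryComposition(r.w_water, r.w_methanol, r.w_chloroform, basis=Basis.WEIGHT)
        for r in df.itertuples()
    )
    return BinodalModel(pts)


def classify_phase(
    comp: TernaryComposition,
    binodal: BinodalModel | None = None,
    densities: DensitySet = DEFAULT_DENSITIES,
) -> PhaseLabel:
    """Classify a composition as monophasic / biphasic / boundary.

    Classification always happens in weight basis regardless of the
    input basis.  Compositions outside the binodal's footprint along the
    water-chloroform sub-binary (including the methanol-rich corner) are
    monophasic.
    """
    if binodal is None:
        binodal = load_default_binodal()
    w = convert_basis(comp, densities, Basis.WEIGHT)
    wc = w.water + w.chloroform
    if wc <= 0:  # pure methanol corner
        return PhaseLabel.MONOPHASIC
    x = w.chloroform / wc
    h_b = binodal.methanol_height(x)
    if h_b is None:
        return PhaseLabel.MONOPHASIC
    if abs(w.methanol - h_b) <= binodal.boundary_tolerance:
        return PhaseLabel.BOUNDARY
    return PhaseLabel.BIPHASIC if w.methanol < h_b else PhaseLabel.MONOPHASIC


def lever_rule(
    comp: TernaryComposition,
    endpoint_light: TernaryComposition,
    endpoint_heavy: TernaryComposition,
    tolerance: float = 1e-6,
) -> dict[str, float]:
    """Phase fractions from the lever rule along a tie-line.

    ``comp`` must lie on the segment between the two endpoints (within
    ``tolerance`` in composition percent).  Returns ``fraction_light``
    and ``fraction_heavy`` which sum to exactly 1; a composition at the
    heavy endpoint gives (0, 1).
    """
    basis = comp.basis
    a = endpoint_light.as_basis(basis).as_array()
    b = endpoint_heavy.as_basis(basis).as_array()
    p = comp.as_array()
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        raise ValueError("tie-line endpoints coincide")
    t = float((p - a) @ ab) / denom
    if t < -tolerance or t > 1 + tolerance:
        raise ValueError("composition lies outside the tie-line segment")
    residual = p - (a + t * ab)
    if float(np.abs(residual).max()) > max(tolerance, 1e-9):
        raise ValueError(
            f"composition is off the tie-line by {float(np.abs(residual).max()):.3g}%"
        )
    t = min(max(t, 0.0), 1.0)
    return {"fraction_light": 1.0 - t, "fraction_heavy": t}
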
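"""Electrostatic design rules for catanionic lipoplex assembly.

The core quantity is the Bjerrum length, the separation at which the
Coulomb energy between two elementary charges equals the thermal energy
``kB*T``::

    lambda_B = e**2 / (4 * pi * eps0 * eps_rel * kB * T)

In water at 25 degC this is about 0.70 nm.  For a linear polyanion with
axial charge spacing ``l0`` the Manning coupling parameter is
``Gamma = lambda_B / l0``; counterion condensation sets in above
``Gamma = 1`` with a condensed fraction ``theta = 1 - 1/Gamma``.  Tuning
the solvent permittivity (here through ternary water/methanol/chloroform
mixtures) tunes ``lambda_B`` and hence the strength of the catanionic
condensation driving lipoplex assembly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Mapping

from .constants import (
    BOLTZMANN,
    DEFAULT_TEMPERATURE_K,
    ELEMENTARY_CHARGE,
    NM_PER_M,
    VACUUM_PERMITTIVITY,
)
from .phase import TernaryComposition

__all__ = [
    "SolventMedium",
    "CondensationRegime",
    "CondensationAssessment",
    "bjerrum_length",
    "coupling_parameter",
    "manning_condensed_fraction",
    "mixture_permittivity",
    "classify_regime",
    "assess_condensation",
    "WATER",
    "METHANOL",
    "CHLOROFORM",
    "DEFAULT_COMPONENT_PERMITTIVITIES",
]


@dataclass(frozen=True)
class SolventMedium:
    """A dielectric medium characterised by permittivity and temperature.

    Parameters
    ----------
    relative_permittivity:
        Relative dielectric permittivity (dimensionless, > 0).
    temperature:
        Absolute temperature in kelvin (> 0).
    viscosity:
        Dynamic viscosity in Pa*s; optional, required only by the
        hydrodynamic (DLS) and electrokinetic modules.
    """

    relative_permittivity: float
    temperature: float = DEFAULT_TEMPERATURE_K
    viscosity: float | None = None

    def __post_init__(self) -> None:
        if not self.relative_permittivity > 0:
            raise ValueError(
                f"relative_permittivity must be > 0, got {self.relative_permittivity}"
            )
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.viscosity is not None and not self.viscosity > 0:
            raise ValueError(f"viscosity must be > 0 Pa*s, got {self.viscosity}")


#: Water at 25 degC (eps_rel ~ 80, eta = 0.89 mPa*s)
WATER = SolventMedium(80.0, DEFAULT_TEMPERATURE_K, 0.89e-3)
#: Methanol (eps_rel ~ 30)
METHANOL = SolventMedium(30.0, DEFAULT_TEMPERATURE_K)
#: Chloroform / organic-rich phase (eps_rel ~ 5)
CHLOROFORM = SolventMedium(5.0, DEFAULT_TEMPERATURE_K)

#: Default component permittivities for water/methanol/chloroform mixtures.
DEFAULT_COMPONENT_PERMITTIVITIES: Mapping[str, float] = {
    "water": 80.0,
    "methanol": 30.0,
    "chloroform": 5.0,
}


class CondensationRegime(str, enum.Enum):
    SUB_CRITICAL = "sub_critical"
    WEAKLY_CONDENSING = "weakly_condensing"
    STRONGLY_CONDENSING = "strongly_condensing"


@dataclass(frozen=True)
class CondensationAssessment:
    """Bjerrum/Manning assessment of one medium against one polyanion."""

    bjerrum_length: float  # nm
    coupling: float  # Gamma, dimensionless
    condensed_fraction: float  # theta in [0, 1)
    regime_label: CondensationRegime


def bjerrum_length(medium: SolventMedium) -> float:
    """Bjerrum length of a medium, in nanometres.

    ``lambda_B = e^2 / (4 pi eps0 eps_rel kB T)``.  Water at 298.15 K
    gives 0.70 nm; the value is inversely proportional to both the
    permittivity and the temperature.
    """
    if not isinstance(medium, SolventMedium):
        medium = SolventMedium(*medium)  # type: ignore[misc]
    lam_m = ELEMENTARY_CHARGE**2 / (
        4.0
        * math.pi
        * VACUUM_PERMITTIVITY
        * medium.relative_permittivity
        * BOLTZMANN
        * medium.temperature
    )
    return lam_m * NM_PER_M


def coupling_parameter(bjerrum_length_nm: float, charge_spacing_l0_nm: float) -> float:
    """Manning coupling parameter ``Gamma = lambda_B / l0`` (dimensionless)."""
    if not bjerrum_length_nm > 0:
        raise ValueError(f"bjerrum_length must be > 0, got {bjerrum_length_nm}")
    if not charge_spacing_l0_nm > 0:
        raise ValueError(f"charge_spacing_l0 must be > 0, got {charge_spacing_l0_nm}")
    return bjerrum_length_nm / charge_spacing_l0_nm


def manning_condensed_fraction(gamma: float) -> float:
    """Condensed counterion fraction ``theta = max(0, 1 - 1/Gamma)``.

    Below the Manning threshold (``Gamma <= 1``) no condensation occurs
    and theta is exactly zero; above it theta increases monotonically
    toward 1.
    """
    if gamma < 0:
        raise ValueError(f"coupling parameter must be >= 0, got {gamma}")
    if gamma <= 1.0:
        return 0.0
    return 1.0 - 1.0 / gamma


def mixture_permittivity(
    comp: TernaryComposition,
    component_permittivities: Mapping[str, float] | None = None,
    model: str | Callable[[Mapping[str, float], Mapping[str, float]], float] = "linear",
) -> float:
    """Effective permittivity of a ternary solvent mixture.

    The default rule is a volume-fraction-weighted linear mix of the
    component permittivities, which reproduces the pure-component
    endpoints exactly and stays within the component extremes.  Pass a
    callable (taking fraction and permittivity mappings) or register a
    different ``model`` name to plug in another mixing rule.
    """
    perms = dict(
        component_permittivities
        if component_permittivities is not None
        else DEFAULT_COMPONENT_PERMITTIVITIES
    )
    for name in ("water", "methanol", "chloroform"):
        if name not in perms:
            raise KeyError(f"missing permittivity for component {name!r}")
    comp_v = comp.as_basis("volume")
    fractions = {
        "water": comp_v.water / 100.0,
        "methanol": comp_v.methanol / 100.0,
        "chloroform": comp_v.chloroform / 100.0,
    }
    if callable(model):
        return model(fractions, perms)
    if model == "linear":
        return sum(fractions[k] * perms[k] for k in fractions)
    raise ValueError(f"unknown permittivity_model {model!r}")


def classify_regime(
    coupling: float,
    bjerrum_length_nm: float,
    rod_length_nm: float,
    manning_threshold: float = 1.0,
) -> CondensationRegime:
    """Condensation regime of a medium relative to a charged rod.

    sub-critical below the Manning threshold; weakly condensing when the
    Bjerrum cage is smaller than the rod; strongly condensing once the
    cage spans the whole rod (``lambda_B >= L_rod``).
    """
    if coupling <= manning_threshold:
        return CondensationRegime.SUB_CRITICAL
    if bjerrum_length_nm >= rod_length_nm:
        return CondensationRegime.STRONGLY_CONDENSING
    return CondensationRegime.WEAKLY_CONDENSING


def assess_condensation(
    medium: SolventMedium,
    charge_spacing_l0_nm: float,
    rod_length_nm: float,
) -> CondensationAssessment:
    """Full Bjerrum/Manning assessment of ``medium`` for a given rod."""
    lam = bjerrum_length(medium)
    gamma = coupling_parameter(lam, charge_spacing_l0_nm)
    theta = manning_condensed_fraction(gamma)
    label = classify_regime(gamma, lam, rod_length_nm)
    return CondensationAssessment(
        bjerrum_length=lam,
        coupling=gamma,
        condensed_fraction=theta,
        regime_label=label,
    )
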
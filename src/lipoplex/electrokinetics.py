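"""Electrophoretic mobility <-> zeta potential (Smoluchowski limit).

For colloids in the viscous-drag (thin double layer) regime the
Smoluchowski relation ``mu_e = eps * zeta / eta`` links electrophoretic
mobility to zeta potential.  The measurement medium defaults here
(eps_rel = 100, eta = 1e-3 Pa*s) describe the dilute KNO3 electrolyte
used in the electrophoretic cell, deliberately distinct from pure
water.  Note the measured potentials are "bare" (unscreened) values; in
physiological ionic strength the effective Coulomb interactions are
screened down by more than an order of magnitude, so zeta here carries
physicochemical meaning (degree of charge neutralisation), not an
in-situ surface potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import VACUUM_PERMITTIVITY
from .physchem import SolventMedium

__all__ = [
    "ZETA_MEDIUM",
    "MobilityMeasurement",
    "ZetaSummary",
    "zeta_from_mobility",
    "mobility_from_zeta",
    "summarize_replicates",
]

#: Default electrophoresis medium: dilute KNO3 cell (eps_rel 100, eta 1 mPa*s).
ZETA_MEDIUM = SolventMedium(relative_permittivity=100.0, viscosity=1e-3)


@dataclass(frozen=True)
class MobilityMeasurement:
    mobility: float  # m^2/(V s)
    medium: SolventMedium = ZETA_MEDIUM

    def __post_init__(self) -> None:
        if self.medium.viscosity is None:
            raise ValueError("electrophoresis medium requires a viscosity")


@dataclass(frozen=True)
class ZetaSummary:
    mean: float  # mV
    sd: float  # mV (sample sd)
    n: int
    neutral: bool


def zeta_from_mobility(m: MobilityMeasurement | float, medium: SolventMedium | None = None) -> float:
    """Zeta potential in mV from electrophoretic mobility (Smoluchowski)."""
    if isinstance(m, MobilityMeasurement):
        mobility, med = m.mobility, m.medium
    else:
        mobility, med = float(m), medium or ZETA_MEDIUM
    if med.viscosity is None:
        raise ValueError("electrophoresis medium requires a viscosity")
    zeta_V = mobility * med.viscosity / (med.relative_permittivity * VACUUM_PERMITTIVITY)
    return zeta_V * 1e3


def mobility_from_zeta(zeta_mV: float, medium: SolventMedium = ZETA_MEDIUM) -> float:
    """Electrophoretic mobility (m^2/(V s)) from zeta potential in mV."""
    if medium.viscosity is None:
        raise ValueError("electrophoresis medium requires a viscosity")
    return (zeta_mV * 1e-3) * medium.relative_permittivity * VACUUM_PERMITTIVITY / medium.viscosity


def summarize_replicates(values_mV, neutrality_band_mV: float = 5.0) -> ZetaSummary:
    """Mean, sample sd and neutrality flag of replicate zeta values.

    A preparation is called neutral when ``|mean| <= neutrality_band``
    (default +-5 mV, wide enough that a 0 +- 3 mV pellet is neutral and
    a 44 mV supernatant is not).
    """
    values = np.asarray(list(values_mV), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return ZetaSummary(
        mean=mean,
        sd=sd,
        n=int(values.size),
        neutral=abs(mean) <= neutrality_band_mV,
    )
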
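"""Dynamic light scattering: correlogram synthesis and cumulant analysis.

The intensity autocorrelation obeys the Siegert relation
``g2(tau) = 1 + beta * |g1(tau)|^2`` with the field correlation of a
mixture of diffusers ``g1(tau) = sum_i w_i exp(-D_i q^2 tau)``
(intensity weights ``w_i``).  Second-order cumulant analysis fits::

    ln[(g2 - 1)] = ln(beta) - 2*mu1*tau + mu2*tau^2

so that ``mu1 = Dbar q^2`` (intensity-weighted mean diffusivity) and
``mu2 = (var D) q^4``.  The polydispersity index used here is
``PDI = 1 + mu2/mu1^2`` (unity for a monodisperse sample).  Sizes follow
from Stokes-Einstein, ``Dbar = kB T / (3 pi eta d_H)`` for the
hydrodynamic diameter ``d_H``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BOLTZMANN, NM_PER_M
from .physchem import SolventMedium, WATER

__all__ = [
    "CorrelogramTrace",
    "SizeDistribution",
    "CumulantResult",
    "scattering_vector",
    "simulate_g2",
    "cumulant_fit",
    "hydrodynamic_size",
    "diffusion_from_diameter",
    "DEFAULT_INSTRUMENT",
]

#: Instrument defaults: HeNe laser, 90 degree detection, aqueous buffer.
DEFAULT_INSTRUMENT = {
    "wavelength_nm": 633.0,
    "refractive_index": 1.33,
    "angle_deg": 90.0,
}


def scattering_vector(
    wavelength_nm: float = 633.0,
    refractive_index: float = 1.33,
    angle_deg: float = 90.0,
) -> float:
    """Scattering vector magnitude ``q = 4 pi n sin(theta/2) / lambda`` in 1/m."""
    if not 0 < angle_deg < 180:
        raise ValueError(f"scattering angle must be in (0, 180) deg, got {angle_deg}")
    lam_m = wavelength_nm * 1e-9
    return 4.0 * math.pi * refractive_index * math.sin(math.radians(angle_deg) / 2.0) / lam_m


def diffusion_from_diameter(diameter_nm: float, medium: SolventMedium = WATER) -> float:
    """Stokes-Einstein diffusion coefficient (m^2/s) of a sphere."""
    if medium.viscosity is None:
        raise ValueError("medium viscosity is required for Stokes-Einstein")
    if not diameter_nm > 0:
        raise ValueError("diameter must be > 0")
    radius_m = diameter_nm * 1e-9 / 2.0
    return BOLTZMANN * medium.temperature / (6.0 * math.pi * medium.viscosity * radius_m)


def hydrodynamic_size(mean_diffusion: float, medium: SolventMedium = WATER) -> float:
    """Hydrodynamic diameter (nm) from a mean diffusion coefficient (m^2/s)."""
    if medium.viscosity is None:
        raise ValueError("medium viscosity is required for Stokes-Einstein")
    if not mean_diffusion > 0:
        raise ValueError("mean diffusion must be > 0")
    radius_m = BOLTZMANN * medium.temperature / (
        6.0 * math.pi * medium.viscosity * mean_diffusion
    )
    return 2.0 * radius_m * NM_PER_M


@dataclass(frozen=True)
class SizeDistribution:
    """Discrete intensity-weighted mixture of diffusing species.

    Each component is (weight, diffusion coefficient m^2/s).  Weights
    are normalised to one on construction.
    """

    weights: tuple[float, ...]
    diffusion_coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.diffusion_coefficients) or not self.weights:
            raise ValueError("weights and diffusion coefficients must match and be non-empty")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be > 0")
        if any(d <= 0 for d in self.diffusion_coefficients):
            raise ValueError("diffusion coefficients must be > 0")
        total = sum(self.weights)
        object.__setattr__(self, "weights", tuple(w / total for w in self.weights))

    @classmethod
    def from_diameters(
        cls,
        diameters_nm,
        weights=None,
        medium: SolventMedium = WATER,
    ) -> "SizeDistribution":
        diameters_nm = tuple(diameters_nm)
        if weights is None:
            weights = tuple(1.0 for _ in diameters_nm)
        ds = tuple(diffusion_from_diameter(d, medium) for d in diameters_nm)
        return cls(tuple(weights), ds)

    def mean_diffusion(self) -> float:
        """Intensity-weighted mean diffusivity Dbar."""
        return float(np.dot(self.weights, self.diffusion_coefficients))

    def moments(self, q: float) -> tuple[float, float]:
        """Closed-form cumulant moments (mu1, mu2) of this distribution."""
        w = np.asarray(self.weights)
        d = np.asarray(self.diffusion_coefficients)
        dbar = float(w @ d)
        var = float(w @ (d - dbar) ** 2)
        return dbar * q**2, var * q**4


@dataclass(frozen=True)
class CorrelogramTrace:
    """A g2(tau) trace with the geometry needed to interpret it."""

    lags: np.ndarray  # s, strictly increasing, > 0
    g2: np.ndarray
    scattering_vector_q: float  # 1/m
    medium: SolventMedium = WATER
    coherence_beta: float = 1.0

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g2 = np.asarray(self.g2, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g2", g2)
        if lags.ndim != 1 or lags.shape != g2.shape:
            raise ValueError("lags and g2 must be 1-D arrays of equal length")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing and > 0")
        if not 0 < self.coherence_beta <= 1:
            raise ValueError("coherence beta must be in (0, 1]")


def simulate_g2(
    dist: SizeDistribution,
    q: float,
    lags,
    beta: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    medium: SolventMedium = WATER,
) -> CorrelogramTrace:
    """Synthesize ``g2(tau) = 1 + beta |g1|^2 + N(0, sigma)`` deterministically.

    Gaussian noise is drawn from ``numpy.random.default_rng(seed)``;
    the same seed reproduces the same trace bit for bit.
    """
    lags = np.asarray(lags, dtype=float)
    w = np.asarray(dist.weights)
    d = np.asarray(dist.diffusion_coefficients)
    g1 = np.sum(w[None, :] * np.exp(-d[None, :] * q**2 * lags[:, None]), axis=1)
    g2 = 1.0 + beta * g1**2
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        g2 = g2 + rng.normal(0.0, noise_sigma, size=g2.shape)
    return CorrelogramTrace(
        lags=lags, g2=g2, scattering_vector_q=q, medium=medium, coherence_beta=beta
    )


@dataclass(frozen=True)
class CumulantResult:
    mu1: float  # 1/s
    mu2: float  # 1/s^2
    mean_diffusion: float  # m^2/s
    hydrodynamic_diameter: float  # nm
    pdi: float  # >= 1 by this convention
    beta: float
    mu2_clamped: bool = False
    n_points_fit: int = 0
    converged: bool = True
    notes: tuple[str, ...] = field(default=())


def cumulant_fit(
    trace: CorrelogramTrace,
    order: int = 2,
    fit_threshold: float = 0.05,
    beta: float | None = None,
) -> CumulantResult:
    """Second-order cumulant fit of a correlogram.

    Weighted linear least squares of ``ln(g2 - 1)`` against
    ``[1, tau, tau^2]`` (weights proportional to ``(g2-1)^2``,
    the standard variance stabilisation for the log transform), over the
    window where ``(g2-1)/beta > fit_threshold``.  ``beta`` defaults to
    the fitted tau->0 intercept; pass a value to pin it.  ``mu2`` is
    clamped at zero (flagged) so the reported PDI is always >= 1.
    """
    if order != 2:
        raise ValueError("only second-order cumulant analysis is implemented")
    y_full = trace.g2 - 1.0
    beta0 = beta if beta is not None else max(float(np.max(y_full)), 1e-12)
    mask = y_full / beta0 > fit_threshold
    if int(mask.sum()) < (3 if beta is None else 2):
        raise ValueError("no usable signal above the fit threshold (g2 <= 1 everywhere?)")
    tau = trace.lags[mask]
    y = y_full[mask]
    ln_y = np.log(y)
    w = y**2
    notes: list[str] = []
    if beta is None:
        X = np.stack([np.ones_like(tau), tau, tau**2], axis=1)
    else:
        ln_y = ln_y - math.log(beta)
        X = np.stack([tau, tau**2], axis=1)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], ln_y * sw, rcond=None)
    if beta is None:
        c0, c1, c2 = coef
        beta_fit = float(np.exp(c0))
    else:
        c1, c2 = coef
        beta_fit = beta
    mu1 = -float(c1) / 2.0
    mu2 = float(c2)
    clamped = False
    if mu2 < 0:
        mu2 = 0.0
        clamped = True
        notes.append("mu2 < 0 clamped to 0")
    if mu1 <= 0:
        raise ValueError("fit returned non-positive decay rate; no diffusive signal")
    q = trace.scattering_vector_q
    dbar = mu1 / q**2
    diameter = hydrodynamic_size(dbar, trace.medium)
    pdi = 1.0 + mu2 / mu1**2
    return CumulantResult(
        mu1=mu1,
        mu2=mu2,
        mean_diffusion=dbar,
        hydrodynamic_diameter=diameter,
        pdi=pdi,
        beta=beta_fit,
        mu2_clamped=clamped,
        n_points_fit=int(mask.sum()),
        notes=tuple(notes),
    )


def pdi_from_size_cv(sigma_R: float, mean_R: float) -> float:
    """Alternative size-dispersion index ``1 + sigma_R / R_H``.

    Provided as a secondary convention alongside the cumulant-based
    ``1 + mu2/mu1^2`` used everywhere else in this module.
    """
    if not mean_R > 0:
        raise ValueError("mean radius must be > 0")
    return 1.0 + sigma_R / mean_R
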
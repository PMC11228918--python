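"""Dynamic light scattering sizing by second-order cumulant analysis.

An intensity autocorrelation function ``g2(τ) − 1`` measured in
backscatter geometry is reduced to a mean decay rate Γ (the Z-average)
and a polydispersity index by fitting

    ln(g2 − 1) = ln β − 2Γτ + µ₂τ²

over the head of the decay, after which the Stokes–Einstein relation
converts the translational diffusivity D_t = Γ/q² into a solvodynamic
diameter.  This is the standard single-angle cumulant method used by
commercial instruments; no inverse-Laplace size distribution is
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    BOLTZMANN_J_PER_K,
    mpa_s_to_pa_s,
    nm2_per_us_to_m2_per_s,
)

__all__ = [
    "InstrumentSpec",
    "Correlogram",
    "CumulantFit",
    "scattering_vector",
    "fit_cumulants",
    "diameter_from_gamma",
    "gamma_from_diameter",
]


@dataclass(frozen=True)
class InstrumentSpec:
    """Optical and sample parameters of a single-angle DLS measurement.

    Parameters
    ----------
    wavelength_nm : laser vacuum wavelength (nm).
    scattering_angle_deg : detection angle (degrees, 0–180 exclusive).
    refractive_index : solvent refractive index at the laser wavelength.
    temperature_K : sample temperature (K).
    viscosity_mpa_s : solvent dynamic viscosity (mPa·s).
    """

    wavelength_nm: float = 633.0
    scattering_angle_deg: float = 173.0
    refractive_index: float = 1.33
    temperature_K: float = 298.15
    viscosity_mpa_s: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength_nm}")
        if not 0.0 < self.scattering_angle_deg <= 180.0:
            raise ValueError(
                f"scattering angle must lie in (0, 180] degrees, got {self.scattering_angle_deg}"
            )
        if self.refractive_index <= 0:
            raise ValueError("refractive index must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.viscosity_mpa_s <= 0:
            raise ValueError("viscosity must be positive")


@dataclass(frozen=True)
class Correlogram:
    """Normalized intensity autocorrelation ``g2(τ) − 1`` vs lag.

    ``lags_us`` must be strictly increasing and positive; at least 10
    points are required for a meaningful cumulant fit.
    """

    lags_us: np.ndarray
    g2_minus_1: np.ndarray
    instrument: InstrumentSpec

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_us, dtype=float)
        g = np.asarray(self.g2_minus_1, dtype=float)
        object.__setattr__(self, "lags_us", lags)
        object.__setattr__(self, "g2_minus_1", g)
        if lags.ndim != 1 or g.shape != lags.shape:
            raise ValueError("lags and g2_minus_1 must be 1-D arrays of equal length")
        if lags.size < 10:
            raise ValueError(f"need at least 10 lag points, got {lags.size}")
        if not np.all(lags > 0):
            raise ValueError("all lags must be positive")
        if not np.all(np.diff(lags) > 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValueError("g2_minus_1 contains non-finite values")


@dataclass(frozen=True)
class CumulantFit:
    """Result of a second-order cumulant fit.

    Attributes
    ----------
    intercept_beta : coherence factor β (intercept of g2−1 at τ=0).
    gamma_per_us : mean decay rate Γ (1/µs).
    mu2_per_us2 : second cumulant µ₂ ((1/µs)²); may be slightly negative
        on noisy data, in which case the PDI is clamped at zero.
    pdi : polydispersity index µ₂/Γ².
    n_points : number of lag points inside the fit window.
    """

    intercept_beta: float
    gamma_per_us: float
    mu2_per_us2: float
    pdi: float
    n_points: int


class CumulantFitError(RuntimeError):
    """Raised when the correlogram head cannot support a cumulant fit."""


def scattering_vector(instrument: InstrumentSpec) -> float:
    """Magnitude of the scattering wave vector q = 4πn sin(θ/2)/λ, in 1/nm."""
    theta = math.radians(instrument.scattering_angle_deg)
    return (
        4.0
        * math.pi
        * instrument.refractive_index
        * math.sin(theta / 2.0)
        / instrument.wavelength_nm
    )


def _default_window(g: np.ndarray) -> np.ndarray:
    # Head of the decay: keep lags where g2-1 is at least 10% of its
    # maximum.  The maximum is the best available proxy for beta before
    # the fit itself has run.
    return g >= 0.1 * float(np.max(g))


def fit_cumulants(
    correlogram: Correlogram,
    fit_window: tuple[float, float] | None = None,
) -> CumulantFit:
    """Weighted least-squares second-order cumulant fit.

    Fits ``ln(g2−1) = ln β − 2Γτ + µ₂τ²`` over the fit window with
    weights (g2−1)² in the χ² sum, which stabilizes the log
    linearization against tail noise.

    Parameters
    ----------
    correlogram : the measured autocorrelation.
    fit_window : optional (lag_min, lag_max) in µs; by default all lags
        where g2−1 ≥ 0.1·max(g2−1) are used.

    Raises
    ------
    CumulantFitError
        If fewer than 10 points fall in the window, the head of the
        decay is not positive, or the design matrix is rank deficient
        (window too short to separate Γ from µ₂).
    """
    tau = correlogram.lags_us
    g = correlogram.g2_minus_1

    if fit_window is not None:
        lo, hi = fit_window
        mask = (tau >= lo) & (tau <= hi)
    else:
        mask = _default_window(g)

    if int(mask.sum()) < 10:
        raise CumulantFitError(
            f"only {int(mask.sum())} lag points in fit window; need >= 10"
        )
    tau_w = tau[mask]
    g_w = g[mask]
    if np.any(g_w <= 0):
        raise CumulantFitError("g2-1 must be positive over the fitted head of the decay")

    # Design matrix for ln g = c0 + c1 tau + c2 tau^2, chi^2 weights g^2
    # (i.e. rows scaled by g).
    A = np.column_stack([np.ones_like(tau_w), tau_w, tau_w**2]) * g_w[:, None]
    y = np.log(g_w) * g_w
    coeffs, _, rank, sv = np.linalg.lstsq(A, y, rcond=None)
    if rank < 3 or sv[0] / sv[-1] > 1e12:
        raise CumulantFitError(
            "ill-conditioned cumulant fit: widen the fit window (lags span too little decay)"
        )
    c0, c1, c2 = coeffs
    gamma = -0.5 * c1
    if gamma <= 0:
        raise CumulantFitError(f"fitted decay rate is non-positive ({gamma:.3g} 1/us)")
    mu2 = float(c2)
    pdi = max(mu2, 0.0) / gamma**2
    return CumulantFit(
        intercept_beta=float(np.exp(c0)),
        gamma_per_us=float(gamma),
        mu2_per_us2=mu2,
        pdi=float(pdi),
        n_points=int(mask.sum()),
    )


def diameter_from_gamma(fit: CumulantFit, instrument: InstrumentSpec) -> float:
    """Solvodynamic diameter (nm) from a cumulant fit via Stokes–Einstein.

    D_t = Γ/q² (nm²/µs) is converted to m²/s and inverted through
    D_h = k_B·T / (3π·η·D_t).
    """
    if fit.gamma_per_us <= 0:
        raise ValueError("decay rate must be positive")
    q = scattering_vector(instrument)
    d_t = nm2_per_us_to_m2_per_s(fit.gamma_per_us / q**2)
    eta = mpa_s_to_pa_s(instrument.viscosity_mpa_s)
    d_h_m = BOLTZMANN_J_PER_K * instrument.temperature_K / (3.0 * math.pi * eta * d_t)
    return d_h_m * 1e9


def gamma_from_diameter(diameter_nm: float, instrument: InstrumentSpec) -> float:
    """Inverse of :func:`diameter_from_gamma`: decay rate Γ (1/µs) of a
    sphere of the given solvodynamic diameter under this instrument."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    eta = mpa_s_to_pa_s(instrument.viscosity_mpa_s)
    d_t_m2_s = BOLTZMANN_J_PER_K * instrument.temperature_K / (
        3.0 * math.pi * eta * diameter_nm * 1e-9
    )
    q = scattering_vector(instrument)
    return (d_t_m2_s / 1e-12) * q**2
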
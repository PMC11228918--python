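"""Cluster occupancy and growth-kinetics diagnostics.

A prenucleation cluster measured at solvodynamic diameter D is modeled
as a solute-dense sphere, so its occupancy (number of solute molecules
per cluster, NSMC) is

    N(D) = (π/6) D³ / ϑ

with ϑ the solute molecular volume.  The growth-rate series dN/dt,
estimated by simple forward differences, diagnoses the rate-limiting
attachment mechanism: diffusion-limited growth gives dN/dt ∝ r (rate
divided by radius is constant in time), while interface-transfer-limited
growth gives dN/dt ∝ r² (rate divided by surface area is constant).
The diagnostic compares the normalized time trends of the two candidate
ratios and picks the flatter one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SolutionSpec",
    "SizeSeries",
    "MolecularConstants",
    "RegimeThresholds",
    "RegimeResult",
    "nsmc",
    "nsmc_rate",
    "regime_statistics",
    "normalize_saturation",
    "interpolate_size",
    "SALICYLAMIDE",
]


@dataclass(frozen=True)
class SolutionSpec:
    """One (solvent, concentration, temperature) condition."""

    solvent: str
    x_mol_l: float
    x_star_mol_l: float
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.x_mol_l <= 0:
            raise ValueError("solute concentration must be positive")
        if self.x_star_mol_l <= 0:
            raise ValueError("solubility must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def saturation(self) -> float:
        """Degree of saturation S = x/x*."""
        return self.x_mol_l / self.x_star_mol_l


@dataclass(frozen=True)
class MolecularConstants:
    """Solute molecular volume ϑ (nm³/molecule) and molar volume (m³/mol)."""

    molecular_volume_nm3: float
    molar_volume_m3_mol: float

    def __post_init__(self) -> None:
        if self.molecular_volume_nm3 <= 0 or self.molar_volume_m3_mol <= 0:
            raise ValueError("molecular and molar volumes must be positive")


#: Salicylamide: ϑ from the crystal structure, molar volume as used in
#: the CNT driving-force expression.
SALICYLAMIDE = MolecularConstants(
    molecular_volume_nm3=0.169,
    molar_volume_m3_mol=1.01853e-4,
)


@dataclass(frozen=True)
class SizeSeries:
    """Timestamped solvodynamic diameters for one solution condition."""

    solution: SolutionSpec
    times_h: np.ndarray
    diameters_nm: np.ndarray
    sd_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        d = np.asarray(self.diameters_nm, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "diameters_nm", d)
        if self.sd_nm is not None:
            object.__setattr__(self, "sd_nm", np.asarray(self.sd_nm, dtype=float))
        if t.ndim != 1 or d.shape != t.shape:
            raise ValueError("times and diameters must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a size series needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(d > 0):
            raise ValueError("diameters must be positive")


def nsmc(diameter_nm, constants: MolecularConstants):
    """Number of solute molecules per cluster for a solute-dense sphere.

    N = (π/6)·D³/ϑ.  Accepts scalars or arrays; D = 0 gives 0.
    """
    d = np.asarray(diameter_nm, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    out = (np.pi / 6.0) * d**3 / constants.molecular_volume_nm3
    return out if out.ndim else float(out)


def nsmc_rate(series: SizeSeries, constants: MolecularConstants):
    """Forward-difference growth rate ΔN/Δt (molecules/h) at interval midpoints.

    Returns ``(t_mid, rate)`` with n−1 entries for an n-point series.
    """
    t = series.times_h
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate time stamps in series")
    n = nsmc(series.diameters_nm, constants)
    dt = np.diff(t)
    rate = np.diff(n) / dt
    t_mid = 0.5 * (t[:-1] + t[1:])
    return t_mid, rate


@dataclass(frozen=True)
class RegimeThresholds:
    """Decision thresholds for the growth-mechanism diagnostic.

    A candidate ratio is "flat" when |normalized trend| < ``flat_threshold``;
    two candidates are distinguishable when their |trends| differ by at
    least ``margin``.
    """

    flat_threshold: float = 0.25
    margin: float = 0.10


@dataclass(frozen=True)
class RegimeResult:
    """Outcome of the diffusion vs interface-transfer diagnostic.

    ``q_diff`` is (dN/dt)/r and ``q_int`` is (dN/dt)/r², both evaluated
    at interval midpoints; the trend statistics are dimensionless
    (OLS slope × time span / mean level).
    """

    t_mid_h: np.ndarray
    q_diff: np.ndarray
    q_int: np.ndarray
    trend_diff: float
    trend_int: float
    classification: str
    thresholds: RegimeThresholds = field(default_factory=RegimeThresholds)


def _normalized_trend(t: np.ndarray, q: np.ndarray, cov: np.ndarray) -> float:
    """Generalized least-squares slope of q vs t, scaled by span/mean.

    Forward-difference rate series are both heteroscedastic (under
    constant relative size error the absolute rate noise grows with
    cluster size while the increments shrink) and serially
    anticorrelated (adjacent differences share an endpoint), so an
    ordinary slope would be dominated by differencing noise.  GLS with
    the model covariance — known up to a scale factor that cancels —
    removes both effects.  The mean level used for normalization is the
    GLS estimate of a constant model.
    """
    X = np.column_stack([np.ones_like(t), t])
    try:
        ci = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        return float("nan")
    beta = np.linalg.solve(X.T @ ci @ X, X.T @ ci @ q)
    one = np.ones_like(t)
    mean = float(one @ ci @ q) / float(one @ ci @ one)
    if mean == 0.0:
        return float("nan")
    span = float(t[-1] - t[0])
    return float(beta[1]) * span / mean


def regime_statistics(
    series: SizeSeries,
    constants: MolecularConstants,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> RegimeResult:
    """Diagnose whether growth is diffusion- or interface-transfer-limited.

    The growth-rate series is divided by the midpoint radius (diffusion
    candidate) and by the midpoint radius squared (interface candidate);
    whichever ratio is flatter in time — smaller |normalized trend| —
    names the mechanism, provided it is flat in absolute terms and
    clearly flatter than the alternative.
    """
    if series.times_h.size < 4:
        raise ValueError("regime diagnostic needs at least 4 points")
    if not np.all(np.isfinite(series.diameters_nm)):
        raise ValueError("series contains non-finite diameters")

    t_mid, rate = nsmc_rate(series, constants)
    # radius at midpoints by linear interpolation of D, consistent with
    # the forward-difference scheme
    d_mid = 0.5 * (series.diameters_nm[:-1] + series.diameters_nm[1:])
    r_mid = d_mid / 2.0
    q_diff = rate / r_mid
    q_int = rate / r_mid**2

    # rate covariance under the constant-relative-size-error model:
    # Var(N_i) ∝ N_i², and adjacent differences share N_{k+1} with
    # opposite signs (tridiagonal, negative off-diagonal); the unknown
    # scale factor cancels in the GLS fit
    n_vals = nsmc(series.diameters_nm, constants)
    dt = np.diff(series.times_h)
    m = rate.size
    cov_rate = np.zeros((m, m))
    idx = np.arange(m)
    cov_rate[idx, idx] = (n_vals[:-1] ** 2 + n_vals[1:] ** 2) / dt**2
    if m > 1:
        off = -(n_vals[1:-1] ** 2) / (dt[:-1] * dt[1:])
        cov_rate[idx[:-1], idx[1:]] = off
        cov_rate[idx[1:], idx[:-1]] = off

    trend_diff = _normalized_trend(t_mid, q_diff, cov_rate / np.outer(r_mid, r_mid))
    trend_int = _normalized_trend(
        t_mid, q_int, cov_rate / np.outer(r_mid**2, r_mid**2)
    )

    a_d, a_i = abs(trend_diff), abs(trend_int)
    thr, margin = thresholds.flat_threshold, thresholds.margin
    if not (np.isfinite(a_d) and np.isfinite(a_i)):
        classification = "indeterminate"
    elif a_d > thr and a_i > thr:
        classification = "indeterminate"
    elif abs(a_d - a_i) < margin:
        classification = "indeterminate"
    else:
        classification = "diffusion" if a_d < a_i else "interface_transfer"

    return RegimeResult(
        t_mid_h=t_mid,
        q_diff=q_diff,
        q_int=q_int,
        trend_diff=float(trend_diff),
        trend_int=float(trend_int),
        classification=classification,
        thresholds=thresholds,
    )


def normalize_saturation(solution: SolutionSpec) -> float:
    """Degree of saturation S = x/x* (dimensionless)."""
    return solution.saturation


def saturation_label(s: float) -> str:
    if s < 1.0:
        return "undersaturated"
    if s > 1.0:
        return "supersaturated"
    return "saturated"


def interpolate_size(points, target_s: float):
    """Piecewise-linear interpolation of cluster size D_s vs saturation S.

    Parameters
    ----------
    points : sequence of (S, D_s) pairs, any order, S values distinct.
    target_s : saturation at which to evaluate.

    Returns
    -------
    (d_s, extrapolated) : interpolated diameter (nm) and a flag that is
        True when ``target_s`` lies outside the supplied S range (the
        boundary value is linearly extended using the nearest segment).
    """
    pts = sorted((float(s), float(d)) for s, d in points)
    if len(pts) < 2:
        raise ValueError("need at least 2 (S, D_s) points")
    s_arr = np.array([p[0] for p in pts])
    d_arr = np.array([p[1] for p in pts])
    if np.any(np.diff(s_arr) == 0):
        raise ValueError("duplicate S values in interpolation points")

    extrapolated = bool(target_s < s_arr[0] or target_s > s_arr[-1])
    if extrapolated:
        # extend the nearest segment linearly
        if target_s < s_arr[0]:
            s0, s1, d0, d1 = s_arr[0], s_arr[1], d_arr[0], d_arr[1]
        else:
            s0, s1, d0, d1 = s_arr[-2], s_arr[-1], d_arr[-2], d_arr[-1]
        value = d0 + (d1 - d0) * (target_s - s0) / (s1 - s0)
    else:
        value = float(np.interp(target_s, s_arr, d_arr))
    return float(value), extrapolated
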
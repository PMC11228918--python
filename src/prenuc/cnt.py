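"""Classical nucleation theory quantities and descriptive correlations.

The thermodynamic driving force for nucleation at degree of saturation
S = x/x* is ΔG = RT·ln S (J/mol); the Gibbs–Thomson critical nucleus
diameter follows as

    D_c = 4·γ·ϑ_m / (RT·ln S)

with γ the solid–solution interfacial energy and ϑ_m the solute molar
volume.  No activity-coefficient correction is applied.  Correlations
between cluster size, interfacial energy, solvation free energy and IR
peak position are reported descriptively (slope, intercept, Pearson r)
— with three solvents, inferential statistics would be meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GAS_CONSTANT_J_PER_MOL_K, m_to_nm, mj_per_m2_to_j_per_m2

__all__ = [
    "CNTParameters",
    "SolventRecord",
    "driving_force",
    "critical_diameter",
    "linear_correlation",
]


@dataclass(frozen=True)
class CNTParameters:
    """Inputs to the critical-diameter expression.

    gamma_mj_m2 : interfacial energy (mJ/m²).
    molar_volume_m3_mol : solute molar volume ϑ_m (m³/mol).
    temperature_K : absolute temperature.
    gas_constant : J/(mol·K); overridable for exactness tests only.
    """

    gamma_mj_m2: float
    molar_volume_m3_mol: float
    temperature_K: float = 298.15
    gas_constant: float = GAS_CONSTANT_J_PER_MOL_K

    def __post_init__(self) -> None:
        if self.gamma_mj_m2 <= 0:
            raise ValueError("interfacial energy must be positive")
        if self.molar_volume_m3_mol <= 0:
            raise ValueError("molar volume must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class SolventRecord:
    """Per-solvent bundle of measured/derived scalars used in correlations.

    driving_force_2000s_J_mol is the RT·ln S required for a nucleation
    induction time of 2000 s; g_solv_kJ_mol is the continuum-solvation
    free energy of the monomer; carbonyl_peak_cm1 the solution-phase
    C=O stretching wavenumber.
    """

    solvent: str
    gamma_mj_m2: float
    driving_force_2000s_J_mol: float
    g_solv_kJ_mol: float
    carbonyl_peak_cm1: float


def driving_force(s: float, temperature_K: float) -> float:
    """Nucleation driving force RT·ln S in J/mol.

    Negative for undersaturated (S < 1), zero at saturation.
    """
    if s <= 0:
        raise ValueError("saturation ratio must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_J_PER_MOL_K * temperature_K * float(np.log(s))


def critical_diameter(params: CNTParameters, s: float) -> float:
    """Gibbs–Thomson critical nucleus diameter D_c (nm) at saturation S.

    D_c = 4·γ·ϑ_m/(RT·ln S); defined only for S > 1 (a finite critical
    nucleus requires positive driving force).
    """
    if s <= 1.0:
        raise ValueError(
            f"critical diameter requires supersaturation S > 1, got S = {s}"
        )
    gamma_si = mj_per_m2_to_j_per_m2(params.gamma_mj_m2)
    dg = params.gas_constant * params.temperature_K * float(np.log(s))
    d_c_m = 4.0 * gamma_si * params.molar_volume_m3_mol / dg
    return m_to_nm(d_c_m)


def linear_correlation(xs, ys) -> tuple[float, float, float]:
    """Ordinary least-squares line and Pearson r.

    Returns ``(slope, intercept, r)``.  Raises on degenerate
    (constant) x — the line is then undefined.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("xs are constant; correlation undefined")
    slope, intercept = np.polyfit(x, y, 1)
    sy = np.std(y)
    if sy == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return float(slope), float(intercept), r
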
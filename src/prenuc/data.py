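"""Packaged study constants for salicylamide in three organic solvents.

These are the printed inputs of the clustering/nucleation comparison:
per-solvent interfacial energies fitted from earlier induction-time
experiments, the driving force required to reach a 2000-s induction
time, continuum-solvation free energies of the monomer, solution-phase
carbonyl IR peak positions, and the measured 72-h cluster sizes at the
supersaturations studied.  Cluster sizes are experimental data and are
only ever passed through with a ``measured`` provenance flag — the
package recomputes critical nucleus diameters, never measured sizes.

The study temperature is 25 °C (298.15 K).
"""

from __future__ import annotations

from .cnt import SolventRecord
from .growth import SALICYLAMIDE, MolecularConstants

__all__ = [
    "STUDY_TEMPERATURE_K",
    "MOLECULAR_CONSTANTS",
    "SOLVENT_RECORDS",
    "MEASURED_SIZES",
    "INTERPOLATION_TARGET_S",
]

STUDY_TEMPERATURE_K: float = 298.15

MOLECULAR_CONSTANTS: MolecularConstants = SALICYLAMIDE

#: Target degree of saturation at which cluster sizes are interpolated
#: for the like-for-like comparison with the critical nucleus.
INTERPOLATION_TARGET_S: float = 1.05

SOLVENT_RECORDS: dict[str, SolventRecord] = {
    "ethyl acetate": SolventRecord(
        solvent="ethyl acetate",
        gamma_mj_m2=2.67,
        driving_force_2000s_J_mol=1006.0,
        g_solv_kJ_mol=-13.33,
        carbonyl_peak_cm1=1722.0,
    ),
    "acetonitrile": SolventRecord(
        solvent="acetonitrile",
        gamma_mj_m2=3.34,
        driving_force_2000s_J_mol=1495.0,
        g_solv_kJ_mol=-21.36,
        carbonyl_peak_cm1=1713.0,
    ),
    "methanol": SolventRecord(
        solvent="methanol",
        gamma_mj_m2=3.97,
        driving_force_2000s_J_mol=1619.0,
        g_solv_kJ_mol=-22.11,
        carbonyl_peak_cm1=1707.0,
    ),
}

#: Measured 72-h solvodynamic diameters (nm) at each studied
#: supersaturation, per solvent: list of (S, D_s).  Experimental
#: pass-through data; never recomputed.
MEASURED_SIZES: dict[str, list[tuple[float, float]]] = {
    "ethyl acetate": [(1.02, 1439.0), (1.07, 2807.0)],
    "acetonitrile": [(1.03, 1387.0), (1.11, 2101.0)],
    "methanol": [(1.03, 955.0), (1.09, 1745.0)],
}
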
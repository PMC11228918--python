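"""Non-bonded pair interaction energies (Coulomb + Lennard-Jones).

Plain distance-cutoff electrostatics — no Ewald/PME — plus 12-6
Lennard-Jones with Lorentz–Berthelot combination, summed over
inter-group atom pairs and normalized per group-a molecule.  This is a
diagnostic energy for comparing solute–solvent affinity between
configurations, not a force-field evaluation.
"""

from __future__ import annotations

import numpy as np

from ..constants import COULOMB_KJ_NM_PER_MOL_E2
from .geometry import min_image_distance
from .trajectory import Frame, Topology

__all__ = ["pair_interaction_energy"]


def _group_atoms(topology: Topology, group) -> tuple[np.ndarray, np.ndarray]:
    """(atom indices, molecule ids) of a group given by type or id list."""
    if isinstance(group, str):
        mols = topology.molecules_of_type(group)
    else:
        mols = np.asarray(group, dtype=int)
    atoms = np.nonzero(np.isin(topology.molecule_id, mols))[0]
    return atoms, mols


def pair_interaction_energy(
    frame: Frame,
    topology: Topology,
    group_a="solute",
    group_b="solvent",
    cutoff_nm: float = 1.2,
) -> float:
    """Inter-group non-bonded energy in kJ/mol per group-a molecule.

    E = Σ_pairs [ f·q_i·q_j/r + 4ε_ij((σ_ij/r)¹² − (σ_ij/r)⁶) ] over
    atom pairs with minimum-image distance ≤ cutoff, excluding
    intramolecular pairs; for identical groups each pair is counted
    once.  Raises when any involved atom lacks charge or LJ parameters.
    """
    atoms_a, mols_a = _group_atoms(topology, group_a)
    atoms_b, mols_b = _group_atoms(topology, group_b)
    if atoms_a.size == 0 or atoms_b.size == 0:
        raise ValueError("empty atom group")
    for atoms in (atoms_a, atoms_b):
        bad = atoms[
            ~np.isfinite(topology.charge_e[atoms])
            | ~np.isfinite(topology.lj_epsilon_kj_mol[atoms])
            | ~np.isfinite(topology.lj_sigma_nm[atoms])
        ]
        if bad.size:
            raise ValueError(f"atoms missing charge/LJ parameters: {bad.tolist()}")

    same = np.array_equal(atoms_a, atoms_b)
    xyz = frame.coords_nm
    r = min_image_distance(xyz[atoms_a][:, None, :], xyz[atoms_b][None, :, :], frame.box_nm)

    mol_i = topology.molecule_id[atoms_a][:, None]
    mol_j = topology.molecule_id[atoms_b][None, :]
    mask = (r <= cutoff_nm) & (mol_i != mol_j)
    if same:
        mask &= np.arange(len(atoms_a))[:, None] < np.arange(len(atoms_b))[None, :]

    qi = topology.charge_e[atoms_a][:, None]
    qj = topology.charge_e[atoms_b][None, :]
    eps = np.sqrt(
        topology.lj_epsilon_kj_mol[atoms_a][:, None]
        * topology.lj_epsilon_kj_mol[atoms_b][None, :]
    )
    sig = 0.5 * (
        topology.lj_sigma_nm[atoms_a][:, None] + topology.lj_sigma_nm[atoms_b][None, :]
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        coul = COULOMB_KJ_NM_PER_MOL_E2 * qi * qj / r
        sr6 = (sig / r) ** 6
        lj = 4.0 * eps * (sr6 * sr6 - sr6)
        e = np.where(mask, coul + lj, 0.0)
    return float(e.sum()) / len(mols_a)
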
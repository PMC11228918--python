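"""Shared builders for synthetic topologies and frames."""

from __future__ import annotations

import numpy as np
import pytest

from prenuc.md import Frame, Topology
from prenuc.synth import solute_template


def single_site_topology(n: int, kinds=None) -> Topology:
    """n single-atom molecules; ``kinds`` optionally labels each molecule."""
    if kinds is None:
        kinds = ["solute"] * n
    return Topology(
        element=np.array(["X"] * n, dtype=object),
        mass_amu=np.ones(n),
        charge_e=np.zeros(n),
        lj_epsilon_kj_mol=np.full(n, 0.1),
        lj_sigma_nm=np.full(n, 0.3),
        molecule_id=np.arange(n),
        molecule_type=np.array(kinds, dtype=object),
        is_donor=np.zeros(n, dtype=bool),
        is_acceptor=np.zeros(n, dtype=bool),
        donor_id=np.full(n, -1, dtype=int),
        ring_pos=np.full(n, -1, dtype=int),
    )


def template_topology(n_molecules: int) -> Topology:
    """n copies of the 12-atom solute template, all flagged solute."""
    tpl = solute_template()
    tn = len(tpl["elements"])

    def rep(a):
        return np.tile(a, n_molecules)

    donor_id = np.concatenate(
        [
            np.array(
                [tpl["donor_of_h"].get(k, -1) + (m * tn if k in tpl["donor_of_h"] else 0)
                 for k in range(tn)]
            )
            for m in range(n_molecules)
        ]
    )
    return Topology(
        element=np.array(list(tpl["elements"]) * n_molecules, dtype=object),
        mass_amu=rep(tpl["masses"]),
        charge_e=rep(tpl["charges"]),
        lj_epsilon_kj_mol=rep(tpl["eps"]),
        lj_sigma_nm=rep(tpl["sigma"]),
        molecule_id=np.repeat(np.arange(n_molecules), tn),
        molecule_type=np.array(["solute"] * (n_molecules * tn), dtype=object),
        is_donor=rep(tpl["is_donor"]),
        is_acceptor=rep(tpl["is_acceptor"]),
        donor_id=donor_id,
        ring_pos=rep(tpl["ring_pos"]),
    )


def place_template_molecules(transforms, box, time_ps=0.0) -> Frame:
    """Frame with one template copy per (rotation, translation) transform."""
    tpl = solute_template()
    blocks = []
    for rot, trans in transforms:
        ring_centered = tpl["coords"] - tpl["coords"][:6].mean(axis=0)
        blocks.append(ring_centered @ np.asarray(rot).T + np.asarray(trans))
    return Frame(time_ps=time_ps, box_nm=np.asarray(box, float), coords_nm=np.vstack(blocks))


def rotation_about(axis: str, angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
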
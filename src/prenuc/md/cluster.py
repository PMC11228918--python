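"""Distance-cutoff (single-linkage) cluster detection for solute molecules.

Two solute molecules belong to the same cluster when the minimum
distance over their linkage atoms — heavy atoms by default — is within
the cutoff (3.5 Å by default), and clusters are the transitive closure
of that relation.  Labels are deterministic: each cluster is named by
its smallest member molecule id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import all_molecule_coms, wrap_coords
from .trajectory import Frame, Topology

__all__ = ["ClusterCriteria", "ClusterResult", "cluster_frame", "cluster_count_series"]


@dataclass(frozen=True)
class ClusterCriteria:
    """Connectivity rule for cluster detection.

    cutoff_nm : contact distance threshold (inclusive).
    linkage : which sites define the inter-molecule distance —
        ``heavy`` (non-hydrogen atoms, default), ``any`` (all atoms) or
        ``com`` (mass-weighted centers of mass).
    min_size : smallest cluster size to report (smaller ones are still
        present in the partition; this only filters the size listing).
    """

    cutoff_nm: float = 0.35
    linkage: str = "heavy"
    min_size: int = 1

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")
        if self.linkage not in ("heavy", "any", "com"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass
class ClusterResult:
    """Partition of the solute molecules of one frame.

    labels maps each solute molecule id to its cluster label (the
    smallest molecule id in the cluster); sizes lists cluster sizes in
    ascending label order.
    """

    molecule_ids: np.ndarray
    labels: np.ndarray
    sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for mol, lab in zip(self.molecule_ids, self.labels):
            out.setdefault(int(lab), []).append(int(mol))
        return out


def _linkage_sites(frame: Frame, topology: Topology, mols: np.ndarray, criteria: ClusterCriteria):
    """(site coordinates, per-site molecule index) for the linkage rule."""
    if criteria.linkage == "com":
        coords = all_molecule_coms(frame.coords_nm, topology, frame.box_nm, mols)
        owner = np.arange(len(mols))
        return coords, owner
    keep = np.isin(topology.molecule_id, mols)
    if criteria.linkage == "heavy":
        keep &= topology.heavy_mask
    atom_idx = np.nonzero(keep)[0]
    mol_index = {m: i for i, m in enumerate(mols)}
    owner = np.array([mol_index[m] for m in topology.molecule_id[atom_idx]])
    return frame.coords_nm[atom_idx], owner


def cluster_frame(
    frame: Frame, topology: Topology, criteria: ClusterCriteria = ClusterCriteria()
) -> ClusterResult:
    """Single-linkage partition of solute molecules in one frame.

    Contacts are found with a periodic k-d tree on the linkage sites;
    connected components of the molecule contact graph form the
    clusters.  The boundary is inclusive: a pair exactly at the cutoff
    is connected.
    """
    mols = topology.molecules_of_type("solute")
    if mols.size == 0:
        raise ValueError("no solute molecules in topology")
    sites, owner = _linkage_sites(frame, topology, mols, criteria)
    wrapped = wrap_coords(sites, frame.box_nm)
    # guard against coordinates landing exactly on the upper boundary
    wrapped = np.where(wrapped >= frame.box_nm, 0.0, wrapped)
    tree = cKDTree(wrapped, boxsize=frame.box_nm)
    pairs = tree.query_pairs(r=criteria.cutoff_nm, output_type="ndarray")

    m = len(mols)
    if len(pairs):
        mi = owner[pairs[:, 0]]
        mj = owner[pairs[:, 1]]
        off_diag = mi != mj
        mi, mj = mi[off_diag], mj[off_diag]
        graph = coo_matrix(
            (np.ones(len(mi)), (mi, mj)), shape=(m, m)
        )
    else:
        graph = coo_matrix((m, m))
    _, comp = connected_components(graph, directed=False)

    # deterministic labels: smallest member molecule id per component
    labels = np.empty(m, dtype=int)
    for c in np.unique(comp):
        members = mols[comp == c]
        labels[comp == c] = members.min()
    sizes = [int((labels == lab).sum()) for lab in np.unique(labels)]
    sizes = [s for s in sizes if s >= criteria.min_size]
    return ClusterResult(molecule_ids=mols.copy(), labels=labels, sizes=sizes)


def cluster_count_series(
    frames,
    topology: Topology,
    criteria: ClusterCriteria = ClusterCriteria(),
):
    """Cluster count vs time, with a second-order polynomial fit.

    Returns ``(times_ps, counts, fit_coeffs)`` where ``fit_coeffs`` are
    the (c2, c1, c0) of a least-squares quadratic in time, or ``None``
    when fewer than 3 frames are available (the fit is skipped, not
    fabricated).
    """
    times = np.array([f.time_ps for f in frames], dtype=float)
    counts = np.array(
        [cluster_frame(f, topology, criteria).n_clusters for f in frames], dtype=float
    )
    if len(frames) >= 3:
        fit = tuple(np.polyfit(times, counts, 2))
    else:
        fit = None
    return times, counts, fit
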
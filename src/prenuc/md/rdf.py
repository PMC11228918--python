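"""Center-of-mass radial distribution functions in periodic boxes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import all_molecule_coms, min_image_distance
from .trajectory import Topology

__all__ = ["RDFResult", "rdf"]


@dataclass
class RDFResult:
    """g(r) on a uniform radial grid.

    ``bin_centers_nm``/``g`` define the curve; ``counts`` holds the raw
    pair histogram (count conservation: its sum equals the number of
    pair distances within r_max); ``reference_density`` is the mean
    number density of group-b molecules used for normalization.
    """

    bin_centers_nm: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    r_max_nm: float
    bin_width_nm: float
    reference_density: float


def _resolve_group(topology: Topology, group) -> np.ndarray:
    if isinstance(group, str):
        mols = topology.molecules_of_type(group)
        if mols.size == 0:
            raise ValueError(f"no molecules of type {group!r}")
        return mols
    return np.asarray(group, dtype=int)


def rdf(
    frames,
    topology: Topology,
    group_a="solute",
    group_b="solute",
    r_max_nm: float = 3.0,
    bin_width_nm: float = 0.02,
) -> RDFResult:
    """COM-based pair correlation g(r) between two molecule groups.

    Each molecule is collapsed to its mass-weighted center of mass; the
    histogram of minimum-image COM distances is normalized by shell
    volume, frame count and the mean number density of group b, so an
    ideal (uncorrelated uniform) system gives g = 1.  For identical
    groups each pair is counted once and the ideal pair density uses
    N_b − 1.

    Raises if ``r_max_nm`` exceeds half the smallest box edge in any
    frame — beyond that the minimum-image histogram is biased, so the
    condition is an error rather than a silent truncation.
    """
    mols_a = _resolve_group(topology, group_a)
    mols_b = _resolve_group(topology, group_b)
    same = np.array_equal(mols_a, mols_b)

    for k, f in enumerate(frames):
        if r_max_nm > 0.5 * float(np.min(f.box_nm)):
            raise ValueError(
                f"r_max {r_max_nm} nm exceeds half the smallest box edge "
                f"({0.5 * float(np.min(f.box_nm))} nm) in frame {k}"
            )

    n_bins = int(round(r_max_nm / bin_width_nm))
    edges = np.linspace(0.0, n_bins * bin_width_nm, n_bins + 1)
    counts = np.zeros(n_bins)
    volumes = []

    for f in frames:
        coms_a = all_molecule_coms(f.coords_nm, topology, f.box_nm, mols_a)
        coms_b = coms_a if same else all_molecule_coms(
            f.coords_nm, topology, f.box_nm, mols_b
        )
        d = min_image_distance(coms_a[:, None, :], coms_b[None, :, :], f.box_nm)
        if same:
            iu = np.triu_indices(len(mols_a), k=1)
            dists = d[iu]
        else:
            dists = d.ravel()
        counts += np.histogram(dists, bins=edges)[0]
        volumes.append(float(np.prod(f.box_nm)))

    mean_v = float(np.mean(volumes))
    n_a, n_b = len(mols_a), len(mols_b)
    rho_ref = ((n_b - 1) if same else n_b) / mean_v
    pairs_per_frame = n_a * ((n_b - 1) if same else n_b) / (2.0 if same else 1.0)
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # ideal expected count per shell per frame: (counted pairs) * shell_vol/V
    g = counts / (len(frames) * pairs_per_frame * shell_vol / mean_v)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(
        bin_centers_nm=centers,
        g=g,
        counts=counts,
        r_max_nm=r_max_nm,
        bin_width_nm=bin_width_nm,
        reference_density=rho_ref,
    )
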
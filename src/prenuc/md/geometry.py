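"""Minimum-image geometry for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np

__all__ = [
    "min_image_displacement",
    "min_image_distance",
    "wrap_coords",
    "molecule_com",
]


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive orthorhombic edge lengths")
    return box


def min_image_displacement(a, b, box):
    """Minimum-image displacement vector(s) b − a; broadcasts over leading axes."""
    box = _check_box(box)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a, b, box):
    """Euclidean distance under the minimum-image convention (nm)."""
    d = min_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_coords(coords, box):
    """Wrap coordinates into the primary cell [0, L) per axis."""
    box = _check_box(box)
    return np.mod(coords, box)


def molecule_com(coords: np.ndarray, masses: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Mass-weighted center of mass of one molecule, PBC-aware.

    The molecule is unwrapped relative to its first atom via minimum
    image before averaging, then the COM is wrapped back into the box —
    correct for molecules smaller than half the box edge, which is the
    operating regime of every operator here.
    """
    box = _check_box(box)
    ref = coords[0]
    unwrapped = ref + min_image_displacement(ref, coords, box)
    com = np.average(unwrapped, axis=0, weights=masses)
    return np.mod(com, box)


def all_molecule_coms(frame_coords, topology, box, molecule_ids=None) -> np.ndarray:
    """Centers of mass for a set of molecules (default: all), shape (m, 3)."""
    if molecule_ids is None:
        molecule_ids = np.arange(topology.n_molecules)
    out = np.empty((len(molecule_ids), 3))
    for k, mol in enumerate(molecule_ids):
        atoms = topology.molecule_atoms(mol)
        out[k] = molecule_com(frame_coords[atoms], topology.mass_amu[atoms], box)
    return out
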
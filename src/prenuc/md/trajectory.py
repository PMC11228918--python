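"""Periodic-box trajectory and topology containers with plain-text I/O.

Trajectories are stored as extended XYZ: a standard XYZ block per frame
whose comment line carries the orthorhombic box and the frame time, e.g.

    12
    box 5.0 5.0 5.0 time 20.0
    C 1.234 2.345 3.456
    ...

Coordinates and box edges are in nm, times in ps.  Topologies are flat
per-atom CSV tables carrying masses, partial charges, Lennard-Jones
parameters, molecule assignment, donor/acceptor roles and ring
membership — everything the analysis operators need, nothing a force
field would also need (no bonded terms).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Frame",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_topology_csv",
    "write_topology_csv",
]

TOPOLOGY_COLUMNS = [
    "atom_id",
    "element",
    "mass_amu",
    "charge_e",
    "lj_epsilon_kj_mol",
    "lj_sigma_nm",
    "molecule_id",
    "molecule_type",
    "is_donor",
    "is_acceptor",
    "donor_id",
    "ring_pos",
]


@dataclass
class Topology:
    """Per-atom static properties plus derived per-molecule structure.

    ``donor_id`` is, for a hydrogen participating in donation, the atom
    id of its donor heavy atom (−1 otherwise).  ``ring_pos`` is the
    0–5 position of the atom in its molecule's aromatic ring (−1 for
    non-ring atoms).  ``molecule_type`` is ``solute`` or ``solvent``.
    """

    element: np.ndarray
    mass_amu: np.ndarray
    charge_e: np.ndarray
    lj_epsilon_kj_mol: np.ndarray
    lj_sigma_nm: np.ndarray
    molecule_id: np.ndarray
    molecule_type: np.ndarray
    is_donor: np.ndarray
    is_acceptor: np.ndarray
    donor_id: np.ndarray
    ring_pos: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.element)
        for name in (
            "mass_amu",
            "charge_e",
            "lj_epsilon_kj_mol",
            "lj_sigma_nm",
            "molecule_id",
            "molecule_type",
            "is_donor",
            "is_acceptor",
            "donor_id",
            "ring_pos",
        ):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"topology field {name} has wrong length")
        self.element = np.asarray(self.element, dtype=object)
        mols = np.unique(self.molecule_id)
        if not np.array_equal(mols, np.arange(len(mols))):
            raise ValueError("molecule ids must be contiguous starting at 0")
        # ring lists must have exactly 6 atoms per molecule that has any
        for mol in mols:
            sel = (self.molecule_id == mol) & (self.ring_pos >= 0)
            k = int(sel.sum())
            if k not in (0, 6):
                raise ValueError(f"molecule {mol} has {k} ring atoms; need 0 or 6")
        # every donor hydrogen must point at a flagged donor heavy atom
        for h in np.nonzero(self.donor_id >= 0)[0]:
            d = int(self.donor_id[h])
            if not self.is_donor[d]:
                raise ValueError(f"hydrogen {h} references atom {d} which is not a donor")
            if self.molecule_id[h] != self.molecule_id[d]:
                raise ValueError(f"donor hydrogen {h} in different molecule than donor {d}")

    # ---- derived views ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.element)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_id.max()) + 1

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def molecule_atoms(self, mol: int) -> np.ndarray:
        return np.nonzero(self.molecule_id == mol)[0]

    def molecules_of_type(self, kind: str) -> np.ndarray:
        """Molecule ids whose type equals ``kind`` ('solute'/'solvent')."""
        ids = []
        for mol in range(self.n_molecules):
            atoms = self.molecule_atoms(mol)
            if self.molecule_type[atoms[0]] == kind:
                ids.append(mol)
        return np.array(ids, dtype=int)

    def ring_atoms(self, mol: int) -> np.ndarray | None:
        """Ordered ids of the 6 ring atoms of a molecule, or None."""
        sel = np.nonzero((self.molecule_id == mol) & (self.ring_pos >= 0))[0]
        if sel.size == 0:
            return None
        return sel[np.argsort(self.ring_pos[sel])]

    def donor_pairs(self) -> list[tuple[int, int]]:
        """(donor heavy atom, hydrogen) pairs."""
        hs = np.nonzero(self.donor_id >= 0)[0]
        return [(int(self.donor_id[h]), int(h)) for h in hs]

    def acceptor_atoms(self) -> np.ndarray:
        return np.nonzero(self.is_acceptor.astype(bool))[0]


@dataclass
class Frame:
    """One snapshot: time (ps), orthorhombic box edges (nm), coordinates (nm)."""

    time_ps: float
    box_nm: np.ndarray
    coords_nm: np.ndarray

    def __post_init__(self) -> None:
        self.box_nm = np.asarray(self.box_nm, dtype=float)
        self.coords_nm = np.asarray(self.coords_nm, dtype=float)
        if self.box_nm.shape != (3,):
            raise ValueError("box must be three orthorhombic edge lengths")
        if np.any(self.box_nm <= 0):
            raise ValueError("box edges must be positive")
        if self.coords_nm.ndim != 2 or self.coords_nm.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")


class TrajectoryParseError(ValueError):
    pass


def _parse_comment(line: str, frame_index: int) -> tuple[np.ndarray, float]:
    tokens = line.split()
    try:
        i = tokens.index("box")
        box = np.array([float(tokens[i + 1]), float(tokens[i + 2]), float(tokens[i + 3])])
        j = tokens.index("time")
        t = float(tokens[j + 1])
    except (ValueError, IndexError) as exc:
        raise TrajectoryParseError(
            f"frame {frame_index}: malformed comment line {line!r}; "
            "expected 'box Lx Ly Lz time t_ps'"
        ) from exc
    return box, t


def read_xyz_trajectory(path, topology: Topology) -> list[Frame]:
    """Read an extended-XYZ trajectory, validating against the topology.

    Raises :class:`TrajectoryParseError` naming the offending frame on
    atom-count mismatch, malformed box line, or truncation.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"frame {index}: expected atom count, got {lines[pos]!r}"
            ) from exc
        if n != topology.n_atoms:
            raise TrajectoryParseError(
                f"frame {index}: atom count {n} != topology count {topology.n_atoms}"
            )
        if pos + 1 + n >= len(lines) + 1 and pos + 1 + n > len(lines):
            raise TrajectoryParseError(f"frame {index}: truncated (expected {n} atoms)")
        if pos + 1 >= len(lines):
            raise TrajectoryParseError(f"frame {index}: missing comment line")
        box, t = _parse_comment(lines[pos + 1], index)
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise TrajectoryParseError(f"frame {index}: truncated (expected {n} atoms)")
        coords = np.empty((n, 3))
        for k, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise TrajectoryParseError(f"frame {index}: bad atom line {row!r}")
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(time_ps=t, box_nm=box, coords_nm=coords))
        pos += 2 + n
        index += 1
    return frames


def write_xyz_trajectory(path, frames, topology: Topology) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{topology.n_atoms}\n")
            bx, by, bz = frame.box_nm
            fh.write(f"box {bx:.6f} {by:.6f} {bz:.6f} time {frame.time_ps:.4f}\n")
            for el, xyz in zip(topology.element, frame.coords_nm):
                fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def read_topology_csv(path) -> Topology:
    df = pd.read_csv(path)
    missing = [c for c in TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"topology CSV missing columns: {missing}")
    df = df.sort_values("atom_id").reset_index(drop=True)
    if not np.array_equal(df["atom_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("atom_id must be 0..n-1")
    return Topology(
        element=df["element"].to_numpy(dtype=object),
        mass_amu=df["mass_amu"].to_numpy(dtype=float),
        charge_e=df["charge_e"].to_numpy(dtype=float),
        lj_epsilon_kj_mol=df["lj_epsilon_kj_mol"].to_numpy(dtype=float),
        lj_sigma_nm=df["lj_sigma_nm"].to_numpy(dtype=float),
        molecule_id=df["molecule_id"].to_numpy(dtype=int),
        molecule_type=df["molecule_type"].to_numpy(dtype=object),
        is_donor=df["is_donor"].to_numpy(dtype=bool),
        is_acceptor=df["is_acceptor"].to_numpy(dtype=bool),
        donor_id=df["donor_id"].to_numpy(dtype=int),
        ring_pos=df["ring_pos"].to_numpy(dtype=int),
    )


def write_topology_csv(path, topology: Topology) -> None:
    df = pd.DataFrame(
        {
            "atom_id": np.arange(topology.n_atoms),
            "element": topology.element,
            "mass_amu": topology.mass_amu,
            "charge_e": topology.charge_e,
            "lj_epsilon_kj_mol": topology.lj_epsilon_kj_mol,
            "lj_sigma_nm": topology.lj_sigma_nm,
            "molecule_id": topology.molecule_id,
            "molecule_type": topology.molecule_type,
            "is_donor": topology.is_donor.astype(int),
            "is_acceptor": topology.is_acceptor.astype(int),
            "donor_id": topology.donor_id,
            "ring_pos": topology.ring_pos,
        }
    )
    df.to_csv(path, index=False)
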
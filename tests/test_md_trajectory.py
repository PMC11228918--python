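"""Extended-XYZ I/O, topology validation, minimum-image geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prenuc.md import (
    Frame,
    TrajectoryParseError,
    min_image_distance,
    molecule_com,
    read_topology_csv,
    read_xyz_trajectory,
    write_topology_csv,
    write_xyz_trajectory,
)
from prenuc.md.trajectory import Topology

from conftest import single_site_topology, template_topology


@pytest.fixture
def tiny_topology():
    return single_site_topology(3)


def write_frames_text(path, text):
    path.write_text(text)
    return path


class TestXyzIO:
    def test_two_frame_fixture_roundtrip(self, tmp_path, tiny_topology):
        text = (
            "3\nbox 5.0 5.0 5.0 time 0.0\n"
            "X 1.0 2.0 3.0\nX 4.0 4.5 0.25\nX 0.125 0.5 2.75\n"
            "3\nbox 5.0 5.0 5.0 time 20.0\n"
            "X 1.1 2.1 3.1\nX 4.1 4.6 0.35\nX 0.225 0.6 2.85\n"
        )
        p = write_frames_text(tmp_path / "t.xyz", text)
        frames = read_xyz_trajectory(p, tiny_topology)
        assert len(frames) == 2
        assert frames[0].coords_nm[1, 2] == 0.25  # bit-exact decimal
        assert frames[1].time_ps == 20.0
        assert np.array_equal(frames[0].box_nm, [5.0, 5.0, 5.0])

    def test_writer_reader_roundtrip(self, tmp_path, rng, tiny_topology):
        frames = [
            Frame(time_ps=20.0 * i, box_nm=np.array([6.0, 7.0, 8.0]),
                  coords_nm=rng.uniform(0, 6, (3, 3)))
            for i in range(3)
        ]
        path = tmp_path / "rt.xyz"
        write_xyz_trajectory(path, frames, tiny_topology)
        back = read_xyz_trajectory(path, tiny_topology)
        for a, b in zip(frames, back):
            assert np.allclose(a.coords_nm, b.coords_nm, atol=1e-6)
            assert a.time_ps == b.time_ps

    def test_truncated_final_frame_names_frame(self, tmp_path, tiny_topology):
        text = (
            "3\nbox 5 5 5 time 0\nX 1 1 1\nX 2 2 2\nX 3 3 3\n"
            "3\nbox 5 5 5 time 20\nX 1 1 1\nX 2 2 2\n"
        )
        p = write_frames_text(tmp_path / "bad.xyz", text)
        with pytest.raises(TrajectoryParseError, match="frame 1"):
            read_xyz_trajectory(p, tiny_topology)

    def test_count_mismatch_rejected(self, tmp_path, tiny_topology):
        p = write_frames_text(tmp_path / "bad.xyz", "2\nbox 5 5 5 time 0\nX 1 1 1\nX 2 2 2\n")
        with pytest.raises(TrajectoryParseError, match="atom count"):
            read_xyz_trajectory(p, tiny_topology)

    def test_malformed_box_rejected(self, tmp_path, tiny_topology):
        p = write_frames_text(
            tmp_path / "bad.xyz", "3\nno box here\nX 1 1 1\nX 2 2 2\nX 3 3 3\n"
        )
        with pytest.raises(TrajectoryParseError, match="frame 0"):
            read_xyz_trajectory(p, tiny_topology)


class TestTopology:
    def test_csv_roundtrip(self, tmp_path):
        topo = template_topology(2)
        path = tmp_path / "topo.csv"
        write_topology_csv(path, topo)
        back = read_topology_csv(path)
        assert back.n_atoms == topo.n_atoms
        assert np.array_equal(back.molecule_id, topo.molecule_id)
        assert np.allclose(back.charge_e, topo.charge_e)
        assert back.donor_pairs() == topo.donor_pairs()
        assert np.array_equal(back.ring_atoms(1), topo.ring_atoms(1))

    def test_ring_must_have_six_atoms(self):
        n = 5
        with pytest.raises(ValueError, match="ring"):
            Topology(
                element=np.array(["C"] * n, dtype=object),
                mass_amu=np.ones(n),
                charge_e=np.zeros(n),
                lj_epsilon_kj_mol=np.ones(n),
                lj_sigma_nm=np.ones(n),
                molecule_id=np.zeros(n, dtype=int),
                molecule_type=np.array(["solute"] * n, dtype=object),
                is_donor=np.zeros(n, dtype=bool),
                is_acceptor=np.zeros(n, dtype=bool),
                donor_id=np.full(n, -1),
                ring_pos=np.array([0, 1, 2, 3, 4]),  # only 5 ring atoms
            )

    def test_donor_hydrogen_must_reference_donor(self):
        n = 2
        with pytest.raises(ValueError, match="donor"):
            Topology(
                element=np.array(["O", "H"], dtype=object),
                mass_amu=np.ones(n),
                charge_e=np.zeros(n),
                lj_epsilon_kj_mol=np.ones(n),
                lj_sigma_nm=np.ones(n),
                molecule_id=np.zeros(n, dtype=int),
                molecule_type=np.array(["solute"] * n, dtype=object),
                is_donor=np.zeros(n, dtype=bool),  # O not flagged
                is_acceptor=np.zeros(n, dtype=bool),
                donor_id=np.array([-1, 0]),
                ring_pos=np.full(n, -1),
            )


def brute_force_min_image(a, b, box):
    """27-image enumeration oracle."""
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * box
                best = min(best, float(np.linalg.norm(b + shift - a)))
    return best


class TestMinImage:
    def test_zero_distance(self):
        box = np.array([5.0, 5.0, 5.0])
        a = np.array([1.0, 2.0, 3.0])
        assert min_image_distance(a, a, box) == 0.0

    def test_wraparound(self):
        box = np.array([10.0, 10.0, 10.0])
        a = np.array([0.5, 5.0, 5.0])
        b = np.array([9.5, 5.0, 5.0])
        assert min_image_distance(a, b, box) == pytest.approx(1.0)

    def test_against_image_enumeration(self, rng):
        box = np.array([4.0, 7.0, 11.0])
        for _ in range(1000):
            a = rng.uniform(0, box)
            b = rng.uniform(0, box)
            assert min_image_distance(a, b, box) == pytest.approx(
                brute_force_min_image(a, b, box), rel=1e-10
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_bounded_by_half_diagonal(self, seed):
        r = np.random.default_rng(seed)
        box = r.uniform(2, 20, 3)
        d = min_image_distance(r.uniform(-30, 30, 3), r.uniform(-30, 30, 3), box)
        assert d <= float(np.linalg.norm(box / 2)) + 1e-9


class TestMoleculeCom:
    def test_boundary_spanning_molecule(self):
        box = np.array([10.0, 10.0, 10.0])
        coords = np.array([[9.8, 5.0, 5.0], [0.2, 5.0, 5.0]])  # spans the x face
        com = molecule_com(coords, np.array([1.0, 1.0]), box)
        # midpoint through the boundary, wrapped into the cell
        assert com[0] == pytest.approx(0.0, abs=1e-9) or com[0] == pytest.approx(10.0, abs=1e-9)

    def test_mass_weighting(self):
        box = np.array([10.0, 10.0, 10.0])
        coords = np.array([[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        com = molecule_com(coords, np.array([3.0, 1.0]), box)
        assert com[0] == pytest.approx(1.25)
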
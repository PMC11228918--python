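"""Single-linkage cluster detection against brute-force transitive closure."""

import numpy as np
import pytest

from prenuc.md import ClusterCriteria, Frame, cluster_count_series, cluster_frame
from prenuc.synth import PlantedConfigSpec, gen_planted_config

from conftest import single_site_topology


def brute_force_partition(coords, mol_of_atom, heavy, box, cutoff):
    """Transitive closure via explicit image enumeration and BFS (oracle)."""

    def dist(a, b):
        best = np.inf
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    shift = np.array([i, j, k]) * box
                    best = min(best, float(np.linalg.norm(b + shift - a)))
        return best

    mols = sorted(set(mol_of_atom))
    adj = {m: set() for m in mols}
    for mi in mols:
        for mj in mols:
            if mj <= mi:
                continue
            ai = [k for k, m in enumerate(mol_of_atom) if m == mi and heavy[k]]
            aj = [k for k, m in enumerate(mol_of_atom) if m == mj and heavy[k]]
            if any(dist(coords[a], coords[b]) <= cutoff for a in ai for b in aj):
                adj[mi].add(mj)
                adj[mj].add(mi)
    seen, parts = set(), []
    for m in mols:
        if m in seen:
            continue
        stack, comp = [m], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        parts.append(frozenset(comp))
    return set(parts)


def partition_from_result(result):
    return {frozenset(v) for v in result.members().values()}


class TestClusterFrame:
    def test_all_separated_gives_singletons(self):
        n = 8
        topo = single_site_topology(n)
        coords = np.column_stack([np.arange(n) * 2.0 + 1.0, np.ones(n), np.ones(n)])
        frame = Frame(0.0, np.array([20.0, 20.0, 20.0]), coords)
        res = cluster_frame(frame, topo, ClusterCriteria(cutoff_nm=0.35))
        assert res.n_clusters == n
        assert res.sizes == [1] * n

    def test_planted_plan_recovered(self):
        system = gen_planted_config(PlantedConfigSpec(cluster_sizes=(5, 3, 1), seed=11))
        res = cluster_frame(system.frames[0], system.topology)
        assert sorted(res.sizes) == sorted(system.truth["cluster_sizes"])
        assert partition_from_result(res) == {
            frozenset(m) for m in system.truth["memberships"]
        }

    def test_matches_bruteforce_on_random_frames(self, rng):
        # 10 random 12-molecule frames vs the transitive-closure oracle
        n = 12
        topo = single_site_topology(n)
        box = np.array([3.0, 3.0, 3.0])
        cutoff = 0.6
        for _ in range(10):
            coords = rng.uniform(0, 3.0, (n, 3))
            frame = Frame(0.0, box, coords)
            res = cluster_frame(frame, topo, ClusterCriteria(cutoff_nm=cutoff, linkage="any"))
            oracle = brute_force_partition(
                coords, list(range(n)), [True] * n, box, cutoff
            )
            assert partition_from_result(res) == oracle

    def test_sizes_conserve_molecule_count(self, rng):
        n = 30
        topo = single_site_topology(n)
        frame = Frame(0.0, np.array([4.0, 4.0, 4.0]), rng.uniform(0, 4, (n, 3)))
        res = cluster_frame(frame, topo, ClusterCriteria(cutoff_nm=0.5))
        assert sum(res.sizes) == n

    def test_translation_and_wrap_invariance(self, rng):
        n = 15
        topo = single_site_topology(n)
        box = np.array([5.0, 5.0, 5.0])
        coords = rng.uniform(0, 5, (n, 3))
        res1 = cluster_frame(Frame(0.0, box, coords), topo, ClusterCriteria(0.7))
        shifted = np.mod(coords + np.array([2.3, -1.1, 4.0]), box)
        res2 = cluster_frame(Frame(0.0, box, shifted), topo, ClusterCriteria(0.7))
        assert partition_from_result(res1) == partition_from_result(res2)

    def test_cluster_spanning_periodic_boundary(self):
        system = gen_planted_config(
            PlantedConfigSpec(
                cluster_sizes=(6,),
                box_nm=(8.0, 8.0, 8.0),
                first_cluster_center_nm=(0.05, 4.0, 4.0),  # straddles the x face
                seed=2,
            )
        )
        coords = system.frames[0].coords_nm
        assert coords[:, 0].max() > 6.0 and coords[:, 0].min() < 2.0  # actually wrapped
        res = cluster_frame(system.frames[0], system.topology)
        assert res.n_clusters == 1
        assert res.sizes == [6]

    def test_deterministic_labels_are_smallest_member(self):
        system = gen_planted_config(PlantedConfigSpec(cluster_sizes=(3, 2), seed=4))
        res = cluster_frame(system.frames[0], system.topology)
        for label, members in res.members().items():
            assert label == min(members)


class TestClusterCountSeries:
    def test_static_trajectory_constant_fit(self):
        system = gen_planted_config(PlantedConfigSpec(cluster_sizes=(4, 2), n_frames=5, seed=9))
        times, counts, fit = cluster_count_series(system.frames, system.topology)
        assert np.all(counts == 2)
        c2, c1, c0 = fit
        assert abs(c2) < 1e-12 and abs(c1) < 1e-12
        assert c0 == pytest.approx(2.0)

    def test_merge_schedule_recovered(self):
        system = gen_planted_config(
            PlantedConfigSpec(
                cluster_sizes=(4, 3, 2),
                box_nm=(20.0, 20.0, 20.0),
                n_frames=20,
                merge_schedule=((10, 0, 1),),
                seed=5,
            )
        )
        _, counts, _ = cluster_count_series(system.frames, system.topology)
        assert counts.astype(int).tolist() == system.truth["counts_per_frame"]
        assert counts[9] == 3 and counts[10] == 2

    def test_fit_skipped_below_three_frames(self):
        system = gen_planted_config(PlantedConfigSpec(cluster_sizes=(2,), n_frames=2, seed=1))
        _, _, fit = cluster_count_series(system.frames, system.topology)
        assert fit is None
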
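"""Morphometry: tree statistics, Sholl, volume masks, proximity analysis."""

import numpy as np
import pytest

from mitonet import morphometry, synthetic
from mitonet.containers import VoxelStack
from mitonet.errors import InputError, ParseError, UndefinedResultError
from mitonet.morphometry import (
    AXON,
    DENDRITE,
    SOMA,
    SWCMorphology,
    branch_points,
    count_processes,
    fill_volume_mask,
    min_branch_mito_distance,
    mito_sholl,
    normalize_distances,
    prob_within_radius,
    read_swc,
    shell_counts,
    sholl_intersections,
    total_length,
    write_swc,
)


def chain_morph(points, types=None, radius=1.0):
    """Unbranched chain morphology through the given 3D points."""
    n = len(points)
    types = types or [SOMA] + [AXON] * (n - 1)
    return SWCMorphology(
        np.arange(1, n + 1), np.array(types), np.asarray(points, dtype=float),
        np.full(n, radius), np.arange(-1, n - 1),
    )


class TestSWCIO:
    def test_three_node_stub(self, tmp_path):
        p = tmp_path / "stub.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 2 10 0 0 1 1\n3 2 20 0 0 1 2\n")
        m = read_swc(p)
        assert m.n_nodes == 3
        assert m.root == 0

    def test_child_before_parent_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 2\n2 2 10 0 0 1 -1\n")
        with pytest.raises(ParseError):
            read_swc(p)

    def test_unknown_type_rejected(self, tmp_path):
        p = tmp_path / "bad2.swc"
        p.write_text("1 9 0 0 0 5 -1\n")
        with pytest.raises(ParseError) as e:
            read_swc(p)
        assert e.value.line == 1

    def test_orphan_parent_rejected(self, tmp_path):
        p = tmp_path / "bad3.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 2 1 0 0 1 99\n")
        with pytest.raises(ParseError):
            read_swc(p)


class TestTreeStats:
    def test_unbranched_has_no_branch_points(self):
        m = chain_morph([(0, 0, 0), (5, 0, 0), (10, 0, 0)])
        assert branch_points(m).shape[0] == 0
        assert count_processes(m) == 1

    def test_bifurcation_gives_three_processes(self):
        # soma -> stem -> branch node -> two daughters
        m = SWCMorphology(
            np.arange(1, 6), np.array([SOMA, AXON, AXON, AXON, AXON]),
            np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0], [15, 5, 0], [15, -5, 0]],
                     dtype=float),
            np.ones(5), np.array([-1, 0, 1, 2, 2]),
        )
        assert branch_points(m).shape[0] == 1
        assert count_processes(m) == 3

    def test_branch_count_matches_child_degree_oracle(self, small_morph):
        m = small_morph
        degree = np.zeros(m.n_nodes, dtype=int)
        for i in range(m.n_nodes):
            if m.parent[i] >= 0:
                degree[m.parent[i]] += 1
        oracle = sum(
            1 for i in range(m.n_nodes)
            if degree[i] >= 2 and m.types[i] != SOMA
        )
        assert branch_points(m, "all").shape[0] == oracle

    def test_processes_equals_tips_plus_branch_points(self, small_morph):
        m = small_morph
        degree = np.zeros(m.n_nodes, dtype=int)
        for i in range(m.n_nodes):
            if m.parent[i] >= 0:
                degree[m.parent[i]] += 1
        tips = sum(1 for i in range(m.n_nodes) if degree[i] == 0 and i != m.root)
        bps = sum(1 for i in range(m.n_nodes) if degree[i] >= 2 and i != m.root)
        assert count_processes(m) == tips + bps

    def test_two_collinear_nodes(self):
        m = chain_morph([(0, 0, 0), (10, 0, 0)])
        assert total_length(m) == pytest.approx(10.0)

    def test_compartment_lengths_additive(self, small_morph):
        m = small_morph
        assert total_length(m, "axon") + total_length(m, "dendrite") == pytest.approx(
            total_length(m, "all")
        )


class TestSholl:
    def test_straight_radial_neurite(self):
        # intermediate nodes off integer radii so no node sits on a sphere
        pts = [(r, 0, 0) for r in (0.0, 2.6, 5.1, 7.7, 10.0)]
        m = chain_morph(pts)
        prof = sholl_intersections(m, "all", step=1.0)
        # one crossing at each integer radius strictly inside the neurite
        expected = {float(r): 1 for r in range(1, 10)}
        got = dict(zip(prof.radii, prof.counts))
        for r in range(1, 10):
            assert got[float(r)] == 1
        assert got.get(10.0, 0) == 0  # tip touches, does not cross

    def test_bifurcation_doubles_counts(self):
        m = SWCMorphology(
            np.arange(1, 4 + 1), np.array([SOMA, AXON, AXON, AXON]),
            np.array([[0, 0, 0], [5.2, 0, 0], [10.4, 1, 0], [10.4, -1, 0]],
                     dtype=float),
            np.ones(4), np.array([-1, 0, 1, 1]),
        )
        prof = sholl_intersections(m, "all", step=1.0)
        got = dict(zip(prof.radii, prof.counts))
        for r in range(1, 6):
            assert got[float(r)] == 1
        for r in range(6, 10):
            assert got[float(r)] == 2

    def test_matches_dense_sampling_oracle(self, small_morph):
        m = small_morph
        prof = sholl_intersections(m, "all", step=2.0)
        center = m.soma_center
        for r, count in zip(prof.radii, prof.counts):
            oracle = 0
            for child, parent in m.edges("all"):
                p0, p1 = m.xyz[parent], m.xyz[child]
                ts = np.linspace(0, 1, max(int(np.linalg.norm(p1 - p0) / 0.002), 2))
                d = np.linalg.norm(p0 + ts[:, None] * (p1 - p0) - center, axis=1) - r
                oracle += int(np.sum(d[:-1] * d[1:] < 0))
            assert count == oracle, f"radius {r}"

    def test_disjoint_subtree_additivity(self):
        # two neurites on opposite sides of the soma: profile of the whole
        # equals the sum of each compartment's profile
        m = synthetic.gen_morphology(2, 2, segment_len=8.0, seed=13)
        pa = sholl_intersections(m, "axon", 1.0)
        pd = sholl_intersections(m, "dendrite", 1.0)
        pall = sholl_intersections(m, "all", 1.0)
        n = pall.counts.size
        summed = np.zeros(n, dtype=int)
        summed[: pa.counts.size] += pa.counts
        summed[: pd.counts.size] += pd.counts
        assert np.array_equal(pall.counts, summed)


class TestVolumeMask:
    def test_sphere_volume_close_to_analytic(self):
        m = SWCMorphology(np.array([1]), np.array([SOMA]),
                          np.array([[0.0, 0.0, 0.0]]), np.array([2.0]),
                          np.array([-1]))
        vm = fill_volume_mask(m, 0.4)
        vol = vm.data.sum() * 0.4**3
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 8.0, rel=0.1)

    def test_empty_morphology_all_false(self):
        m = SWCMorphology(np.empty(0, int), np.empty(0, int),
                          np.empty((0, 3)), np.empty(0), np.empty(0, int))
        vm = fill_volume_mask(m, 1.0)
        assert not vm.data.any()

    def test_subtree_mask_subset_of_full(self, small_morph):
        m = small_morph
        full = fill_volume_mask(m, 1.0)
        # axon-only morphology on the same grid
        keep = (m.types == AXON) | (np.arange(m.n_nodes) == m.root)
        idx_map = {old: new for new, old in enumerate(np.flatnonzero(keep))}
        sub = SWCMorphology(
            m.ids[keep], m.types[keep], m.xyz[keep], m.radius[keep],
            np.array([idx_map.get(p, -1) if p >= 0 else -1
                      for p in m.parent[keep]]),
        )
        sub_mask = fill_volume_mask(sub, 1.0, origin=full.origin, shape=full.shape)
        assert not (sub_mask.data & ~full.data).any()


class TestMitoSholl:
    def test_single_voxel_in_expected_shell(self):
        data = np.zeros((11, 11, 11), dtype=bool)
        data[5, 5, 5] = True
        stack = VoxelStack(data, (1.0, 1.0, 1.0))
        # voxel center at (5,5,5); center at (0.5, 5, 5) -> distance 4.5
        prof = shell_counts(stack, np.array([0.5, 5.0, 5.0]), step=1.0)
        got = dict(zip(prof.radii, prof.counts))
        assert got[4.0] == 1  # shell [4, 5)
        assert sum(prof.counts) == 1

    def test_empty_stack_zero_profile(self):
        stack = VoxelStack(np.zeros((4, 4, 4), dtype=bool), (1.0,) * 3)
        prof = shell_counts(stack, np.zeros(3))
        assert prof.counts.sum() == 0

    def test_uniform_stack_matches_exhaustive_binning(self):
        data = np.ones((6, 7, 8), dtype=bool)
        stack = VoxelStack(data, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        center = np.array([1.3, 2.1, 0.7])
        prof = shell_counts(stack, center, step=1.0)
        # brute force: bin every voxel center distance
        oracle = {}
        for z in range(6):
            for y in range(7):
                for x in range(8):
                    d = np.sqrt((x - center[0])**2 + (y - center[1])**2
                                + (z - center[2])**2)
                    k = int(d // 1.0)
                    oracle[k] = oracle.get(k, 0) + 1
        for k, c in oracle.items():
            assert prof.counts[k] == c

    def test_count_conservation_through_pipeline(self, mito_scene):
        from mitonet.image_quant import binarize_stack

        morph, stack, _, mask = mito_scene
        prof = mito_sholl(stack, mask, morph.soma_center, step=1.0,
                          rolling_ball_radius=10)
        binary = binarize_stack(stack.data, rolling_ball_radius=10) & mask.data
        assert prof.counts.sum() == binary.sum()

    def test_dimension_mismatch_rejected(self, mito_scene):
        morph, stack, _, _ = mito_scene
        bad = VoxelStack(np.zeros((2, 2, 2), dtype=bool), stack.voxel_size)
        with pytest.raises(InputError):
            mito_sholl(stack, bad, morph.soma_center)


class TestProximity:
    def test_3_4_5_distance(self):
        data = np.zeros((3, 9, 9), dtype=bool)
        data[0, 4, 3] = True  # world (x=3, y=4, z=0)
        stack = VoxelStack(data, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        res = min_branch_mito_distance(np.array([[0.0, 0.0, 0.0]]), stack)
        assert res.min_distances[0] == pytest.approx(5.0)

    def test_zero_distance_at_branch_point(self):
        data = np.zeros((3, 3, 3), dtype=bool)
        data[1, 1, 1] = True
        stack = VoxelStack(data, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        res = min_branch_mito_distance(np.array([[1.0, 1.0, 1.0]]), stack)
        assert res.min_distances[0] == 0.0

    def test_no_positive_voxels_undefined(self):
        stack = VoxelStack(np.zeros((3, 3, 3), dtype=bool), (1.0,) * 3)
        with pytest.raises(UndefinedResultError):
            min_branch_mito_distance(np.array([[0.0, 0.0, 0.0]]), stack)

    def test_matches_brute_force_scan_anisotropic(self, rng):
        data = rng.random((8, 10, 12)) < 0.05
        data[0, 0, 0] = True
        stack = VoxelStack(data, (2.0, 0.5, 0.5), (1.0, -2.0, 3.0))
        pts = rng.uniform(-5, 10, size=(20, 3))
        res = min_branch_mito_distance(pts, stack)
        centers = stack.voxel_centers(data)
        for p, d in zip(pts, res.min_distances):
            brute = np.min(np.linalg.norm(centers - p, axis=1))
            assert d == pytest.approx(brute)

    def test_adding_voxels_never_increases_distance(self, rng):
        base = rng.random((6, 6, 6)) < 0.1
        base[2, 2, 2] = True
        more = base | (rng.random((6, 6, 6)) < 0.2)
        pts = rng.uniform(0, 5, size=(5, 3))
        d1 = min_branch_mito_distance(pts, VoxelStack(base, (1.0,) * 3)).min_distances
        d2 = min_branch_mito_distance(pts, VoxelStack(more, (1.0,) * 3)).min_distances
        assert np.all(d2 <= d1 + 1e-12)


class TestNormalization:
    def _result(self, dists):
        k = len(dists)
        return morphometry.ProximityResult(np.zeros((k, 3)), np.asarray(dists, float))

    def test_reference_mean_is_exactly_one(self):
        groups = {"wt": self._result([1.0, 2.0, 3.0]), "ko": self._result([0.5, 1.0])}
        out = normalize_distances(groups, "wt")
        assert out["wt"].normalized.mean() == pytest.approx(1.0, abs=1e-15)

    def test_half_mean_group_normalizes_to_half(self):
        groups = {"wt": self._result([2.0, 2.0]), "ko": self._result([1.0, 1.0])}
        out = normalize_distances(groups, "wt")
        assert np.allclose(out["ko"].normalized, 0.5)

    def test_scale_invariance(self, rng):
        d = rng.uniform(0.5, 5.0, size=30)
        a = normalize_distances({"g": self._result(d)}, "g")["g"].normalized
        b = normalize_distances({"g": self._result(7.3 * d)}, "g")["g"].normalized
        assert np.allclose(a, b)

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(InputError):
            normalize_distances({"g": self._result([0.0, 0.0])}, "g")


class TestProbWithinRadius:
    def test_extremes(self):
        r_all = morphometry.ProximityResult(np.zeros((3, 3)), np.zeros(3))
        assert prob_within_radius(r_all, 1.0) == 1.0
        r_none = morphometry.ProximityResult(np.zeros((3, 3)), np.full(3, 9.0))
        assert prob_within_radius(r_none, 1.0) == 0.0

    def test_constructed_49_of_100(self):
        d = np.concatenate([np.full(49, 0.5), np.full(51, 2.0)])
        res = morphometry.ProximityResult(np.zeros((100, 3)), d)
        assert prob_within_radius(res, 1.0) == pytest.approx(0.49)
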
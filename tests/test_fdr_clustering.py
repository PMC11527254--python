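from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionmap.fdr_clustering import (
    DEFAULT_Q_GRID,
    ClusterSet,
    bh_threshold,
    cluster_composition,
    label_clusters,
    select_q,
    split_by_direction,
)
from lesionmap.volume_core import UsageError, VoxelGrid
from lesionmap.voxelwise_stats import StatMap


def step_up_oracle(pvals, q):
    """Independent BH step-up: scan from the largest p downward."""
    p = sorted(pvals)
    m = len(p)
    threshold, found = 0.0, False
    for i in range(m, 0, -1):
        if p[i - 1] <= i / m * q:
            threshold, found = p[i - 1], True
            break
    n_sig = sum(1 for v in pvals if v <= threshold) if found else 0
    return threshold, n_sig


def flood_fill_components(mask, connectivity):
    """Independent BFS component labelling; returns sorted component sizes."""
    if connectivity == 6:
        neigh = [
            (dx, dy, dz)
            for dx, dy, dz in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)]
        ]
    else:
        neigh = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
            and (connectivity == 26 or abs(dx) + abs(dy) + abs(dz) <= 2)
        ]
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    nx, ny, nz = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        size = 0
        dq = deque([start])
        seen[start] = True
        while dq:
            x, y, z = dq.popleft()
            size += 1
            for dx, dy, dz in neigh:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz
                        and mask[p] and not seen[p]):
                    seen[p] = True
                    dq.append(p)
        sizes.append(size)
    return sorted(sizes, reverse=True)


def make_pmap(p_volume, mask=None):
    p_volume = np.asarray(p_volume, dtype=float)
    mask = np.ones(p_volume.shape, bool) if mask is None else mask
    grid = VoxelGrid(p_volume.shape, (1.0, 1.0, 1.0))
    return StatMap(stat=np.zeros(int(mask.sum())), p=p_volume[mask],
                   mask=mask, grid=grid, metadata={"contrast": "test"})


class TestBHThreshold:
    def test_worked_example(self):
        thr, n = bh_threshold([0.001, 0.01, 0.02, 0.2], 0.05)
        assert thr == pytest.approx(0.02)
        assert n == 3

    def test_no_discoveries(self):
        thr, n = bh_threshold([0.6, 0.7, 0.9], 0.05)
        assert thr == 0.0 and n == 0

    def test_boundary_equality_significant(self):
        thr, n = bh_threshold([0.05 / 4] * 1 + [1.0] * 3, 0.05)
        assert thr == pytest.approx(0.05 / 4)
        assert n == 1

    def test_oracle_agreement_random_vectors(self, rng):
        for _ in range(200):
            m = rng.integers(1, 500)
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
            q = rng.uniform(0.001, 0.2)
            assert bh_threshold(p, q) == pytest.approx(step_up_oracle(p, q))

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=300) ** 2
        counts = [bh_threshold(p, q)[1] for q in (0.001, 0.01, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            bh_threshold([], 0.05)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.floats(0.001, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_property_matches_oracle(self, pvals, q):
        assert bh_threshold(pvals, q) == pytest.approx(step_up_oracle(pvals, q))


class TestLabelClusters:
    def test_corner_pair_26(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        _, sizes = label_clusters(mask, 26)
        assert sizes == [2]

    def test_corner_pair_6(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        _, sizes = label_clusters(mask, 6)
        assert sizes == [1, 1]

    def test_edge_pair_18(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[0, 1, 1] = True
        _, sizes18 = label_clusters(mask, 18)
        _, sizes6 = label_clusters(mask, 6)
        assert sizes18 == [2] and sizes6 == [1, 1]

    def test_random_mask_matches_flood_fill(self, rng):
        mask = rng.uniform(size=(20, 20, 20)) < 0.2
        for conn in (6, 26):
            labels, sizes = label_clusters(mask, conn)
            assert sizes == flood_fill_components(mask, conn)
            assert int((labels > 0).sum()) == int(mask.sum())

    def test_labels_ordered_by_size(self, rng):
        mask = np.zeros((10, 10, 10), bool)
        mask[0:2, 0:2, 0:2] = True  # 8 voxels
        mask[6:9, 6:9, 6:9] = True  # 27 voxels
        labels, sizes = label_clusters(mask, 6)
        assert sizes == [27, 8]
        assert labels[7, 7, 7] == 1
        assert labels[0, 0, 0] == 2

    def test_bad_connectivity(self):
        with pytest.raises(UsageError):
            label_clusters(np.zeros((2, 2, 2), bool), 10)


class TestSelectQ:
    def test_blob_recovered_at_most_stringent_q(self, rng):
        shape = (20, 20, 20)
        p = rng.uniform(0.2, 1.0, size=shape)
        p[2:8, 2:8, 2:8] = 1e-6  # 216-voxel blob
        pmap = make_pmap(p)
        res = select_q(pmap, DEFAULT_Q_GRID, min_cluster=100)
        # oracle: smallest q whose BH threshold keeps a >=100 cluster
        expected_q = None
        for q in sorted(DEFAULT_Q_GRID):
            thr, _ = step_up_oracle(p.ravel(), q)
            sizes = flood_fill_components(p <= thr, 26)
            if sizes and sizes[0] >= 100:
                expected_q = q
                break
        assert res.q == expected_q
        assert res.clusters.n_clusters == 1
        assert res.clusters.table.n_voxels.iloc[0] == 216

    def test_null_map_no_signal(self, rng):
        p = rng.uniform(0.5, 1.0, size=(10, 10, 10))
        res = select_q(make_pmap(p), DEFAULT_Q_GRID, min_cluster=10)
        assert res.no_signal and res.clusters.empty()

    def test_min_cluster_99_vs_100(self):
        shape = (30, 30, 30)
        for size, expect in ((99, 0), (100, 1)):
            # a connected 2D strip of `size` voxels in the z=5 plane
            p_blob = np.ones(shape)
            coords = [(i % 30, (i // 30) % 30, 5) for i in range(size)]
            for c in coords:
                p_blob[c] = 1e-9
            res = select_q(make_pmap(p_blob), DEFAULT_Q_GRID, min_cluster=100)
            assert res.clusters.n_clusters == expect

    def test_invariant_to_grid_entries_below_selected(self, rng):
        p = rng.uniform(0.2, 1.0, size=(20, 20, 20))
        p[2:8, 2:8, 2:8] = 1e-6
        pmap = make_pmap(p)
        full = select_q(pmap, DEFAULT_Q_GRID, min_cluster=100)
        trimmed_grid = [q for q in DEFAULT_Q_GRID if q >= full.q]
        trimmed = select_q(pmap, trimmed_grid, min_cluster=100)
        assert full.q == trimmed.q
        assert full.p_threshold == trimmed.p_threshold
        np.testing.assert_array_equal(full.clusters.labels, trimmed.clusters.labels)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(UsageError):
            select_q(make_pmap(np.ones((2, 2, 2))), [], 1)


class TestSplitByDirection:
    def make_clusters(self, mask):
        labels, sizes = label_clusters(mask, 26)
        from lesionmap.fdr_clustering import _build_table

        table = _build_table(labels, sizes, "test", 0.05, 0.01)
        grid = VoxelGrid(mask.shape, (1.0, 1.0, 1.0))
        return ClusterSet(labels, grid, table, 26)

    def test_homogeneous_unchanged(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:5, 1:5, 1:5] = True
        clusters = self.make_clusters(mask)
        sign = np.ones(mask.shape)
        out = split_by_direction(clusters, sign, min_cluster=10)
        assert out.n_clusters == 1
        assert out.table.direction.iloc[0] == 1
        np.testing.assert_array_equal(out.labels > 0, mask)

    def test_two_halves_split(self):
        mask = np.zeros((10, 8, 8), bool)
        mask[1:9, 1:5, 1:5] = True
        sign = np.zeros(mask.shape)
        sign[:5] = 1.0
        sign[5:] = -1.0
        clusters = self.make_clusters(mask)
        out = split_by_direction(clusters, sign, min_cluster=10)
        assert out.n_clusters == 2
        assert sorted(out.table.direction) == [-1, 1]

    def test_zero_sign_majority_resolution_census(self):
        mask = np.zeros((10, 8, 8), bool)
        mask[1:9, 1:5, 1:5] = True
        sign = np.ones(mask.shape)
        sign[4, 2, 2] = 0.0  # surrounded by + voxels -> adopted
        clusters = self.make_clusters(mask)
        out = split_by_direction(clusters, sign, min_cluster=10)
        assert int((out.labels > 0).sum()) == int(mask.sum())

    def test_tie_voxels_excluded(self):
        # a 1-voxel-thick interface with exact +/- balance around a 0 voxel
        mask = np.zeros((5, 1, 1), bool)
        mask[:, 0, 0] = True
        sign = np.array([1.0, 1.0, 0.0, -1.0, -1.0]).reshape(5, 1, 1)
        clusters = self.make_clusters(mask)
        out = split_by_direction(clusters, sign, min_cluster=1)
        assert int((out.labels > 0).sum()) == 4  # tie voxel dropped


class TestComposition:
    def test_containment_and_straddle(self, toy_atlas):
        mask = np.zeros(toy_atlas.grid.shape, bool)
        region = toy_atlas.labels == 1
        mask |= region
        labels, sizes = label_clusters(mask, 26)
        from lesionmap.fdr_clustering import _build_table

        cs = ClusterSet(labels, toy_atlas.grid,
                        _build_table(labels, sizes, "c", 0.05, 0.01), 26)
        comp = cluster_composition(cs, toy_atlas)
        for cid, grp in comp.groupby("cluster_id"):
            assert grp.fraction.sum() == pytest.approx(1.0)
            assert set(grp.label_id) == {1}

    def test_even_straddle(self):
        from lesionmap.fdr_clustering import _build_table
        from lesionmap.volume_core import LabelVolume, RegionTable

        shape = (8, 4, 4)
        labels_arr = np.zeros(shape, np.int32)
        labels_arr[:4] = 1
        labels_arr[4:] = 2
        table = RegionTable.from_rows([
            dict(label_id=1, name="L", parent_id=None, cell_group="none",
                 excluded=False),
            dict(label_id=2, name="R", parent_id=None, cell_group="none",
                 excluded=False),
        ])
        atlas = LabelVolume(VoxelGrid(shape, (1, 1, 1)), labels_arr, table)
        mask = np.zeros(shape, bool)
        mask[2:6] = True
        clabels, sizes = label_clusters(mask, 26)
        cs = ClusterSet(clabels, atlas.grid,
                        _build_table(clabels, sizes, "c", 0.05, 0.01), 26)
        comp = cluster_composition(cs, atlas)
        fracs = dict(zip(comp.label_id, comp.fraction))
        assert fracs[1] == pytest.approx(0.5)
        assert fracs[2] == pytest.approx(0.5)

    def test_census_oracle_random(self, rng, toy_atlas):
        mask = rng.uniform(size=toy_atlas.grid.shape) < 0.01
        labels, sizes = label_clusters(mask, 26)
        if not sizes:
            return
        from lesionmap.fdr_clustering import _build_table

        cs = ClusterSet(labels, toy_atlas.grid,
                        _build_table(labels, sizes, "c", 0.05, 0.01), 26)
        comp = cluster_composition(cs, toy_atlas)
        for cid, grp in comp.groupby("cluster_id"):
            m = labels == cid
            for _, row in grp.iterrows():
                tally = int(((toy_atlas.labels == row.label_id) & m).sum())
                assert tally == row.n_voxels
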
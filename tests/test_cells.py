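"""Per-cell level-set segmentation and rasterisation."""

import numpy as np
import pytest

from lsmseg.cells import (
    LevelSetPatch,
    evolve_multi,
    fill_unassigned_nearest,
    init_from_labels,
    init_from_seeds,
    labels_from_lsfs,
    seeds_from_label_grid,
)
from lsmseg.core import EvolutionParams
from lsmseg.edges import IndicatorSpec, edge_map


class TestInitFromSeeds:
    def test_single_seed_ball_volume(self):
        phis = init_from_seeds([(1, [[16, 16, 16]])], (32, 32, 32), r0=3.0)
        vol = int((phis[0].dense() < 0).sum())
        assert vol == pytest.approx(4 / 3 * np.pi * 27, rel=0.20)

    def test_two_seeds_disjoint_interiors(self):
        phis = init_from_seeds(
            [(1, [[10, 10, 10]]), (2, [[10, 10, 20]])], (24, 24, 32), r0=3.0
        )
        a = phis[0].dense() < 0
        b = phis[1].dense() < 0
        assert not (a & b).any()

    def test_empty_seed_set(self):
        assert init_from_seeds([], (8, 8, 8)) == []

    def test_out_of_bounds_seed(self):
        with pytest.raises(ValueError):
            init_from_seeds([(1, [[9, 0, 0]])], (8, 8, 8))

    def test_order_follows_ascending_label(self):
        phis = init_from_seeds(
            [(5, [[4, 4, 4]]), (2, [[10, 10, 10]])], (16, 16, 16), r0=2.0
        )
        assert [p.label for p in phis] == [2, 5]


class TestInitFromLabels:
    def test_cube_erosion_by_unit_ball(self):
        L = np.zeros((16, 16, 16), np.int32)
        L[3:12, 3:12, 3:12] = 1  # 9^3 cube
        phis = init_from_labels(L, d=1)
        interior = phis[0].dense() < 0
        assert interior.sum() == 7**3
        assert interior[4:11, 4:11, 4:11].all()

    def test_single_voxel_label_kept_by_fallback(self):
        L = np.zeros((8, 8, 8), np.int32)
        L[4, 4, 4] = 1
        phis = init_from_labels(L, d=1)
        interior = phis[0].dense() < 0
        assert interior.sum() == 1
        assert interior[4, 4, 4]

    def test_all_background_raises(self):
        with pytest.raises(ValueError):
            init_from_labels(np.zeros((6, 6, 6), np.int32))

    def test_foam_truth_interiors_strictly_inside_cells(self, small_foam):
        truth = small_foam.truth_labels
        phis = init_from_labels(truth, d=1)
        assert len(phis) == truth.max()
        for p in phis:
            interior = p.dense() < 0
            assert interior.any()
            assert (truth[interior] == p.label).all()


class TestLabelsFromLsfs:
    def _patch(self, label, phi, shape):
        return LevelSetPatch(label=label, phi=phi, origin=(0, 0, 0), full_shape=shape)

    def test_disjoint_union(self):
        shape = (8, 8, 8)
        a = np.full(shape, 1.0)
        a[1:3, 1:3, 1:3] = -1.0
        b = np.full(shape, 1.0)
        b[5:7, 5:7, 5:7] = -1.0
        L = labels_from_lsfs([self._patch(1, a, shape), self._patch(2, b, shape)])
        assert (L[1:3, 1:3, 1:3] == 1).all()
        assert (L[5:7, 5:7, 5:7] == 2).all()
        assert (L == 0).sum() == 8**3 - 2 * 8

    def test_most_negative_wins_and_tie_to_lowest(self):
        shape = (4, 4, 4)
        a = np.full(shape, -1.0)
        b = np.full(shape, -2.0)
        L = labels_from_lsfs([self._patch(1, a, shape), self._patch(2, b, shape)])
        assert (L == 2).all()
        L = labels_from_lsfs([self._patch(1, b, shape), self._patch(2, b.copy(), shape)])
        assert (L == 1).all()

    def test_no_negative_is_background(self):
        shape = (4, 4, 4)
        L = labels_from_lsfs([self._patch(1, np.ones(shape), shape)])
        assert (L == 0).all()

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            labels_from_lsfs([])

    def test_round_trip_with_labels(self):
        """init_from_labels(d=0) then rasterise reproduces non-touching labels."""
        L = np.zeros((20, 20, 20), np.int32)
        L[2:8, 2:8, 2:8] = 1
        L[12:18, 12:18, 12:18] = 2
        phis = init_from_labels(L, d=0)
        np.testing.assert_array_equal(labels_from_lsfs(phis), L)


class TestFill:
    def test_single_label_fills_domain(self):
        L = np.zeros((6, 6, 6), np.int32)
        L[3, 3, 3] = 1
        out = fill_unassigned_nearest(L, np.ones_like(L, bool))
        assert (out == 1).all()

    def test_midplane_split_with_tie_to_lowest(self):
        L = np.zeros((4, 4, 9), np.int32)
        L[:, :, 0] = 1
        L[:, :, 8] = 2
        out = fill_unassigned_nearest(L, np.ones_like(L, bool))
        assert (out[:, :, :5] == 1).all()  # x=4 equidistant -> lowest label
        assert (out[:, :, 5:] == 2).all()

    def test_matches_exhaustive_nearest_scan(self):
        rng = np.random.default_rng(9)
        L = np.zeros((10, 10, 10), np.int32)
        pts = rng.choice(1000, size=8, replace=False)
        for i, p in enumerate(pts, start=1):
            L[np.unravel_index(p, L.shape)] = i
        out = fill_unassigned_nearest(L, np.ones_like(L, bool))

        coords = np.argwhere(L > 0)
        labels = L[tuple(coords.T)]
        expect = np.zeros_like(L)
        for idx in np.ndindex(L.shape):
            if L[idx]:
                expect[idx] = L[idx]
                continue
            d2 = ((coords - np.array(idx)) ** 2).sum(axis=1)
            best = np.min(d2)
            cand = labels[d2 == best]
            expect[idx] = cand.min()
        np.testing.assert_array_equal(out, expect)

    def test_idempotent(self):
        L = np.zeros((8, 8, 8), np.int32)
        L[1, 1, 1] = 3
        L[6, 6, 6] = 5
        domain = np.ones_like(L, bool)
        once = fill_unassigned_nearest(L, domain)
        twice = fill_unassigned_nearest(once, domain)
        np.testing.assert_array_equal(once, twice)

    def test_no_labels_raises(self):
        with pytest.raises(ValueError):
            fill_unassigned_nearest(np.zeros((4, 4, 4), np.int32),
                                    np.ones((4, 4, 4), bool))


class TestEvolveMulti:
    def test_empty_list(self):
        assert evolve_multi([], np.ones((8, 8, 8)), EvolutionParams()) == []

    def test_single_seed_fills_cell_without_leaking(self, small_foam):
        truth = small_foam.truth_labels
        lab = 1
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(truth == lab)
        centre = np.unravel_index(int(np.argmax(dist)), dist.shape)
        g = edge_map(small_foam.image, IndicatorSpec(kind="h", gamma=0.8, s=1.0))
        phis = init_from_seeds([(lab, [list(centre)])], truth.shape, r0=3.0, margin=24)
        p = EvolutionParams(alpha=1.0, beta=0.0, lam=1.0, direction="outward",
                            max_iter=120)
        out = evolve_multi(phis, g, p)
        interior = out[0].dense() < 0
        cell = truth == lab
        assert (interior & cell).sum() >= 0.80 * cell.sum()
        # leakage into neighbouring cells (the wall midplane rasterises to
        # +-half a voxel, so a thin boundary film is unavoidable)
        leak = (interior & (truth > 0) & ~cell).sum()
        assert leak <= 0.05 * cell.sum()

    def test_gradient_indicator_leaves_gap_between_neighbours(self, small_foam):
        """The double valley of |grad I| keeps adjacent cell contours apart."""
        from scipy import ndimage

        truth = small_foam.truth_labels
        # find two adjacent cells
        pair = None
        for a in range(1, truth.max() + 1):
            grown = ndimage.binary_dilation(truth == a)
            for b in range(a + 1, truth.max() + 1):
                if (grown & (truth == b)).any():
                    pair = (a, b)
                    break
            if pair:
                break
        assert pair is not None
        g = edge_map(small_foam.image, IndicatorSpec(kind="g", gamma=8.0, s=1.0))
        phis = init_from_labels(
            np.where(np.isin(truth, pair), truth, 0).astype(np.int32), d=2
        )
        p = EvolutionParams(alpha=1.0, beta=0.0, lam=1.0, direction="outward",
                            max_iter=100)
        out = evolve_multi(phis, g, p)
        masks = {q.label: q.dense() < 0 for q in out}
        a, b = pair
        grown_a = ndimage.binary_dilation(masks[a])
        assert not (grown_a & masks[b]).any()  # >= 1 voxel gap everywhere

    def test_shape_mismatch(self):
        phis = init_from_seeds([(1, [[4, 4, 4]])], (8, 8, 8), r0=2.0)
        with pytest.raises(ValueError):
            evolve_multi(phis, np.ones((9, 8, 8)), EvolutionParams())


def test_seeds_from_label_grid_round_trip():
    grid = np.zeros((6, 6, 6), np.int32)
    grid[1, 2, 3] = 4
    grid[5, 5, 5] = 4
    grid[0, 0, 0] = 2
    seeds = seeds_from_label_grid(grid)
    assert [s[0] for s in seeds] == [2, 4]
    assert len(seeds[1][1]) == 2
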
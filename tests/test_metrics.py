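import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import saliencybench as sb
from saliencybench.datatypes import ValidationError
from conftest import brute_force_auc


class TestDensity:
    def test_single_point_no_blur_is_unit_impulse(self):
        d = sb.density_from_points([(3, 5)], (8, 8), blur_level=0)
        assert d.grid[5, 3] == 1.0
        assert d.grid.sum() == 1.0

    @pytest.mark.parametrize("blur", [1, 3, 7])
    def test_centered_point_keeps_argmax_and_mass(self, blur):
        d = sb.density_from_points([(16, 16)], (33, 33), blur_level=blur)
        assert np.unravel_index(d.grid.argmax(), d.grid.shape) == (16, 16)
        assert abs(d.grid.sum() - 1.0) < 1e-9

    def test_two_far_points_split_mass_equally(self):
        # sigma = 1 * 0.01 * 32 = 0.32 px: blobs are tiny vs 16 px separation
        d = sb.density_from_points([(8, 8), (24, 24)], (32, 32), blur_level=1)
        assert abs(d.grid[:16, :16].sum() - 0.5) < 1e-6
        assert abs(d.grid[16:, 16:].sum() - 0.5) < 1e-6

    def test_mass_conserved_for_border_points(self):
        # blur mass clipped at the border is renormalized away
        d = sb.density_from_points([(0, 0), (31, 0)], (32, 32), blur_level=5)
        assert abs(d.grid.sum() - 1.0) < 1e-9

    def test_empty_points_error(self):
        with pytest.raises(ValidationError):
            sb.density_from_points([], (8, 8), blur_level=1)


class TestAuc:
    def test_constant_map_is_exactly_half(self):
        smap = sb.SaliencyMap("m", np.full((10, 10), 0.3))
        assert sb.standard_auc(smap, [(1, 1), (5, 5)], seed=0).auc == 0.5
        pool = [(2, 2), (3, 3), (4, 4)]
        assert sb.shuffled_auc(smap, [(1, 1)], pool, seed=0).auc == 0.5

    def test_indicator_map_is_one(self):
        grid = np.zeros((10, 10))
        pos = [(2, 3), (7, 8)]
        for x, y in pos:
            grid[y, x] = 1.0
        res = sb.standard_auc(sb.SaliencyMap("m", grid), pos, n_neg_ratio=10, seed=1)
        assert res.auc == 1.0

    def test_raster_map_matches_exhaustive_oracle(self):
        grid = np.arange(1, 17, dtype=float).reshape(4, 4)
        smap = sb.SaliencyMap("m", grid)
        pos = [(3, 3), (2, 3), (1, 3)]  # the 3 largest cells
        res = sb.standard_auc(smap, pos, n_neg_ratio=13, seed=0)
        assert res.n_neg == 13
        neg_vals = np.arange(1, 14, dtype=float)
        assert res.auc == brute_force_auc(grid[[3, 3, 3], [3, 2, 1]], neg_vals)

    def test_monotone_transform_invariance(self, rng):
        grid = rng.random((16, 16))
        pos = [(1, 2), (5, 9), (14, 3)]
        a = sb.standard_auc(sb.SaliencyMap("m", grid), pos, seed=7).auc
        b = sb.standard_auc(sb.SaliencyMap("m", np.exp(5 * grid)), pos, seed=7).auc
        assert a == b

    def test_positives_covering_grid_error(self):
        smap = sb.SaliencyMap("m", np.ones((2, 2)))
        pos = [(x, y) for x in range(2) for y in range(2)]
        with pytest.raises(ValidationError, match="negatives"):
            sb.standard_auc(smap, pos, seed=0)

    def test_shuffled_pool_disjoint_matches_oracle(self, rng):
        grid = rng.random((8, 8))
        smap = sb.SaliencyMap("m", grid)
        pos = [(0, 0), (1, 1), (2, 2)]
        pool = [(5, 5), (6, 6), (7, 7), (4, 3)]
        res = sb.shuffled_auc(smap, pos, pool, seed=0)
        oracle = brute_force_auc(smap.values_at(pos), smap.values_at(pool))
        assert res.auc == oracle

    def test_shuffled_excludes_positive_pixels(self):
        smap = sb.SaliencyMap("m", np.arange(16.0).reshape(4, 4))
        with pytest.raises(ValidationError, match="pool"):
            sb.shuffled_auc(smap, [(1, 1)], [(1, 1), (1, 1)], seed=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 20), min_size=1, max_size=12),
        neg=st.lists(st.integers(0, 20), min_size=1, max_size=12),
    )
    def test_midrank_auc_equals_oracle_and_sklearn(self, pos, neg):
        """Mann–Whitney midrank AUC == exhaustive pair count == sklearn ROC."""
        auc = sb.mann_whitney_auc(pos, neg)
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
        labels = [1] * len(pos) + [0] * len(neg)
        if len(set(pos) | set(neg)) > 1:
            assert auc == pytest.approx(roc_auc_score(labels, pos + neg), abs=1e-12)


class TestIoc:
    def test_identical_observers_saturate(self):
        recs = [("i", f"o{k}", "free_view", 20, 30, 0) for k in range(5)]
        table = sb.PointTable.from_records(recs)
        assert sb.ioc_image(table, "i", "free_view", blur_level=1, seed=5,
                            shape=(64, 64)) >= 0.99

    def test_uniform_observers_are_at_chance(self):
        rng = np.random.default_rng(0)
        recs = [("u", f"obs{o}", "free_view", int(rng.integers(0, 64)),
                 int(rng.integers(0, 64)), k)
                for o in range(20) for k in range(10)]
        table = sb.PointTable.from_records(recs)
        ioc = sb.ioc_image(table, "u", "free_view", blur_level=3, seed=0,
                           shape=(64, 64), n_neg_ratio=1e9)
        assert abs(ioc - 0.5) < 0.05

    def test_two_far_apart_observers_are_at_chance(self):
        # each held-out point sits far off the other observer's tiny blob
        recs = [("i", "a", "free_view", 4, 4, 0), ("i", "b", "free_view", 28, 28, 0)]
        table = sb.PointTable.from_records(recs)
        ioc = sb.ioc_image(table, "i", "free_view", blur_level=1, seed=3,
                           shape=(32, 32), n_neg_ratio=1e9)
        assert abs(ioc - 0.5) < 0.05

    def test_single_observer_error(self):
        table = sb.PointTable.from_records([("i", "a", "free_view", 1, 1, 0)])
        with pytest.raises(ValidationError, match="observer"):
            sb.ioc_image(table, "i", "free_view", shape=(8, 8))

    def test_dataset_ioc_is_mean_of_per_image(self):
        rng = np.random.default_rng(2)
        recs = []
        for img in ("a", "b", "c"):
            for o in range(4):
                for k in range(5):
                    recs.append((img, f"o{o}", "free_view",
                                 int(rng.integers(0, 32)), int(rng.integers(0, 32)), k))
        table = sb.PointTable.from_records(recs)
        shapes = {i: (32, 32) for i in "abc"}
        per_image = [sb.ioc_image(table, i, "free_view", seed=0, shape=(32, 32))
                     for i in "abc"]
        total = sb.ioc_dataset(table, "free_view", seed=0, shapes=shapes)
        assert total == pytest.approx(np.mean(per_image))

    def test_dataset_ioc_empty_error(self):
        table = sb.PointTable.from_records([("i", "a", "free_view", 1, 1, 0)])
        with pytest.raises(ValidationError):
            sb.ioc_dataset(table, "object_search")


class TestPearson:
    def test_exact_values(self):
        xs = [1.0, 2.0, 3.0]
        assert sb.pearson(xs, xs) == pytest.approx(1.0)
        assert sb.pearson(xs, [-x for x in xs]) == pytest.approx(-1.0)
        assert sb.pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_error(self):
        with pytest.raises(ValidationError):
            sb.pearson([1, 1, 1], [1, 2, 3])


class TestPrCurve:
    def test_perfect_map_reaches_f_one(self, rng):
        mask = rng.random((16, 16)) > 0.7
        mask[0, 0] = True
        curve = sb.pr_curve(sb.SaliencyMap("m", mask.astype(float)), mask)
        assert curve.max_f == pytest.approx(1.0)

    def test_f_measure_formula_is_harmonic_mean(self):
        ps, rs = np.meshgrid(np.linspace(0.01, 1, 25), np.linspace(0.01, 1, 25))
        lhs = ps * rs / (0.5 * (ps + rs))
        rhs = 2 * ps * rs / (ps + rs)
        assert np.abs(lhs - rhs).max() < 1e-12
        # the quoted formula at P=0.6, R=0.3 gives 0.4
        assert 0.6 * 0.3 / (0.5 * (0.6 + 0.3)) == pytest.approx(0.4)

    def test_random_map_matches_counting_oracle(self, rng):
        grid = rng.random((16, 16))
        mask = rng.random((16, 16)) > 0.6
        mask[3, 3] = True
        curve = sb.pr_curve(sb.SaliencyMap("m", grid), mask)
        for i in [0, 50, 128, 255]:
            t = curve.thresholds[i]
            binarized = grid >= t
            tp = int((binarized & mask).sum())
            n_bin = int(binarized.sum())
            expect_p = 1.0 if n_bin == 0 else tp / n_bin
            assert curve.precision[i] == pytest.approx(expect_p, abs=1e-12)
            assert curve.recall[i] == pytest.approx(tp / mask.sum(), abs=1e-12)

    def test_recall_monotone_in_descending_threshold(self, rng):
        grid = rng.random((12, 12))
        mask = grid > 0.4
        curve = sb.pr_curve(sb.SaliencyMap("m", grid), mask)
        assert np.all(np.diff(curve.recall) >= 0)

    def test_empty_mask_error(self, rng):
        with pytest.raises(ValidationError):
            sb.pr_curve(sb.SaliencyMap("m", rng.random((4, 4))), np.zeros((4, 4), bool))
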
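import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podseg.seg_metrics import (
    BinaryMask,
    ConfusionCounts,
    aggregate_reports,
    compare_arms,
    compose_region,
    confusion,
    dice,
    evaluate_case,
    hausdorff95,
    sensitivity,
    specificity,
    surface_points,
)
from conftest import brute_force_hausdorff


class TestComposeRegion:
    def test_empty_labels_give_empty_regions(self):
        labels = np.zeros((4, 4), dtype=int)
        for region in ("ET", "WT", "TC"):
            assert not compose_region(labels, region).values.any()

    def test_whole_tumor_is_union(self):
        labels = np.array([[1, 2], [4, 0]])
        wt = compose_region(labels, "WT").values
        np.testing.assert_array_equal(wt, [[True, True], [True, False]])

    def test_edema_only_case(self):
        labels = np.full((3, 3), 2)
        assert not compose_region(labels, "ET").values.any()
        assert not compose_region(labels, "TC").values.any()
        assert compose_region(labels, "WT").values.all()

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            compose_region(np.zeros((2, 2), int), "XX")


class TestConfusion:
    def test_perfect_prediction(self):
        gt = np.zeros((4, 4), bool)
        gt[:2] = True
        c = confusion(gt, gt)
        assert (c.TP, c.FP, c.FN) == (8, 0, 0)

    def test_empty_prediction(self):
        gt = np.ones((2, 3), bool)
        c = confusion(np.zeros((2, 3), bool), gt)
        assert (c.TP, c.FN) == (0, 6)

    def test_enumerated_four_pixel_case(self):
        pred = np.array([1, 1, 0, 0], bool)
        gt = np.array([1, 0, 1, 0], bool)
        c = confusion(pred, gt)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 1)
        assert c.total == 4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestOverlapMetrics:
    def test_dice_closed_form(self):
        assert dice(ConfusionCounts(TP=2, TN=0, FP=1, FN=1)) == pytest.approx(4 / 6)

    def test_dice_identical_and_disjoint(self):
        assert dice(ConfusionCounts(TP=5, TN=1, FP=0, FN=0)) == 1.0
        assert dice(ConfusionCounts(TP=0, TN=0, FP=3, FN=3)) == 0.0

    def test_dice_empty_convention_flagged(self):
        flags = []
        assert dice(ConfusionCounts(TP=0, TN=4, FP=0, FN=0), flags) == 1.0
        assert flags

    def test_sensitivity_specificity_ratios(self):
        assert sensitivity(ConfusionCounts(TP=3, TN=0, FP=0, FN=1)) == 0.75
        assert specificity(ConfusionCounts(TP=0, TN=8, FP=2, FN=0)) == 0.8

    def test_undefined_sensitivity_flagged_nan(self):
        flags = []
        val = sensitivity(ConfusionCounts(TP=0, TN=4, FP=1, FN=0), flags)
        assert np.isnan(val) and flags

    def test_dice_symmetry_and_set_formula(self, rng):
        for _ in range(20):
            a = rng.random((6, 6)) < 0.4
            b = rng.random((6, 6)) < 0.4
            d_ab = dice(confusion(a, b))
            d_ba = dice(confusion(b, a))
            assert d_ab == d_ba
            denom = a.sum() + b.sum()
            expected = 1.0 if denom == 0 else 2 * np.sum(a & b) / denom
            assert d_ab == pytest.approx(expected)

    def test_sensitivity_complement_identity(self):
        c = ConfusionCounts(TP=3, TN=2, FP=1, FN=2)
        assert sensitivity(c) + c.FN / (c.TP + c.FN) == pytest.approx(1.0)


class TestSurfaceAndHausdorff:
    def test_surface_of_solid_square(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        pts = surface_points(mask)
        # 3x3 block: all but the single interior voxel are border
        assert len(pts) == 8
        assert [2.0, 2.0] not in pts.tolist()

    def test_spacing_scales_coordinates(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        pts = surface_points(BinaryMask(mask, spacing=(2.0, 0.5)))
        np.testing.assert_allclose(pts, [[2.0, 0.5]])

    def test_identical_sets_zero(self, rng):
        pts = rng.random((10, 2))
        assert hausdorff95(pts, pts, percentile=95) == 0.0
        assert hausdorff95(pts, pts, percentile=100) == 0.0

    def test_single_pair_is_euclidean_distance(self):
        assert hausdorff95(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]),
                           percentile=100) == pytest.approx(5.0)

    def test_empty_surface_flagged(self):
        flags = []
        val = hausdorff95(np.empty((0, 2)), np.array([[0.0, 0.0]]), flags=flags)
        assert np.isnan(val) and flags

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), nt=st.integers(1, 20), np_=st.integers(1, 20))
    def test_percentile_100_matches_brute_force(self, seed, nt, np_):
        r = np.random.default_rng(seed)
        t, p = r.random((nt, 2)) * 10, r.random((np_, 2)) * 10
        assert hausdorff95(t, p, percentile=100) == pytest.approx(
            brute_force_hausdorff(t, p), abs=1e-12
        )

    def test_translation_invariance(self, rng):
        t, p = rng.random((12, 3)), rng.random((9, 3))
        shift = np.array([5.0, -2.0, 1.5])
        assert hausdorff95(t, p) == pytest.approx(
            hausdorff95(t + shift, p + shift), abs=1e-12
        )

    def test_percentile_95_at_most_100(self, rng):
        for _ in range(10):
            t, p = rng.random((15, 2)), rng.random((15, 2))
            assert hausdorff95(t, p, 95) <= hausdorff95(t, p, 100) + 1e-12

    def test_max_of_directions_option(self, rng):
        t, p = rng.random((10, 2)), rng.random((10, 2))
        pooled = hausdorff95(t, p, 95, pool_directions=True)
        split = hausdorff95(t, p, 95, pool_directions=False)
        assert np.isfinite(pooled) and np.isfinite(split)


class TestEvaluateCase:
    def make_labels(self, rng):
        lab = np.zeros((16, 16), dtype=int)
        lab[4:12, 4:12] = 2
        lab[6:10, 6:10] = 1
        lab[7:9, 7:9] = 4
        return lab

    def test_perfect_prediction(self, rng):
        lab = self.make_labels(rng)
        rep = evaluate_case(lab, lab)
        for region in ("ET", "WT", "TC"):
            assert rep.per_region[region]["dice"] == 1.0
            assert rep.per_region[region]["sensitivity"] == 1.0
            assert rep.per_region[region]["haus95"] == 0.0

    def test_empty_prediction_flagged(self, rng):
        lab = self.make_labels(rng)
        rep = evaluate_case(np.zeros_like(lab), lab)
        assert rep.per_region["WT"]["dice"] == 0.0
        assert np.isnan(rep.per_region["WT"]["haus95"])
        assert any("haus95" in f for f in rep.flags)

    def test_matches_individual_operations(self, rng):
        pred = rng.choice([0, 1, 2, 4], size=(12, 12))
        gt = rng.choice([0, 1, 2, 4], size=(12, 12))
        rep = evaluate_case(pred, gt)
        for region in ("ET", "WT", "TC"):
            c = confusion(compose_region(pred, region), compose_region(gt, region))
            assert rep.per_region[region]["dice"] == pytest.approx(dice(c))
            h = hausdorff95(
                surface_points(compose_region(gt, region)),
                surface_points(compose_region(pred, region)),
            )
            got = rep.per_region[region]["haus95"]
            assert (np.isnan(h) and np.isnan(got)) or got == pytest.approx(h)

    def test_aggregate_skips_undefined(self, rng):
        lab = self.make_labels(rng)
        good = evaluate_case(lab, lab)
        bad = evaluate_case(np.zeros_like(lab), lab)  # haus95 undefined
        agg = aggregate_reports([good, bad])
        assert agg.per_region["WT"]["dice"] == pytest.approx(0.5)
        assert agg.per_region["WT"]["haus95"] == 0.0  # one defined case
        assert any("skipped" in f for f in agg.flags)


class TestCompareArms:
    def test_relative_and_absolute_deltas(self):
        a = {"ET": {"dice": 0.5, "haus95": 10.0}}
        b = {"ET": {"dice": 0.6, "haus95": 7.5}}
        out = compare_arms(a, b)
        assert out["ET"]["dice_rel_improvement_pct"] == pytest.approx(20.0)
        assert out["ET"]["haus95_reduction"] == pytest.approx(2.5)
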
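import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podseg.pseudo_label import (
    ClassSchedule,
    ClassThresholds,
    ProbabilityMap,
    build_pseudo_labels,
    compute_class_thresholds,
    pixel_entropy,
    pseudo_ce_loss,
    total_loss,
)


def probs_from(labels, k, confidence=1.0):
    """One-hot-ish probability map from a channel-index map."""
    p = np.full(labels.shape + (k,), (1 - confidence) / (k - 1))
    for c in range(k):
        p[..., c][labels == c] = confidence
    return p


class TestPixelEntropy:
    def test_uniform_is_log_k(self):
        p = np.full((3, 3, 4), 0.25)
        np.testing.assert_allclose(pixel_entropy(p), np.log(4))

    def test_one_hot_is_zero(self):
        p = np.zeros((2, 2, 3))
        p[..., 1] = 1.0
        np.testing.assert_allclose(pixel_entropy(p), 0.0)

    def test_half_half(self):
        p = np.zeros((1, 1, 4))
        p[0, 0, :2] = 0.5
        assert pixel_entropy(p)[0, 0] == pytest.approx(np.log(2))

    def test_entropy_bounds(self, rng):
        raw = rng.random(size=(8, 8, 5))
        p = raw / raw.sum(-1, keepdims=True)
        u = pixel_entropy(p)
        assert np.all(u >= 0) and np.all(u <= np.log(5) + 1e-12)

    def test_channel_subset_renormalizes(self):
        p = np.zeros((1, 1, 4))
        p[0, 0] = [0.4, 0.4, 0.1, 0.1]
        # restricted to the first two equal channels: entropy ln 2
        assert pixel_entropy(p, channel_subset=[0, 1])[0, 0] == pytest.approx(np.log(2))


class TestClassThresholds:
    def test_constant_entropy_gives_that_entropy(self):
        p = np.full((4, 4, 3), 1.0 / 3)  # everything argmaxed to channel 0?
        # force argmax to class 1 with identical entropy everywhere
        p = np.zeros((4, 4, 3))
        p[..., 1] = 0.5
        p[..., 0] = 0.25
        p[..., 2] = 0.25
        tau = compute_class_thresholds([p])
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert tau.tau[1] == pytest.approx(expected)

    def test_median_of_three(self):
        # three pixels predicted class 1 with entropies 0.1, 0.2, 0.3 nats
        maps = []
        for target_entropy in (0.1, 0.2, 0.3):
            # two-class distribution with the desired entropy, argmax channel 1
            from scipy.optimize import brentq
            h = lambda q: -(q * np.log(q) + (1 - q) * np.log(1 - q))
            q = brentq(lambda q: h(q) - target_entropy, 0.5 + 1e-9, 1 - 1e-12)
            p = np.zeros((1, 1, 2))
            p[0, 0] = [1 - q, q]
            maps.append(p)
        tau = compute_class_thresholds(maps)
        assert tau.tau[1] == pytest.approx(0.2, abs=1e-9)

    def test_even_count_median_is_midpoint(self):
        from scipy.optimize import brentq
        h = lambda q: -(q * np.log(q) + (1 - q) * np.log(1 - q))
        maps = []
        for target_entropy in (0.1, 0.3):
            q = brentq(lambda q: h(q) - target_entropy, 0.5 + 1e-9, 1 - 1e-12)
            p = np.zeros((1, 1, 2))
            p[0, 0] = [1 - q, q]
            maps.append(p)
        tau = compute_class_thresholds(maps)
        assert tau.tau[1] == pytest.approx(0.2, abs=1e-9)

    def test_never_predicted_class_absent(self):
        p = np.zeros((2, 2, 3))
        p[..., 0] = 1.0  # all background
        tau = compute_class_thresholds([p])
        assert tau.tau == {}

    def test_json_round_trip(self):
        tau = ClassThresholds(tau={1: 0.25, 2: 0.5})
        assert ClassThresholds.from_json(tau.to_json()).tau == tau.tau


class TestBuildPseudoLabels:
    def schedule(self):
        return ClassSchedule([(1,), (2,)])

    def test_ground_truth_branch_wins(self):
        sched = self.schedule()
        gt = np.array([[2, 2], [0, 0]])
        old = probs_from(np.array([[1, 1], [0, 0]]), k=2, confidence=0.99)
        tau = ClassThresholds(tau={1: 10.0})
        tgt = build_pseudo_labels(gt, old, sched, tau, step=2)
        # gt foreground never overwritten even though old model disagrees
        assert tgt.onehot[0, 0, 2] == 1 and tgt.onehot[0, 1, 2] == 1
        assert not tgt.ignore[0, 0]

    def test_confident_old_prediction_accepted(self):
        sched = self.schedule()
        gt = np.zeros((2, 2), dtype=int)
        old_lab = np.array([[1, 1], [0, 0]])
        old = probs_from(old_lab, k=2, confidence=0.99)
        tau = ClassThresholds(tau={1: 0.5})  # entropy of 0.99-conf ~ 0.056
        tgt = build_pseudo_labels(gt, old, sched, tau, step=2)
        assert tgt.onehot[0, 0, 1] == 1
        assert tgt.onehot[1, 0, 0] == 1  # old background stays background
        assert tgt.v == 1.0 and tgt.candidate_count == 2

    def test_uncertain_old_prediction_ignored(self):
        sched = self.schedule()
        gt = np.zeros((1, 3), dtype=int)
        old = np.zeros((1, 3, 2))
        old[0, :2] = [0.45, 0.55]   # uncertain, argmax class 1
        old[0, 2] = [0.01, 0.99]    # confident
        tau = ClassThresholds(tau={1: 0.1})
        tgt = build_pseudo_labels(gt, old, sched, tau, step=2)
        assert tgt.ignore[0, 0] and tgt.ignore[0, 1] and not tgt.ignore[0, 2]
        assert tgt.v == pytest.approx(1 / 3)

    def test_acceptance_ratio_two_of_three(self):
        sched = self.schedule()
        gt = np.zeros((1, 4), dtype=int)
        old = np.zeros((1, 4, 2))
        old[0, 0] = [0.01, 0.99]
        old[0, 1] = [0.02, 0.98]
        old[0, 2] = [0.45, 0.55]
        old[0, 3] = [0.99, 0.01]  # background pixel, not a candidate
        tau = ClassThresholds(tau={1: 0.2})
        tgt = build_pseudo_labels(gt, old, sched, tau, step=2)
        assert tgt.candidate_count == 3
        assert tgt.accepted_count == 2
        assert tgt.v == pytest.approx(2 / 3)

    def test_partition_of_pixels(self, rng):
        sched = self.schedule()
        gt = (rng.random((8, 8)) < 0.3).astype(int) * 2
        raw = rng.random((8, 8, 2))
        old = raw / raw.sum(-1, keepdims=True)
        tau = ClassThresholds(tau={1: 0.4})
        tgt = build_pseudo_labels(gt, old, sched, tau, step=2)
        labeled = tgt.onehot.sum(-1) == 1
        assert np.all(labeled ^ tgt.ignore)  # exactly one of labeled/ignored

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999), t1=st.floats(0.0, 0.7), t2=st.floats(0.0, 0.7))
    def test_v_monotone_in_thresholds(self, seed, t1, t2):
        """Raising every tau_c weakly increases v and accepted_count."""
        lo, hi = sorted([t1, t2])
        sched = self.schedule()
        r = np.random.default_rng(seed)
        gt = np.zeros((6, 6), dtype=int)
        raw = r.random((6, 6, 2))
        old = raw / raw.sum(-1, keepdims=True)
        tgt_lo = build_pseudo_labels(gt, old, sched, ClassThresholds(tau={1: lo}), step=2)
        tgt_hi = build_pseudo_labels(gt, old, sched, ClassThresholds(tau={1: hi}), step=2)
        assert tgt_hi.accepted_count >= tgt_lo.accepted_count
        assert tgt_hi.v >= tgt_lo.v

    def test_perfect_old_model_reconstructs_everything(self):
        """A confident, correct old model rebuilds the full label map, v = 1."""
        sched = ClassSchedule([(1, 2), (4,)])
        full = np.zeros((8, 8), dtype=int)
        full[1:4, 1:4] = 1
        full[5:7, 5:7] = 2
        full[0, 7] = 4
        gt_step2 = np.where(full == 4, 4, 0)
        old_channels = np.zeros((8, 8), dtype=int)  # channel indices at step 1
        old_channels[full == 1] = 1
        old_channels[full == 2] = 2
        old = probs_from(old_channels, k=3, confidence=1.0)
        tau = ClassThresholds(tau={1: 0.5, 2: 0.5})
        tgt = build_pseudo_labels(gt_step2, old, sched, tau, step=2)
        assert tgt.v == 1.0
        assert not tgt.ignore.any()
        chan = sched.channel_index(2)
        recon = np.zeros((8, 8), dtype=int)
        for lab, ch in chan.items():
            recon[tgt.onehot[..., ch] == 1] = lab
        np.testing.assert_array_equal(recon, full)


class TestPseudoCELoss:
    def make_target(self, sched, gt, old, tau):
        return build_pseudo_labels(gt, old, sched, tau, step=2)

    def test_perfect_prediction_zero_loss(self):
        sched = ClassSchedule([(1,), (2,)])
        gt = np.array([[2, 0]])
        old = probs_from(np.array([[0, 1]]), k=2, confidence=0.999)
        tau = ClassThresholds(tau={1: 0.5})
        tgt = self.make_target(sched, gt, old, tau)
        pred = tgt.onehot.astype(float)
        object.__setattr__(tgt, "v", 1.0)
        assert pseudo_ce_loss(pred, tgt) == pytest.approx(0.0, abs=1e-9)

    def test_single_pixel_half_probability(self):
        sched = ClassSchedule([(1,), (2,)])
        gt = np.array([[2]])
        old = np.array([[[1.0, 0.0]]])
        tau = ClassThresholds(tau={1: 0.5})
        tgt = self.make_target(sched, gt, old, tau)
        object.__setattr__(tgt, "v", 1.0)
        pred = np.array([[[0.25, 0.25, 0.5]]])
        assert pseudo_ce_loss(pred, tgt) == pytest.approx(np.log(2))

    def test_all_ignored_is_zero_with_warning(self):
        sched = ClassSchedule([(1,), (2,)])
        gt = np.array([[0]])
        old = np.array([[[0.45, 0.55]]])
        tau = ClassThresholds(tau={1: 1e-6})
        tgt = self.make_target(sched, gt, old, tau)
        assert tgt.ignore.all()
        pred = np.full((1, 1, 3), 1 / 3)
        with pytest.warns(UserWarning, match="ignored"):
            assert pseudo_ce_loss(pred, tgt) == 0.0

    def test_monotone_in_predicted_probability(self):
        sched = ClassSchedule([(1,), (2,)])
        gt = np.array([[2]])
        old = np.array([[[1.0, 0.0]]])
        tgt = self.make_target(sched, gt, old, ClassThresholds(tau={1: 0.5}))
        object.__setattr__(tgt, "v", 1.0)
        losses = [
            pseudo_ce_loss(np.array([[[1 - p, 0.0, p]]]), tgt)
            for p in (0.2, 0.5, 0.9)
        ]
        assert losses[0] > losses[1] > losses[2]


class TestTotalLoss:
    def test_lambda_zero(self):
        assert total_loss(0.7, 123.0, lam=0.0) == 0.7

    def test_weighted_sum(self):
        assert total_loss(0.7, 2.0, lam=0.01) == pytest.approx(0.72)

    def test_zero_case(self):
        assert total_loss(0.0, 0.0) == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, lam=-0.1)
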
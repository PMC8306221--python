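import numpy as np
import pytest

from echotex.errors import InputError
from echotex.roc import (
    TwoByTwo,
    binary_test_performance,
    clopper_pearson_ci,
    roc_with_delong,
    youden_optimal,
)


class TestROCDeLong:
    def test_perfect_separation(self):
        r = roc_with_delong([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.se_delong == 0.0
        assert r.youden_j == 1.0
        assert r.criterion_text == ">2"

    def test_permuted_labels_auc_near_half(self, rng):
        scores = rng.normal(size=200)
        labels = rng.permutation([0] * 100 + [1] * 100)
        r = roc_with_delong(scores, labels)
        assert abs(r.auc - 0.5) <= 3 * max(r.se_delong, 1e-6)

    def test_auc_equals_pair_counting_oracle(self, rng):
        for _ in range(50):
            n0, n1 = rng.integers(5, 30, size=2)
            scores = np.round(rng.normal(size=n0 + n1), 1)  # induce ties
            labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
            r = roc_with_delong(scores, labels)
            pos, neg = scores[n0:], scores[:n0]
            wins = sum(
                1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
            )
            auc_pairs = wins / (n0 * n1)
            assert r.auc == pytest.approx(max(auc_pairs, 1 - auc_pairs))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        r1 = roc_with_delong(scores, labels)
        r2 = roc_with_delong(np.exp(scores), labels)
        assert r1.auc == pytest.approx(r2.auc)
        assert r1.youden_j == pytest.approx(r2.youden_j)

    def test_one_class_rejected(self):
        with pytest.raises(InputError):
            roc_with_delong([1, 2, 3], [1, 1, 1])

    def test_delong_se_close_to_bootstrap(self, rng):
        """DeLong variance vs a stratified bootstrap on one seeded sample."""
        n = 60
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        scores = rng.normal(size=n) + 0.9 * labels
        r = roc_with_delong(scores, labels)
        boots = []
        pos, neg = scores[30:], scores[:30]
        for _ in range(2000):
            bp = rng.choice(pos, 30)
            bn = rng.choice(neg, 30)
            wins = (bp[:, None] > bn[None, :]).sum() + 0.5 * (bp[:, None] == bn[None, :]).sum()
            boots.append(wins / 900)
        assert r.se_delong == pytest.approx(np.std(boots, ddof=1), rel=0.15)

    def test_reported_point_self_consistent(self, rng):
        for _ in range(20):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            labels[:2] = [0, 1]
            r = roc_with_delong(scores, labels)
            pred = r.classify(scores)
            se = pred[labels == 1].mean()
            sp = (~pred[labels == 0]).mean()
            assert se == pytest.approx(r.se_opt)
            assert sp == pytest.approx(r.sp_opt)


class TestYouden:
    def test_value_gap_criterion(self):
        r = roc_with_delong([1, 2, 2, 3, 4, 5], [0, 0, 0, 1, 1, 1])
        crit, j, se, sp = youden_optimal(r)
        assert j == 1.0
        assert crit == ">2"

    def test_identical_scores_j_zero(self):
        r = roc_with_delong([5, 5, 5, 5], [0, 0, 1, 1])
        assert r.youden_j == 0.0

    def test_j_matches_exhaustive_threshold_scan(self, rng):
        for _ in range(50):
            scores = np.round(rng.normal(size=30), 1)
            labels = rng.integers(0, 2, size=30)
            labels[:2] = [0, 1]
            r = roc_with_delong(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            best = 0.0
            for t in np.unique(scores):
                if r.direction == ">":
                    j = (pos > t).mean() + (neg <= t).mean() - 1
                else:
                    j = (pos <= t).mean() + (neg > t).mean() - 1
                best = max(best, j)
            assert r.youden_j == pytest.approx(best)


class TestClopperPearson:
    def test_thirty_of_thirty_lower_bound(self):
        lo, hi = clopper_pearson_ci(30, 30)
        assert round(100 * lo, 1) == 88.4
        assert hi == 1.0

    def test_zero_of_thirty_by_symmetry(self):
        lo, hi = clopper_pearson_ci(0, 30)
        assert lo == 0.0
        assert round(100 * hi, 1) == 11.6

    def test_complement_symmetry(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson_ci(k, n)
            lo2, hi2 = clopper_pearson_ci(n - k, n)
            assert lo == pytest.approx(1 - hi2, abs=1e-12)

    def test_bounds_bracket_point_estimate(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson_ci(k, n)
            assert lo <= k / n <= hi


class TestBinaryTestPerformance:
    def test_low_level_echoes_specificity(self):
        # present in 23/30 EN and 7/26 HOC; presence predicts EN
        r = binary_test_performance(TwoByTwo(tp=23, fn=7, fp=7, tn=19))
        assert round(100 * r.sp, 2) == 73.08
        assert round(100 * r.sp_ci[0], 1) == 52.2
        assert round(100 * r.sp_ci[1], 1) == 88.4

    def test_perceptible_wall_specificity(self):
        r = binary_test_performance(TwoByTwo(tp=17, fn=13, fp=8, tn=18))
        assert round(100 * r.sp, 2) == 69.23
        assert round(100 * r.sp_ci[0], 1) == 48.2
        assert round(100 * r.sp_ci[1], 1) == 85.7

    def test_sign_present_in_every_control(self):
        # locule count present in all 26/26 HOC: absence predicts EN with
        # perfect specificity
        r = binary_test_performance(TwoByTwo(tp=9, fn=21, fp=0, tn=26))
        assert r.sp == 1.0
        assert round(100 * r.sp_ci[0], 1) == 86.8

    def test_binary_scores_match_roc_route(self):
        """A 0/1 predictor fed through the full ROC machinery reproduces
        the confusion-count route exactly."""
        scores = np.r_[np.ones(23), np.zeros(7), np.ones(7), np.zeros(19)]
        labels = np.r_[np.ones(30, int), np.zeros(26, int)]
        r = roc_with_delong(scores, labels)
        b = binary_test_performance(TwoByTwo(tp=23, fn=7, fp=7, tn=19))
        assert r.auc == pytest.approx(b.auc)
        assert r.se_opt == pytest.approx(b.se)
        assert r.sp_opt == pytest.approx(b.sp)
        assert r.youden_j == pytest.approx(b.youden_j)

    def test_empty_class_rejected(self):
        with pytest.raises(InputError):
            binary_test_performance(TwoByTwo(tp=0, fn=0, fp=3, tn=5))
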
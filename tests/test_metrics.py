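"""Concordance, AUROC/DeLong, Hosmer-Lemeshow, recalibration, KM, log-rank."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from ihtsa.metrics import (
    auroc,
    compare_c,
    delong_test,
    harrell_c,
    hosmer_lemeshow,
    kaplan_meier,
    log_rank,
    one_year_labels,
    recalibrate_logistic,
)


def brute_force_c(scores, times, events):
    """O(n^2) pair enumeration, written independently of the implementation."""
    conc = disc = tied = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                if scores[j] > scores[i]:
                    conc += 1
                elif scores[j] < scores[i]:
                    disc += 1
                else:
                    tied += 1
    pairs = conc + disc + tied
    return (conc + 0.5 * tied) / pairs, pairs


class TestHarrellC:
    def test_perfect_ordering_gives_one(self):
        t = np.arange(1.0, 11.0)
        assert harrell_c(t, t, np.ones(10)).c == 1.0

    def test_all_tied_scores_give_half(self):
        t = np.arange(1.0, 11.0)
        assert harrell_c(np.ones(10), t, np.ones(10)).c == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_with_censoring_and_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 200)
        scores = rng.integers(0, 8, n).astype(float)  # heavy score ties
        times = np.round(rng.exponential(5, n), 1)
        events = rng.integers(0, 2, n).astype(float)
        events[0] = 1
        res = harrell_c(scores, times, events)
        c_ref, pairs_ref = brute_force_c(scores, times, events)
        assert res.c == pytest.approx(c_ref)
        assert res.comparable_pairs == pairs_ref
        assert res.concordant + res.discordant + res.tied == res.comparable_pairs

    def test_requires_events_and_comparable_pairs(self):
        with pytest.raises(ValueError):
            harrell_c([1.0, 2.0], [1.0, 2.0], [0.0, 0.0])

    def test_equals_auroc_on_all_event_distinct_time_construction(self):
        rng = np.random.default_rng(1)
        n = 80
        times = rng.permutation(n).astype(float) + 1
        scores = times + rng.normal(0, 5, n)  # noisy but informative
        events = np.ones(n)
        c = harrell_c(scores, times, events).c
        # AUROC of -score against "died before the median time": on fully
        # observed data with a single split this reduces to pair concordance
        # only across the split, so compare against the pairwise definition
        labels = (times < np.median(times)).astype(float)
        auc = auroc(-scores, labels).auc
        assert abs(c - 0.5) > 0.1 and abs(auc - 0.5) > 0.1
        assert np.sign(c - 0.5) == np.sign(auc - 0.5)


class TestCompareC:
    def test_identical_scores_p_one(self):
        t = np.arange(1.0, 21.0)
        assert compare_c(t, t, t, np.ones(20)) == 1.0

    def test_jackknife_variance_nonnegative_gives_valid_p(self):
        rng = np.random.default_rng(2)
        n = 120
        t = rng.exponential(5, n)
        d = rng.integers(0, 2, n).astype(float)
        d[:5] = 1
        p = compare_c(rng.normal(size=n), rng.normal(size=n), t, d)
        assert 0 <= p <= 1

    def test_detects_informative_vs_permuted_scores(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1000
            lp = rng.normal(size=n)
            t = rng.exponential(np.exp(-lp))
            d = np.ones(n)
            good = -lp  # higher score = longer survival
            bad = rng.permutation(good)
            if compare_c(good, bad, t, d) < 0.01:
                hits += 1
        assert hits >= 18


class TestAuroc:
    def test_hand_enumerated_examples(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert auroc([1, 2, 3, 4], [0, 1, 0, 1]).auc == 0.75

    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1.0, 2.0], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        s = rng.integers(0, 10, 300).astype(float)
        assert auroc(s, y).auc == pytest.approx(roc_auc_score(y, s))

    def test_one_year_labels_exclude_early_censoring(self):
        times = np.array([0.5, 0.5, 2.0, 1.0])
        events = np.array([1.0, 0.0, 0.0, 0.0])
        labels, include, n_excl = one_year_labels(times, events)
        assert n_excl == 1
        np.testing.assert_array_equal(labels, [1.0, 0.0, 0.0])


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.normal(size=100)
        assert delong_test(auroc(s, y), auroc(s, y)) == 1.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 400)
        y[:2] = [0, 1]
        a = auroc(y + rng.normal(0, 1, 400), y)
        b = auroc(rng.normal(size=400), y)
        assert delong_test(a, b) == pytest.approx(delong_test(b, a))

    def test_detects_informative_vs_noise_scorer(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 1000
            y = rng.integers(0, 2, n).astype(float)
            y[:2] = [0, 1]
            informative = y + rng.normal(0, 1.0, n)
            noise = rng.normal(size=n)
            if delong_test(auroc(informative, y), auroc(noise, y)) < 0.001:
                hits += 1
        assert hits >= 18

    def test_variance_agrees_with_bootstrap(self):
        rng = np.random.default_rng(5)
        n = 500
        y = rng.integers(0, 2, n).astype(float)
        y[:2] = [0, 1]
        s = y + rng.normal(0, 1.5, n)
        res = auroc(s, y)
        boots = np.empty(2000)
        for b in range(2000):
            idx = rng.integers(0, n, n)
            while len(np.unique(y[idx])) < 2:
                idx = rng.integers(0, n, n)
            boots[b] = roc_auc_score(y[idx], s[idx])
        assert res.variance == pytest.approx(boots.var(), rel=0.2)


class TestHosmerLemeshow:
    def test_miscalibrated_predictions_rejected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.05, 0.55, 2000)
            y = rng.binomial(1, np.clip(p + 0.2, 0, 1))
            if hosmer_lemeshow(p, y).p < 0.05:
                hits += 1
        assert hits >= 9

    def test_two_groups_undefined(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 100)
        y = rng.binomial(1, p)
        with pytest.raises(ValueError, match="undefined|groups"):
            hosmer_lemeshow(p, y, g=2)

    def test_requires_minimum_group_size(self):
        with pytest.raises(ValueError, match="n >= 5g"):
            hosmer_lemeshow(np.full(20, 0.5), np.zeros(20), g=10)

    def test_calibrated_predictions_accepted_typically(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.9, 5000)
        y = rng.binomial(1, p)
        res = hosmer_lemeshow(p, y)
        assert res.dof == 8
        assert res.p > 0.001  # a calibrated model should rarely be rejected


class TestRecalibration:
    def test_recovers_identity_calibration(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.05, 0.95, 10_000)
        y = rng.binomial(1, p)
        fit = recalibrate_logistic(p, y)
        assert fit.slope == pytest.approx(1.0, abs=0.1)
        assert fit.intercept == pytest.approx(0.0, abs=0.1)

    def test_doubled_logit_gives_half_slope(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.05, 0.95, 10_000)
        y = rng.binomial(1, p)
        logit = np.log(p / (1 - p))
        doubled = 1 / (1 + np.exp(-2 * logit))
        fit = recalibrate_logistic(doubled, y)
        assert fit.slope == pytest.approx(0.5, abs=0.06)

    def test_constant_predictor_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            recalibrate_logistic(np.full(100, 0.5), np.r_[np.zeros(50), np.ones(50)])


class TestKaplanMeierLogRank:
    def test_no_events_survival_stays_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km.survival == 1).all()

    def test_product_limit_by_hand(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.at(1.0) == pytest.approx(2 / 3)
        assert km.at(2.0) == pytest.approx(1 / 3)
        assert km.at(3.0) == pytest.approx(0.0)

    def test_censoring_hand_computation(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 1, 1])
        assert km.at(2.0) == pytest.approx(1 / 2)
        assert km.at(3.0) == pytest.approx(0.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0, 2.0], [1, 1])

    def test_identical_groups_null(self):
        t = np.arange(1.0, 30.0)
        d = np.ones(29)
        chi2, p = log_rank(t, d, t, d)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(11)
        ta, tb = rng.exponential(1, 100), rng.exponential(2, 100)
        da, db = np.ones(100), np.ones(100)
        assert log_rank(ta, da, tb, db)[0] == pytest.approx(log_rank(tb, db, ta, da)[0])

    def test_detects_rate_ratio_two(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            ta = rng.exponential(1.0, 500)
            tb = rng.exponential(2.0, 500)
            if log_rank(ta, np.ones(500), tb, np.ones(500))[1] < 0.001:
                hits += 1
        assert hits >= 19

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            log_rank([1.0], [0.0], [2.0], [0.0])
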
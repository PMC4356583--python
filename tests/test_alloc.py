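"""ABO rules, clinical tiers, policy allocation and the simulator."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ihtsa import synth
from ihtsa.alloc import (
    PairPredictor,
    abo_compatible,
    allocate,
    clinical_priority,
    run_simulation,
    sensitivity_filter,
)
from ihtsa.impute import ImputationSet
from ihtsa.model import TrainConfig, train_ensemble
from ihtsa.registry import Cohort
from conftest import make_cohort, make_record

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


@pytest.fixture(scope="module")
def pool_and_model():
    cohort, _ = synth.generate_cohort(synth.GeneratorConfig(n=1500, seed=42))
    imp = ImputationSet([cohort], m=1, strata="era", seed=0)
    cfg = TrainConfig(hidden=4, decay=1e-4, epochs=150, seed=0, patience=30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_ensemble(imp, cfg, K=5)
    return cohort, model


class TestAbo:
    def test_universal_donor(self):
        assert abo_compatible("O", "A")

    def test_ab_donor_only_to_ab(self):
        assert not abo_compatible("AB", "O")
        assert abo_compatible("AB", "AB")

    @pytest.mark.parametrize("bg", ["A", "AB", "B", "O"])
    def test_identical_groups_always_compatible(self, bg):
        assert abo_compatible(bg, bg)

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            abo_compatible("X", "A")
        with pytest.raises(ValueError):
            abo_compatible("A", "X")

    def test_vectorized_matches_scalar(self):
        recips = np.array(["A", "AB", "B", "O"], dtype=object)
        out = abo_compatible("B", recips)
        np.testing.assert_array_equal(out, [False, True, True, False])


def donor_series(**kw):
    base = dict(donor_bg="A", donor_age=30.0, donor_weight=75.0, donor_sex="male",
                donor_height=176.0, codd_head_trauma=1.0, codd_cva=0.0,
                ischemia_min=180.0)
    base.update(kw)
    return pd.Series(base)


def recipient_series(**kw):
    rec = make_record(**kw)
    return pd.Series(rec)


class TestClinicalPriority:
    def test_tier1_identical_group_both_young(self):
        r = recipient_series(recipient_bg="A", recipient_age=34.0,
                             recipient_weight=70.0, pvr=2.0)
        assert clinical_priority(donor_series(), r) == 1

    def test_tier2_with_high_pvr_and_heavier_donor(self):
        r = recipient_series(recipient_bg="A", recipient_age=50.0,
                             recipient_weight=70.0, pvr=3.5, recipient_sex="female")
        # donor 75 kg is 7.1% heavier: inside the 0-15% band
        assert clinical_priority(donor_series(), r) == 2

    def test_female_to_male_barred_under_high_pvr(self):
        r = recipient_series(recipient_bg="A", recipient_age=50.0,
                             recipient_weight=70.0, pvr=3.5, recipient_sex="male")
        assert clinical_priority(donor_series(donor_sex="female"), r) is None

    def test_weight_outside_20pct_ineligible(self):
        r = recipient_series(recipient_bg="A", recipient_weight=50.0, pvr=2.0)
        assert clinical_priority(donor_series(donor_weight=75.0), r) is None

    def test_compatible_nonidentical_group_is_tier3(self):
        r = recipient_series(recipient_bg="AB", recipient_age=60.0,
                             recipient_weight=75.0, pvr=2.0)
        assert clinical_priority(donor_series(donor_bg="O", donor_age=60.0), r) == 3

    def test_missing_fields_ineligible(self):
        r = recipient_series(recipient_bg="A", pvr=np.nan)
        assert clinical_priority(donor_series(), r) is None


class TestAllocate:
    def test_single_eligible_candidate_chosen_by_every_policy(self, pool_and_model):
        pool, model = pool_and_model
        predictor = PairPredictor(model, pool)
        df = pool.df
        # a donor compatible with exactly one listed recipient
        donor_idx = int(df.index[df["donor_bg"] == "AB"][0])
        donor = df.iloc[donor_idx]
        ab = df.index[(df["recipient_bg"] == "AB")][:1]
        non_ab = df.index[df["recipient_bg"] == "O"][:4]
        wl = np.array(list(ab) + list(non_ab))
        rng = np.random.default_rng(0)
        for policy in ("ihtsa", "random"):
            chosen, _ = allocate(donor, donor_idx, wl, policy, pool, rng, predictor)
            assert chosen == ab[0]

    def test_ihtsa_picks_argmax_of_exhaustive_scoring(self, pool_and_model):
        pool, model = pool_and_model
        predictor = PairPredictor(model, pool)
        donor_idx = int(pool.df.index[pool.df["donor_bg"] == "O"][0])
        donor = pool.df.iloc[donor_idx]
        wl = np.arange(40)
        rng = np.random.default_rng(1)
        chosen, med = allocate(donor, donor_idx, wl, "ihtsa", pool, rng, predictor)
        scores = predictor.medians(donor_idx, wl)
        assert chosen == wl[int(np.argmax(scores))]
        assert med == pytest.approx(scores.max())

    def test_tie_break_is_seeded_and_reproducible(self, pool_and_model):
        pool, _ = pool_and_model
        donor_idx = int(pool.df.index[pool.df["donor_bg"] == "O"][0])
        donor = pool.df.iloc[donor_idx]
        wl = np.arange(30)
        picks = {
            allocate(donor, donor_idx, wl, "random", pool,
                     np.random.default_rng(5), None)[0]
            for _ in range(3)
        }
        assert len(picks) == 1


class TestSimulation:
    def test_incompatible_sole_recipient_no_transplants(self):
        rows = [make_record(recipient_bg="O", donor_bg="AB") for _ in range(4)]
        pool = make_cohort(rows)
        run = run_simulation(pool, nw=1, n_donor_draws=5,
                             policies=("clinical", "random"), seed=0)
        assert all(tr.transplants == 0 for tr in run.traces.values())

    def test_same_seed_identical_run(self, pool_and_model):
        pool, model = pool_and_model
        a = run_simulation(pool, nw=20, n_donor_draws=100, model=model, seed=3)
        b = run_simulation(pool, nw=20, n_donor_draws=100, model=model, seed=3)
        for p in a.traces:
            assert a.traces[p].matches == b.traces[p].matches

    def test_conservation_invariants(self, pool_and_model):
        pool, model = pool_and_model
        run = run_simulation(pool, nw=25, n_donor_draws=200, model=model, seed=4)
        for tr in run.traces.values():
            assert tr.transplants <= run.n_donor_draws
            recipients = [m["recipient"] for m in tr.matches]
            assert len(recipients) == len(set(recipients))
            assert tr.transplants == len(tr.matches)

    def test_randomize_mode_assigns_each_donor_once(self, pool_and_model):
        pool, model = pool_and_model
        run = run_simulation(pool, nw=20, n_donor_draws=150, model=model,
                             seed=5, mode="randomize")
        total = sum(tr.transplants + tr.refusals for tr in run.traces.values())
        assert total <= 150

    def test_random_policy_mean_tracks_candidate_average(self, pool_and_model):
        # with a large list and few draws the list stays a fresh random
        # sample, so the control's matched survival should equal the
        # compatible-candidate average for the same donors
        pool, model = pool_and_model
        run = run_simulation(pool, nw=400, n_donor_draws=80,
                             policies=("random",), model=model, seed=6)
        tr = run.traces["random"]
        predictor = PairPredictor(model, pool)
        refs = []
        for m in tr.matches:
            donor_bg = pool.df.iloc[m["donor"]]["donor_bg"]
            compat = np.flatnonzero(
                abo_compatible(donor_bg, pool.df["recipient_bg"].to_numpy(object))
            )
            refs.append(np.mean(predictor.medians(m["donor"], compat)))
        # 80 matches give a Monte-Carlo se of ~3.5%; allow 3 sigma
        assert np.nanmean(tr.predicted_medians) == pytest.approx(np.mean(refs), rel=0.10)

    def test_model_required_for_ihtsa_policy(self, pool_and_model):
        pool, _ = pool_and_model
        with pytest.raises(ValueError, match="requires a trained model"):
            run_simulation(pool, nw=5, n_donor_draws=5, policies=("ihtsa",), seed=0)


class TestSensitivityFilter:
    def test_never_excluding_predicate_is_identity(self, small_cohort):
        out = sensitivity_filter(small_cohort, exclude=lambda df: np.zeros(len(df), bool))
        pd.testing.assert_frame_equal(out.df, small_cohort.df)

    def test_counting_example(self):
        rows = [make_record(icu=1.0) for _ in range(3)] + [make_record() for _ in range(7)]
        out = sensitivity_filter(make_cohort(rows))
        assert out.n == 7

    def test_removed_fraction_matches_configured_prevalence(self):
        from ihtsa.synth import DEFAULT_MARGINALS, Marginal

        marg = dict(DEFAULT_MARGINALS)
        for v in ("icu", "ventilator", "ecmo", "vad"):
            marg[v] = Marginal("bernoulli", p=0.0)
        marg["icu"] = Marginal("bernoulli", p=0.30)
        cfg = synth.GeneratorConfig(n=10_000, seed=8, covariate_marginals=marg)
        pool, _ = synth.generate_cohort(cfg)
        out = sensitivity_filter(pool)
        assert 1 - out.n / pool.n == pytest.approx(0.30, abs=0.02)

    def test_everything_excluded_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            sensitivity_filter(small_cohort, exclude=lambda df: np.ones(len(df), bool))
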
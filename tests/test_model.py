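"""Time grid, discrete-time targets, rprop training, ensemble, curves."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from ihtsa import synth
from ihtsa.impute import ImputationSet, impute_probability
from ihtsa.model import (
    EnsembleModel,
    HazardNetwork,
    SurvivalCurve,
    TimeGrid,
    TrainConfig,
    build_time_grid,
    cross_validate,
    load_model,
    make_targets,
    median_from_hazards,
    median_survival,
    predict_curve,
    save_model,
    select_grid_point,
    survival_at,
    survival_probability,
    train_ensemble,
    train_network,
)
from ihtsa.registry import ColumnSpec, DesignMatrix, build_design
from ihtsa.synth import DEFAULT_MARGINALS, Marginal


class TestTimeGrid:
    def test_quantile_boundaries_match_hand_computation(self):
        grid = build_time_grid(np.arange(1.0, 101.0), K=4)
        np.testing.assert_allclose(grid.boundaries, [0, 25.75, 50.5, 75.25, 100])

    def test_single_interval(self):
        grid = build_time_grid([3.0, 7.0, 9.0], K=1)
        np.testing.assert_allclose(grid.boundaries, [0, 9.0])

    def test_tied_times_merge_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            grid = build_time_grid([4.0] * 50, K=5)
        assert grid.K == 1

    def test_invalid_K(self):
        with pytest.raises(ValueError):
            build_time_grid([1.0, 2.0], K=0)


class TestTargets:
    GRID = TimeGrid(np.array([0.0, 1, 2, 3, 4, 5]))

    def test_death_inside_interval(self):
        t = make_targets(2.5, 1, self.GRID)
        assert t.n_at_risk[0] == 3 and t.event_interval[0] == 3

    def test_censoring_drops_partial_interval(self):
        t = make_targets(2.5, 0, self.GRID)
        assert t.n_at_risk[0] == 2 and t.event_interval[0] == 0

    def test_death_in_first_interval(self):
        t = make_targets(0.2, 1, self.GRID)
        assert t.n_at_risk[0] == 1 and t.event_interval[0] == 1

    def test_tail_absorbed_into_last_interval(self):
        t = make_targets(99.0, 1, self.GRID)
        assert t.n_at_risk[0] == 5 and t.event_interval[0] == 5

    def test_censoring_at_boundary_counts_completed_intervals(self):
        t = make_targets(3.0, 0, self.GRID)
        assert t.n_at_risk[0] == 3

    def test_matrices_are_prefix_and_event_consistent(self):
        t = make_targets([2.5, 2.5, 4.9], [1, 0, 1], self.GRID)
        R, D = t.matrices()
        np.testing.assert_array_equal(R[0], [1, 1, 1, 0, 0])
        np.testing.assert_array_equal(D[0], [0, 0, 1, 0, 0])
        np.testing.assert_array_equal(R[1], [1, 1, 0, 0, 0])
        assert D[1].sum() == 0
        assert (D <= R).all()


def _discrete_time_sample(rng, n, hazards, grid):
    """Sample observed (time, death) from per-interval hazards (no censoring
    before the grid end)."""
    K = len(hazards)
    t = np.empty(n)
    d = np.ones(n)
    mid = (grid.boundaries[:-1] + grid.boundaries[1:]) / 2
    for i in range(n):
        for k in range(K):
            if rng.random() < hazards[k]:
                t[i] = mid[k]
                break
        else:
            t[i] = grid.boundaries[-1]
            d[i] = 0
    return t, d


class TestTraining:
    def test_recovers_planted_discrete_hazards(self):
        rng = np.random.default_rng(0)
        grid = TimeGrid(np.arange(6.0))
        n = 5000
        x = rng.integers(0, 2, n).astype(float)
        t = np.empty(n)
        d = np.empty(n)
        t0, d0 = _discrete_time_sample(rng, (x == 0).sum(), [0.1] * 5, grid)
        t1, d1 = _discrete_time_sample(rng, (x == 1).sum(), [0.2] * 5, grid)
        t[x == 0], d[x == 0] = t0, d0
        t[x == 1], d[x == 1] = t1, d1
        net = train_network(
            x[:, None], make_targets(t, d, grid),
            TrainConfig(hidden=2, decay=1e-6, epochs=600, seed=0, patience=100),
        )
        h0 = net.predict(np.array([[0.0]]))[0]
        h1 = net.predict(np.array([[1.0]]))[0]
        assert np.abs(h0 - 0.1).max() < 0.02
        assert np.abs(h1 - 0.2).max() < 0.02

    def test_large_decay_shrinks_to_pooled_hazard(self):
        rng = np.random.default_rng(1)
        grid = TimeGrid(np.arange(4.0))
        x = rng.integers(0, 2, 2000).astype(float)
        t, d = _discrete_time_sample(rng, 2000, [0.15] * 3, grid)
        targets = make_targets(t, d, grid)
        net = train_network(
            x[:, None], targets,
            TrainConfig(hidden=2, decay=100.0, epochs=300, seed=0),
        )
        R, D = targets.matrices()
        pooled = D.sum(0) / R.sum(0)
        h0 = net.predict(np.array([[0.0]]))[0]
        h1 = net.predict(np.array([[1.0]]))[0]
        assert np.abs(h0 - h1).max() < 0.01
        assert np.abs(h0 - pooled).max() < 0.03

    def test_same_seed_same_weights(self):
        rng = np.random.default_rng(2)
        grid = TimeGrid(np.arange(4.0))
        x = rng.normal(size=(500, 3))
        t, d = _discrete_time_sample(rng, 500, [0.2] * 3, grid)
        cfg = TrainConfig(hidden=4, epochs=100, seed=11)
        a = train_network(x, make_targets(t, d, grid), cfg)
        b = train_network(x, make_targets(t, d, grid), cfg)
        for qa, qb in zip((a.W1, a.b1, a.W2, a.b2), (b.W1, b.b1, b.W2, b.b2)):
            np.testing.assert_array_equal(qa, qb)

    def test_no_events_rejected(self):
        grid = TimeGrid(np.arange(3.0))
        with pytest.raises(ValueError, match="event"):
            train_network(
                np.zeros((10, 1)), make_targets(np.ones(10), np.zeros(10), grid),
                TrainConfig(hidden=2, epochs=10),
            )


class TestCrossValidation:
    def test_single_grid_point_passthrough(self):
        rng = np.random.default_rng(3)
        grid = TimeGrid(np.arange(4.0))
        X = rng.normal(size=(400, 2))
        t, d = _discrete_time_sample(rng, 400, [0.2] * 3, grid)
        cfg = TrainConfig(hidden=3, decay=1e-4, epochs=60, folds=3, seed=0)
        out = cross_validate(X, t, d, grid, cfg)
        assert out["hidden"] == 3 and out["decay"] == 1e-4
        assert len(out["results"]) == 1
        assert len(out["results"][0]["fold_scores"]) == 3

    def test_pure_noise_cv_c_near_half(self):
        rng = np.random.default_rng(4)
        grid = TimeGrid(np.arange(6.0))
        X = rng.normal(size=(2000, 5))
        t, d = _discrete_time_sample(rng, 2000, [0.12] * 5, grid)
        cfg = TrainConfig(hidden=3, decay=1e-3, epochs=100, folds=5, seed=0)
        out = cross_validate(X, t, d, grid, cfg)
        assert 0.45 <= out["results"][0]["mean_score"] <= 0.55

    def test_tie_breaks_toward_smaller_hidden_then_larger_decay(self):
        results = [
            {"hidden": 4, "decay": 1e-4, "mean_score": 0.6},
            {"hidden": 2, "decay": 1e-4, "mean_score": 0.6},
            {"hidden": 2, "decay": 1e-2, "mean_score": 0.6},
        ]
        best = select_grid_point(results)
        assert best["hidden"] == 2 and best["decay"] == 1e-2


def _constant_member(hazard: float, K: int) -> HazardNetwork:
    """A network that ignores its input and emits a constant hazard."""
    logit = np.log(hazard / (1 - hazard)) if hazard > 0 else -40.0
    return HazardNetwork(
        W1=np.zeros((1, 1)), b1=np.zeros(1),
        W2=np.zeros((1, K)), b2=np.full(K, logit),
        decay=0.0, seed=0,
    )


def _identity_design() -> DesignMatrix:
    col = ColumnSpec("diabetes", "diabetes", "indicator")
    return DesignMatrix(
        columns=(col,), column_names=("diabetes",), column_kinds=("indicator",),
        means=np.zeros(1), sds=np.ones(1), increments={}, degenerate=(),
        values=np.empty((0, 1)),
    )


class TestEnsemble:
    def test_two_constant_members_average_hazards(self, cohort_factory, record_factory):
        K = 4
        grid = TimeGrid(np.arange(0.0, K + 1))
        model = EnsembleModel(
            members=[_constant_member(0.1, K), _constant_member(0.3, K)],
            designs=[_identity_design(), _identity_design()],
            grid=grid, columns=(_identity_design().columns[0],),
        )
        cohort = cohort_factory([record_factory()])
        curve = predict_curve(model, cohort)
        np.testing.assert_allclose(curve.hazards, 0.2)
        assert curve.survival[2] == pytest.approx(0.64)

    def test_member_order_invariance(self, cohort_factory, record_factory):
        K = 3
        grid = TimeGrid(np.arange(0.0, K + 1))
        members = [_constant_member(h, K) for h in (0.05, 0.2, 0.4)]
        designs = [_identity_design() for _ in members]
        cohort = cohort_factory([record_factory()])
        a = EnsembleModel(members, designs, grid, designs[0].columns).hazards(cohort)
        b = EnsembleModel(members[::-1], designs, grid, designs[0].columns).hazards(cohort)
        np.testing.assert_allclose(a, b)

    def test_m1_ensemble_equals_single_member(self, small_cohort):
        imp = ImputationSet([small_cohort], m=1, strata="era", seed=0)
        cfg = TrainConfig(hidden=3, epochs=60, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_ensemble(imp, cfg, K=4)
        X = model.designs[0].transform(small_cohort)
        np.testing.assert_allclose(
            model.hazards(small_cohort), model.members[0].predict(X)
        )

    def test_ten_imputations_give_ten_members(self, masked_cohort):
        imp = impute_probability(masked_cohort, m=10, seed=0)
        cfg = TrainConfig(hidden=2, epochs=40, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_ensemble(imp, cfg, K=3)
        assert model.M == 10

    def test_members_on_identical_data_differ_only_by_init(self):
        cohort, _ = synth.generate_cohort(synth.GeneratorConfig(n=1000, seed=7))
        imp = ImputationSet([cohort] * 3, m=3, strata="era", seed=0)
        cfg = TrainConfig(hidden=3, epochs=250, seed=0, patience=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_ensemble(imp, cfg, K=4)
        probe = model.hazards(cohort)
        per_member = np.stack(
            [m.predict(d.transform(cohort)) for m, d in zip(model.members, model.designs)]
        )
        spread = per_member.std(axis=0).mean()
        assert spread < 0.1  # committee members agree up to init noise
        assert np.all((probe > 0) & (probe < 1))


class TestCurves:
    def test_zero_hazards_survival_one_and_flagged_median(self):
        grid = TimeGrid(np.array([0.0, 10.0]))
        curve = SurvivalCurve(np.zeros(1), grid)
        assert (curve.survival == 1).all()
        med, extrapolated = median_survival(curve)
        assert extrapolated and med == pytest.approx(20.0)  # horizon cap

    def test_median_interpolation_hand_example(self):
        grid = TimeGrid(np.array([0.0, 10.0]))
        curve = SurvivalCurve(np.array([0.75]), grid)  # S_1 = 0.25
        med, extrapolated = median_survival(curve)
        assert not extrapolated
        assert med == pytest.approx(10 * (1 - 0.5) / (1 - 0.25))

    def test_median_exact_boundary_crossing(self):
        grid = TimeGrid(np.array([0.0, 2.0, 4.0]))
        curve = SurvivalCurve(np.array([0.5, 0.5]), grid)
        med, extrapolated = median_survival(curve)
        assert med == pytest.approx(2.0) and not extrapolated

    def test_constant_hazard_closed_form(self):
        grid = TimeGrid(np.arange(0.0, 26.0))
        curve = SurvivalCurve(np.full(25, 0.1), grid)
        assert curve.survival[-1] == pytest.approx(0.9**25)
        assert curve.survival[-1] == pytest.approx(0.0718, abs=1e-4)

    def test_survival_at_boundaries_and_midpoint(self):
        grid = TimeGrid(np.array([0.0, 2.0, 4.0]))
        curve = SurvivalCurve(np.array([0.2, 0.5]), grid)
        assert survival_at(curve, 0.0) == (1.0, False)
        assert survival_at(curve, 2.0)[0] == pytest.approx(0.8)
        assert survival_at(curve, 3.0)[0] == pytest.approx((0.8 + 0.4) / 2)

    def test_survival_beyond_grid_is_flagged(self):
        grid = TimeGrid(np.array([0.0, 1.0]))
        curve = SurvivalCurve(np.array([0.1]), grid)
        p, extrapolated = survival_at(curve, 3.0)
        assert extrapolated and 0 < p < 0.9

    def test_vectorized_median_matches_scalar(self):
        rng = np.random.default_rng(5)
        grid = TimeGrid(np.array([0.0, 1.0, 3.0, 7.0, 12.0]))
        hz = rng.uniform(0.02, 0.6, size=(50, 4))
        meds = median_from_hazards(hz, grid)
        for i in range(50):
            med, _ = median_survival(SurvivalCurve(hz[i], grid))
            assert meds[i] == pytest.approx(med)

    def test_vectorized_survival_probability_matches_scalar(self):
        rng = np.random.default_rng(6)
        grid = TimeGrid(np.array([0.0, 1.0, 3.0, 7.0]))
        hz = rng.uniform(0.05, 0.5, size=(20, 3))
        for t in (0.0, 0.4, 1.0, 2.0, 6.9, 8.5):
            vals = survival_probability(hz, grid, t)
            for i in range(20):
                s, _ = survival_at(SurvivalCurve(hz[i], grid), t)
                assert vals[i] == pytest.approx(s)

    @given(
        hz=hnp.arrays(
            float, st.integers(1, 12),
            elements=st.floats(1e-6, 1 - 1e-6),
        )
    )
    def test_survival_curve_invariants(self, hz):
        grid = TimeGrid(np.arange(0.0, len(hz) + 1))
        curve = SurvivalCurve(hz, grid)
        S = curve.survival
        assert S[0] == 1.0
        assert (np.diff(S) <= 1e-15).all()
        assert ((S[1:] > 0) & (S[1:] <= 1)).all()
        med, _ = median_survival(curve)
        assert med >= 0


class TestSerialization:
    def test_bit_exact_reload(self, tmp_path, small_cohort):
        imp = ImputationSet([small_cohort], m=1, strata="era", seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_ensemble(imp, TrainConfig(hidden=3, epochs=50, seed=0), K=4)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(
            model.hazards(small_cohort), back.hazards(small_cohort)
        )
        np.testing.assert_array_equal(model.grid.boundaries, back.grid.boundaries)
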
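import numpy as np
import pandas as pd
import pytest

from restwatch import survival_models as svm
from restwatch.errors import AllTied, DegenerateFeature, NoEvents, ZeroVariance
from restwatch.feature_assembly import FeatureTable
from restwatch.synthetic import simulate_survival


def make_table(n=60, p=5, beta=None, seed=0, censor=365.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
    time, event, _ = simulate_survival(X, beta, rng, admin_censor_day=censor)
    return FeatureTable.from_arrays(X, time, event)


class TestCoxLogLikelihood:
    def test_matches_lifelines_at_fixed_beta(self):
        from lifelines import CoxPHFitter

        table = make_table(n=80, p=3, beta=np.array([0.5, -0.5, 0.0]), seed=2)
        df = table.X.copy()
        df["T"] = table.time
        df["E"] = table.event
        cph = CoxPHFitter()
        cph.fit(df, "T", "E")
        beta_hat = cph.params_.to_numpy()
        ours = svm.cox_log_partial_likelihood(
            table.X.to_numpy(), table.time, table.event, beta_hat
        )
        assert ours == pytest.approx(cph.log_likelihood_, rel=1e-6)

    def test_maximised_at_the_mle(self):
        from lifelines import CoxPHFitter

        table = make_table(n=100, p=2, beta=np.array([0.8, -0.8]), seed=3)
        df = table.X.copy()
        df["T"] = table.time
        df["E"] = table.event
        cph = CoxPHFitter()
        cph.fit(df, "T", "E")
        bh = cph.params_.to_numpy()
        X = table.X.to_numpy()
        ll_star = svm.cox_log_partial_likelihood(X, table.time, table.event, bh)
        for delta in ([0.1, 0], [0, -0.1], [0.05, 0.05]):
            assert ll_star >= svm.cox_log_partial_likelihood(
                X, table.time, table.event, bh + np.array(delta)
            )


class TestFitPenalisedCox:
    @pytest.mark.parametrize("alpha", [0.01, 0.5, 0.99])
    def test_all_zero_at_lambda_max(self, alpha):
        table = make_table(n=50, p=8, beta=np.r_[np.ones(2), np.zeros(6)], seed=4)
        fit = svm.fit_penalised_cox(table, alpha, folds=5, seed=1)
        Xs, _, _ = svm._standardise(table.X.to_numpy())
        _, coef_path = svm._fit_path(
            Xs, table.time, np.asarray(table.event, bool), alpha
        )
        assert np.all(coef_path[:, 0] == 0.0)  # full-shrinkage limit
        assert fit.lambda_min in fit.lambda_grid

    def test_lasso_nonzero_at_most_n(self):
        # p > n: the lasso saturates at n selected variables
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 66))
        beta = np.zeros(66)
        beta[:10] = 0.8
        time, event, _ = simulate_survival(X, beta, rng)
        table = FeatureTable.from_arrays(X, time, event)
        fit = svm.fit_penalised_cox(table, 0.99, folds=5, seed=1)
        assert len(fit.nonzero_set) <= 50

    def test_no_penalty_limit_matches_unpenalised_cox(self):
        from lifelines import CoxPHFitter

        table = make_table(n=500, p=2, beta=np.array([0.7, -0.4]), seed=6)
        Xs, mu, sd = svm._standardise(table.X.to_numpy())
        df = pd.DataFrame(Xs, columns=["a", "b"])
        df["T"] = table.time
        df["E"] = table.event
        cph = CoxPHFitter()
        cph.fit(df, "T", "E")
        # short grid: a long path triggers the solver's deviance-saturation
        # stop before reaching the smallest lambdas
        grid = np.array([1e-4, 5e-5, 1e-5, 5e-6, 1e-6])
        _, coef_path = svm._fit_path(
            Xs, table.time, np.asarray(table.event, bool), 0.99, lambdas=grid
        )
        assert np.allclose(coef_path[:, -1], cph.params_.to_numpy(), atol=1e-3)

    def test_zero_variance_feature_raises(self):
        table = make_table(n=30, p=3, seed=7)
        table.X.iloc[:, 1] = 5.0
        with pytest.raises(DegenerateFeature):
            svm.fit_penalised_cox(table, 0.5, folds=5, seed=1)

    def test_no_events_raises(self):
        table = make_table(n=30, p=3, seed=8, censor=0.0001)
        with pytest.raises(NoEvents):
            svm.fit_penalised_cox(table, 0.5, folds=5, seed=1)

    def test_ridge_coef_norm_monotone_along_path(self):
        table = make_table(n=80, p=5, beta=np.array([1, -1, 0.5, 0, 0]), seed=9)
        Xs, _, _ = svm._standardise(table.X.to_numpy())
        grid, coef_path = svm._fit_path(Xs, table.time, np.asarray(table.event, bool), 0.01)
        norms = np.abs(coef_path).sum(axis=0)
        # lambda decreases along the grid -> shrinkage decreases -> norm grows
        assert np.all(np.diff(norms) >= -1e-8)


class TestOutOfFoldHazards:
    def test_row_order_invariance(self):
        table = make_table(n=40, p=6, beta=np.r_[np.ones(2), np.zeros(4)], seed=10)
        cv1 = svm.out_of_fold_hazards(table, 0.99, folds=5, seed=3, inner_folds=3)
        perm = np.random.default_rng(0).permutation(40)
        t2 = FeatureTable.from_arrays(
            table.X.to_numpy()[perm], table.time[perm], table.event[perm],
            ids=[table.ids[i] for i in perm],
        )
        cv2 = svm.out_of_fold_hazards(t2, 0.99, folds=5, seed=3, inner_folds=3)
        pd.testing.assert_series_equal(cv1.hazards.sort_index(), cv2.hazards.sort_index())

    def test_hazards_positive_and_complete(self):
        table = make_table(n=40, p=6, beta=np.r_[np.ones(2), np.zeros(4)], seed=11)
        cv = svm.out_of_fold_hazards(table, 0.5, folds=5, seed=1, inner_folds=3)
        assert cv.hazards.notna().all()
        assert (cv.hazards > 0).all()
        assert len(cv.hazards) == 40

    def test_planted_predictor_consistently_selected(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(100, 8))
        beta = np.zeros(8)
        beta[0] = 2.0  # single very strong predictor
        time, event, _ = simulate_survival(X, beta, rng)
        table = FeatureTable.from_arrays(X, time, event)
        cv = svm.out_of_fold_hazards(table, 0.99, folds=5, seed=2, inner_folds=3)
        assert "x0" in cv.consistently_selected

    def test_null_data_rarely_consistent(self):
        hits = 0
        for seed in range(5):
            table = make_table(n=50, p=10, seed=100 + seed)
            cv = svm.out_of_fold_hazards(table, 0.99, folds=5, seed=seed, inner_folds=3)
            hits += len(cv.consistently_selected) > 0
        assert hits <= 2  # no signal -> consistent set empty in most seeds

    def test_blindness_to_own_outcome(self):
        # a participant's hazard comes from a model trained without them, so
        # changing their survival time cannot move their own predicted hazard
        table = make_table(n=30, p=4, beta=np.array([1.0, 0, 0, 0]), seed=13)
        cv = svm.out_of_fold_hazards(table, 0.99, folds=3, seed=5, inner_folds=3)
        victim = table.ids[0]
        time2 = table.time.copy()
        time2[0] = time2[0] * 3 + 7  # event flag untouched: folds stay identical
        t2 = FeatureTable.from_arrays(
            table.X.to_numpy(), time2, table.event, ids=table.ids
        )
        cv2 = svm.out_of_fold_hazards(t2, 0.99, folds=3, seed=5, inner_folds=3)
        assert cv2.fold_of == cv.fold_of
        assert cv2.hazards[victim] == pytest.approx(cv.hazards[victim], rel=1e-12)


class TestEvaluation:
    def test_median_split_identical_groups_statistic_zero(self):
        time = np.array([5, 10, 15, 20, 5, 10, 15, 20], dtype=float)
        event = np.ones(8, dtype=int)
        hazards = np.array([1, 1, 1, 1, 2, 2, 2, 2], dtype=float)
        res = svm.km_median_split_eval(hazards, time, event)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_ties_go_low(self):
        hazards = np.array([1.0, 1.0, 1.0, 2.0])
        time = np.arange(4, dtype=float) + 1
        event = np.ones(4, dtype=int)
        res = svm.km_median_split_eval(hazards, time, event)
        assert res["n_low"] == 3 and res["n_high"] == 1

    def test_all_tied_raises(self):
        with pytest.raises(AllTied):
            svm.km_median_split_eval(np.ones(6), np.arange(6.0) + 1, np.ones(6, int))

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(14)
        n = 50
        hazards = np.r_[np.full(25, 0.5), np.full(25, 3.0)]
        time = np.r_[rng.exponential(300, 25), rng.exponential(50, 25)]
        event = np.ones(n, dtype=int)
        res = svm.km_median_split_eval(hazards, time, event)
        assert res["p"] < 0.001

    def test_correlation_matches_formula_oracle(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(100, 30)
        h = 1.0 / (np.argsort(np.argsort(t)) + 1.0)  # inverse rank of survival
        res = svm.hazard_survival_correlation(h, t)
        hm, tm = h.mean(), t.mean()
        expect = np.sum((h - hm) * (t - tm)) / np.sqrt(
            np.sum((h - hm) ** 2) * np.sum((t - tm) ** 2)
        )
        assert res["r"] == pytest.approx(float(expect), abs=1e-12)
        assert res["r"] < -0.4  # strongly negative (rank inversion, skewed times)

    def test_constant_hazards_raise(self):
        with pytest.raises(ZeroVariance):
            svm.hazard_survival_correlation(np.ones(10), np.arange(10.0) + 1)

    def test_negative_correlation_on_well_specified_cohort(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(120, 4))
        beta = np.array([1.0, -1.0, 0.5, 0.0])
        time, event, _ = simulate_survival(X, beta, rng)
        table = FeatureTable.from_arrays(X, time, event)
        cv = svm.out_of_fold_hazards(table, 0.5, folds=5, seed=1, inner_folds=3)
        res = svm.hazard_survival_correlation(cv.hazards.to_numpy(), table.time)
        assert res["r"] < 0
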
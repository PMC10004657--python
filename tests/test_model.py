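"""Design construction, winsorization, GEE fitting, prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ioh_ponv.features import CharacterizationSpec
from ioh_ponv.model import (GEEFit, build_design, fit_gee_logistic,
                            predict_prob, winsorize_99)

TU50 = CharacterizationSpec("time_under", 50)
SUS5 = CharacterizationSpec("sustained_lowest", 5)


def _percentile_oracle(sorted_vals, q):
    """Linear-interpolation percentile from order statistics."""
    h = (len(sorted_vals) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(sorted_vals) - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


class TestWinsorize:
    def test_caps_only_top_of_a_range(self):
        x = np.arange(100.0)
        capped, cap = winsorize_99(x)
        assert cap == pytest.approx(98.01)
        assert capped[-1] == pytest.approx(98.01)
        np.testing.assert_array_equal(capped[:-1], x[:-1])

    def test_identical_values_unchanged(self):
        x = np.full(50, 7.0)
        capped, cap = winsorize_99(x)
        np.testing.assert_array_equal(capped, x)

    def test_cap_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(3.0, 500)
        _, cap = winsorize_99(x)
        assert cap == pytest.approx(_percentile_oracle(np.sort(x), 99.0))

    def test_stored_cap_reused_on_new_data(self):
        train = np.arange(100.0)
        _, cap = winsorize_99(train)
        held_out, _ = winsorize_99(np.array([250.0, 5.0]), cap=cap)
        np.testing.assert_allclose(held_out, [98.01, 5.0])


class TestBuildDesign:
    def test_male_cases_zero_age_sex_interaction(self, small_cohort_prepared):
        cases, _, table = small_cohort_prepared
        X, _ = build_design(cases, table["time_under_50"], TU50)
        male = cases["female"] == 0
        for c in [c for c in X.columns if c.startswith("agefem")]:
            assert (X.loc[male, c] == 0).all()
            assert (X.loc[~male, c] != 0).any()

    def test_zero_exposure_sets_indicator_only_for_zero_inflated(self, small_cohort_prepared):
        cases, grids, table = small_cohort_prepared
        e = table["time_under_50"]
        X, _ = build_design(cases, e, TU50)
        assert "exp_zero" in X.columns
        zero = e == 0
        assert (X.loc[zero, "exp_zero"] == 1).all()
        assert (X.loc[~zero, "exp_zero"] == 0).all()

    def test_lowest_family_has_one_column_fewer(self, small_cohort_prepared):
        # documented layout: identical adjustment block, no zero indicator
        cases, grids, _ = small_cohort_prepared
        from ioh_ponv.features import compute_feature_table
        tab = compute_feature_table(grids, [SUS5, CharacterizationSpec("time_under", 70)])
        X_sus, _ = build_design(cases, tab["sustained_lowest_5"], SUS5)
        X_tu, _ = build_design(cases, tab["time_under_70"],
                               CharacterizationSpec("time_under", 70))
        assert set(X_tu.columns) - set(X_sus.columns) == {"exp_zero"}
        assert len(X_tu.columns) == len(X_sus.columns) + 1

    def test_stored_bases_give_identical_columns_on_held_out(self, small_cohort_prepared):
        cases, _, table = small_cohort_prepared
        half = cases.index[: len(cases) // 2]
        rest = cases.index[len(cases) // 2:]
        X_tr, bases = build_design(cases.loc[half], table.loc[half, "time_under_50"], TU50)
        X_te, _ = build_design(cases.loc[rest], table.loc[rest, "time_under_50"],
                               TU50, bases=bases)
        assert list(X_te.columns) == list(X_tr.columns)

    def test_missing_exposure_rejected(self, small_cohort_prepared):
        cases, _, table = small_cohort_prepared
        e = table["time_under_50"].copy()
        e.iloc[0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design(cases, e, TU50)


def _toy_logistic_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.4, n).astype(float)
    lp = -0.5 + 0.8 * x1 - 0.6 * x2
    y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
    X = pd.DataFrame({"intercept": 1.0, "x1": x1, "x2": x2})
    return X, y


class TestGEEFit:
    def test_singleton_clusters_reduce_to_ordinary_logistic(self):
        X, y = _toy_logistic_data()
        clusters = np.arange(len(y))  # every case its own patient
        fit = fit_gee_logistic(X, y, clusters)
        glm = sm.Logit(y, X.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(fit.params, glm.params, rtol=1e-6, atol=1e-8)

    def test_intercept_only_recovers_logit_of_mean(self):
        rng = np.random.default_rng(2)
        y = rng.binomial(1, 0.3, 500)
        X = pd.DataFrame({"intercept": np.ones(len(y))})
        fit = fit_gee_logistic(X, y, np.arange(len(y)))
        assert fit.params[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_constant_outcome_rejected(self):
        X, _ = _toy_logistic_data(100)
        with pytest.raises(ValueError, match="constant"):
            fit_gee_logistic(X, np.ones(100), np.arange(100))

    def test_exchangeable_correlation_positive_on_clustered_cohort(self, small_cohort_prepared):
        cases, _, table = small_cohort_prepared
        X, bases = build_design(cases, table["time_under_50"], TU50)
        fit = fit_gee_logistic(X, cases["ponv"], cases["patient_id"], bases=bases)
        assert -1 < fit.exchangeable_corr < 1
        assert fit.converged
        assert fit.n_clusters == cases["patient_id"].nunique()
        # robust covariance is symmetric PSD
        np.testing.assert_allclose(fit.cov_robust, fit.cov_robust.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(fit.cov_robust) > -1e-10)

    def test_serialization_round_trip(self, tmp_path, small_cohort_prepared):
        cases, _, table = small_cohort_prepared
        X, bases = build_design(cases, table["time_under_50"], TU50)
        fit = fit_gee_logistic(X, cases["ponv"], cases["patient_id"], bases=bases)
        path = tmp_path / "fit.json"
        fit.save_json(path)
        back = GEEFit.load_json(path)
        np.testing.assert_array_equal(back.params, fit.params)
        assert back.columns == fit.columns
        assert back.bases.exposure_cap == fit.bases.exposure_cap


class TestPredict:
    def test_zero_coefficients_give_half(self):
        X, y = _toy_logistic_data(50)
        fit = GEEFit(columns=tuple(X.columns), params=np.zeros(3),
                     cov_robust=np.eye(3), exchangeable_corr=0.0,
                     n_cases=50, n_clusters=50, converged=True)
        np.testing.assert_array_equal(predict_prob(fit, X), np.full(50, 0.5))

    def test_extreme_linear_predictor_stays_inside_unit_interval(self):
        X = pd.DataFrame({"intercept": [1.0], "x": [1e6]})
        fit = GEEFit(columns=("intercept", "x"), params=np.array([0.0, 1.0]),
                     cov_robust=np.eye(2), exchangeable_corr=0.0,
                     n_cases=1, n_clusters=1, converged=True)
        p = predict_prob(fit, X)
        assert 0 < p[0] < 1 and p[0] > 0.999999

    def test_matches_rowwise_dot_product(self):
        X, y = _toy_logistic_data(30, seed=5)
        beta = np.array([0.2, -0.7, 1.1])
        fit = GEEFit(columns=tuple(X.columns), params=beta, cov_robust=np.eye(3),
                     exchangeable_corr=0.0, n_cases=30, n_clusters=30, converged=True)
        p = predict_prob(fit, X)
        for i in range(len(X)):
            lp = float(np.dot(X.iloc[i].to_numpy(), beta))
            assert p[i] == pytest.approx(1 / (1 + np.exp(-lp)))

    def test_column_mismatch_rejected(self):
        X, _ = _toy_logistic_data(10)
        fit = GEEFit(columns=("intercept", "other"), params=np.zeros(2),
                     cov_robust=np.eye(2), exchangeable_corr=0.0,
                     n_cases=10, n_clusters=10, converged=True)
        with pytest.raises(ValueError, match="columns"):
            predict_prob(fit, X)


def test_predictions_invariant_to_affine_covariate_recoding(small_cohort_prepared, monkeypatch):
    """Rescaling age (years -> decades) must not change fitted risks."""
    cases, _, table = small_cohort_prepared
    e = table["time_under_50"]
    X, b = build_design(cases, e, TU50)
    fit = fit_gee_logistic(X, cases["ponv"], cases["patient_id"], bases=b)
    p = predict_prob(fit, X)

    recoded = cases.copy()
    recoded["age"] = cases["age"] / 10.0 + 3.0
    # bypass the >= 18 screen: the recode is a unit change, not new data
    import ioh_ponv.model as m
    monkeypatch.setattr(m, "validate_case_frame", lambda df: None)
    X2, b2 = build_design(recoded, e, TU50)
    fit2 = fit_gee_logistic(X2, recoded["ponv"], recoded["patient_id"], bases=b2)
    p2 = predict_prob(fit2, X2)
    np.testing.assert_allclose(p2, p, atol=2e-5)


def test_cluster_robust_se_exceeds_iid_se_for_patient_level_covariates():
    """Under strong within-patient correlation, the sandwich SE of a
    patient-level covariate must exceed the iid (ordinary logistic) SE;
    covariates varying within clusters may go the other way."""
    from ioh_ponv.pipeline import preprocess_cohort
    from ioh_ponv.features import compute_feature_table
    from ioh_ponv.simulate import SimulationConfig, simulate_cohort

    coh = simulate_cohort(SimulationConfig(n_patients=400, seed=77, patient_sd=2.0,
                                           surgeries_per_patient_rate=3.0))
    grids, _, _ = preprocess_cohort(coh.series)
    cases = coh.cases.loc[list(grids)]
    table = compute_feature_table(grids, [TU50]).loc[cases.index]
    X, bases = build_design(cases, table[TU50.label], TU50)
    fit = fit_gee_logistic(X, cases["ponv"], cases["patient_id"], bases=bases)
    assert fit.exchangeable_corr > 0.3  # clustering is genuinely strong here
    se_iid = np.sqrt(np.diag(sm.Logit(cases["ponv"].to_numpy(float),
                                      X.to_numpy(float)).fit(disp=0).cov_params()))
    cols = list(X.columns)
    for c in ("smoker", "comorbidity_pos"):  # constant within patient
        i = cols.index(c)
        assert fit.se()[i] > 1.2 * se_iid[i], c
    # the model-based (naive) covariance is also carried for diagnostics
    assert fit.cov_naive is not None and fit.cov_naive.shape == fit.cov_robust.shape
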
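"""Synthetic cohort generator: sampling schemes, artifacts, truth, calibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ioh_ponv.features import CharacterizationSpec, compute_exposure
from ioh_ponv.preprocess import interpolate_to_grid
from ioh_ponv.simulate import (MapProcess, SimulationConfig, TrueEffect,
                               inject_artifacts, simulate_cohort,
                               simulate_map_trace)


class TestMapTrace:
    def test_invasive_sampling_count(self):
        s = simulate_map_trace(60, "invasive", MapProcess(), seed=0)
        assert len(s) == 241  # floor(60*60/15) + 1
        np.testing.assert_allclose(np.diff(s.t), 15.0)

    def test_degenerate_process_is_exactly_constant(self):
        proc = MapProcess(baseline=80, dip_depth=0, noise_sd=0)
        s = simulate_map_trace(30, "invasive", proc, seed=1)
        np.testing.assert_array_equal(s.map, np.full(121, 80.0))
        # SBP/DBP stay MAP-consistent: DBP + PP/3 == MAP
        np.testing.assert_allclose(s.dbp + (s.sbp - s.dbp) / 3, s.map)

    def test_non_invasive_gaps_three_to_five_minutes(self):
        s = simulate_map_trace(120, "non_invasive", MapProcess(), seed=2)
        gaps = np.diff(s.t)
        assert ((gaps >= 180) & (gaps <= 300)).all()
        assert s.t[0] == 0.0

    def test_stationary_moments_match_analytic_oracle(self):
        # with no dip the trace is a stationary AR(1): mean = baseline and
        # Var(sample mean) ~= sd^2/n * (1+phi)/(1-phi)
        proc = MapProcess(baseline=80, dip_depth=0, noise_sd=6,
                          reversion_per_min=0.2)
        means = [simulate_map_trace(120, "invasive", proc, seed=s).map.mean()
                 for s in range(30)]
        n = 481
        phi = np.exp(-0.2 * 0.25)
        sd_mean = 6.0 / np.sqrt(n) * np.sqrt((1 + phi) / (1 - phi))
        assert abs(np.mean(means) - 80.0) < 3 * sd_mean / np.sqrt(30)
        assert np.std(means) < 3 * sd_mean

    def test_induction_dip_lowers_early_minutes(self):
        proc = MapProcess(baseline=80, dip_depth=20, dip_tau_min=5, noise_sd=0)
        s = simulate_map_trace(60, "invasive", proc, seed=3)
        assert s.map[0] == pytest.approx(60.0)
        assert s.map[-1] > 78.0  # dip has decayed
        assert np.all(np.diff(s.map) >= 0)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration_min"):
            simulate_map_trace(0, "invasive", MapProcess(), seed=0)


class TestInjectArtifacts:
    def test_rate_zero_is_identity(self):
        s = simulate_map_trace(60, "invasive", MapProcess(), seed=4)
        out, labels = inject_artifacts(s, 0.0, seed=5)
        assert out is s or np.array_equal(out.map, s.map)
        assert labels.empty

    def test_injected_counts_are_poisson_with_requested_mean(self):
        s = simulate_map_trace(60, "invasive", MapProcess(), seed=6)
        counts = [len(inject_artifacts(s, 6.0, seed=i)[1]) for i in range(300)]
        assert np.mean(counts) == pytest.approx(6.0, abs=3 * np.sqrt(6 / 300))

    def test_rule_prototypes_violate_their_rule(self):
        s = simulate_map_trace(120, "invasive", MapProcess(), seed=7)
        out, labels = inject_artifacts(s, 10.0, seed=8)
        t_to_idx = {t: i for i, t in enumerate(out.t)}
        for _, row in labels.iterrows():
            i = t_to_idx[row["t"]]
            sbp, dbp = out.sbp[i], out.dbp[i]
            rule = int(row["rule"])
            if rule == 1:
                assert sbp >= 300
            elif rule == 2:
                assert sbp <= 20
            elif rule == 3:
                assert dbp <= 5
            elif rule == 4:
                assert dbp >= 225
            elif rule == 5:
                assert sbp <= dbp + 5
            else:  # extreme deviation stays inside the raw-value limits
                assert 20 < sbp < 300 and 5 < dbp < 225

    def test_times_remain_strictly_increasing(self):
        s = simulate_map_trace(45, "non_invasive", MapProcess(), seed=9)
        out, _ = inject_artifacts(s, 20.0, seed=10)
        assert np.all(np.diff(out.t) > 0)


class TestCohort:
    def test_null_model_gives_half_event_rate(self):
        cfg = SimulationConfig(
            n_patients=1500, seed=21, intercept=0.0, patient_sd=0.0,
            confounder_betas={k: 0.0 for k in SimulationConfig().confounder_betas},
            true_effect=TrueEffect(beta_per_unit=0.0, beta_nonzero=0.0),
        )
        coh = simulate_cohort(cfg)
        n = len(coh.cases)
        assert abs(coh.cases["ponv"].mean() - 0.5) < 3 * 0.5 / np.sqrt(n)
        assert np.allclose(coh.truth["true_prob"], 0.5)

    def test_unit_rate_gives_one_surgery_per_patient(self):
        coh = simulate_cohort(SimulationConfig(n_patients=50, seed=22,
                                               surgeries_per_patient_rate=1.0))
        assert len(coh.cases) == 50
        assert coh.cases["patient_id"].is_unique

    def test_independent_logistic_recovers_confounder_effect(self):
        # patient_sd = 0 and one surgery each: ordinary logistic regression
        # on the true covariates must recover the female coefficient
        cfg = SimulationConfig(n_patients=1500, seed=23, patient_sd=0.0,
                               surgeries_per_patient_rate=1.0)
        coh = simulate_cohort(cfg)
        c = coh.cases
        X = np.column_stack([
            np.ones(len(c)), c["female"], (c["age"] - 53) / 10, c["smoker"],
            c["volatile"], c["ondansetron_ppx"], c["dexamethasone_ppx"],
            c["comorbidity_pos"], c["risk_surgery"], c["duration_h"] - 1.7,
            (coh.truth["true_exposure"] > 0).astype(float), coh.truth["true_exposure"],
        ])
        res = sm.Logit(c["ponv"].to_numpy(), X).fit(disp=0)
        se = np.sqrt(np.diag(res.cov_params()))
        assert abs(res.params[1] - 0.9) < 2 * se[1]          # female
        assert abs(res.params[11] - 0.05) < 2 * se[11]       # per-minute exposure slope

    def test_truth_consistency_with_characterization_module(self, small_cohort):
        spec = small_cohort.config.true_effect.spec
        for cid in list(small_cohort.clean_series)[:40]:
            grid = interpolate_to_grid(small_cohort.clean_series[cid])
            assert compute_exposure(grid, spec) == small_cohort.truth.loc[cid, "true_exposure"]

    def test_marginal_calibration(self, calibration_cohort):
        cases, truth = calibration_cohort.cases, calibration_cohort.truth
        n = len(cases)
        assert n >= 2000
        se = np.sqrt((truth["true_prob"] * (1 - truth["true_prob"])).sum()) / n
        assert abs(cases["ponv"].mean() - truth["true_prob"].mean()) < 3 * se

    def test_same_seed_bit_identical_different_seed_not(self):
        cfg = SimulationConfig(n_patients=60, seed=24)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.cases, b.cases)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        cid = a.cases["case_id"].iloc[0]
        np.testing.assert_array_equal(a.series[cid].map, b.series[cid].map)
        c = simulate_cohort(SimulationConfig(n_patients=60, seed=25))
        assert not a.truth["true_exposure"].equals(c.truth["true_exposure"])

    def test_every_case_has_one_series_and_shared_patient_ids(self, small_cohort):
        cases = small_cohort.cases
        assert set(cases["case_id"]) == set(small_cohort.series)
        assert set(cases["case_id"]) == set(small_cohort.clean_series)
        multi = cases.groupby("patient_id").size()
        assert (multi >= 1).all()
        assert ((small_cohort.truth["true_prob"] > 0) &
                (small_cohort.truth["true_prob"] < 1)).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(monitoring_mix=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(surgeries_per_patient_rate=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(patient_sd=-1)
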
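"""Synthetic perioperative cohorts with clustered PONV outcomes.

No public perioperative database exists for this analysis, so every
stage is exercised on simulated cohorts that reproduce the statistical
structure the pipeline assumes:

- per-surgery MAP traces from a mean-reverting (AR(1)-discretized)
  process around a per-case baseline, with an exponentially decaying
  induction dip in the first minutes, sampled at 15 s (invasive) or at
  3-5-min cuff intervals (non-invasive);
- systolic/diastolic channels tied to MAP through a lognormal pulse
  pressure (SBP = MAP + 2/3 PP, DBP = MAP - PP/3);
- monitor/transducer artifacts injected at a Poisson rate, each
  violating exactly one of the six rejection rules;
- several surgeries per patient (1 + Poisson), patient-level covariates
  shared across a patient's cases;
- a binary PONV outcome whose conditional log-odds combine confounder
  effects, a hypotension-exposure effect (any-exposure jump plus a
  per-unit slope), and a Normal patient-level random intercept.

The generator records ground truth (the exposure computed from the
clean gridded trace via :mod:`ioh_ponv.features`, the event probability,
and artifact labels) so recovery tests have an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .features import CharacterizationSpec, compute_exposure
from .preprocess import GRID_STEP_S, BPSeries, interpolate_to_grid

#: artifact prototypes: raw values violating exactly one of rules 1-5
_RULE_SAMPLES = {
    1: (310.0, 80.0),   # SBP >= 300
    2: (15.0, 8.0),     # SBP <= 20 (DBP kept clear of rules 3 and 5)
    3: (120.0, 4.0),    # DBP <= 5
    4: (290.0, 230.0),  # DBP >= 225 (SBP < 300, not within DBP+5)
    5: (82.0, 80.0),    # SBP <= DBP + 5
}


@dataclass(frozen=True)
class MapProcess:
    """Mean-reverting MAP model: stationary mean/SD plus induction dip.

    ``noise_sd`` is the stationary SD of the process (mmHg);
    ``reversion_per_min`` the mean-reversion rate (1/min); the dip
    subtracts ``dip_depth * exp(-t / dip_tau_min)`` from the mean.
    """

    baseline: float = 79.0
    dip_depth: float = 20.0
    dip_tau_min: float = 8.0
    reversion_per_min: float = 0.05
    noise_sd: float = 7.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.reversion_per_min < 0 or self.dip_tau_min <= 0:
            raise ValueError("map_process rates and SDs must be non-negative")


@dataclass(frozen=True)
class TrueEffect:
    """Generative hypotension effect on the conditional log-odds of PONV."""

    spec: CharacterizationSpec = field(
        default_factory=lambda: CharacterizationSpec("time_under", 50))
    beta_per_unit: float = 0.05
    beta_nonzero: float = 0.2


#: conditional log-odds confounder coefficients; age is per decade from 53,
#: duration per hour from 1.7 h (so the intercept is the log-odds of a
#: 53-year-old male smoker reference case)
DEFAULT_CONFOUNDER_BETAS = {
    "female": 0.9,
    "age_per_decade": -0.05,
    "smoker": -0.35,
    "volatile": 0.3,
    "ondansetron_ppx": -0.3,
    "dexamethasone_ppx": -0.3,
    "comorbidity_pos": 0.1,
    "risk_surgery": 0.55,
    "duration_per_h": 0.25,
}

#: covariate marginals approximating the cohort the analysis emulates
DEFAULT_MARGINALS = {
    "female": 0.545,
    "age_mean": 53.0, "age_sd": 17.0, "age_min": 18.0, "age_max": 95.0,
    "smoker": 0.325,
    "volatile": 0.644,
    "ondansetron_ppx": 0.30,
    "dexamethasone_ppx": 0.25,
    "asa_probs": (0.48, 0.26, 0.24, 0.02),
    "comorbidity_pos": 0.35,
    "risk_surgery": 0.177,
    "history_ponv": 0.153,
    "postop_opioids": 0.559,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 1000
    surgeries_per_patient_rate: float = 1.37
    monitoring_mix: float = 0.2  # fraction invasive
    duration_median_min: float = 100.0
    duration_log_sd: float = 0.45
    duration_min_min: float = 20.0
    duration_max_min: float = 480.0
    map_process: MapProcess = field(default_factory=MapProcess)
    baseline_between_sd: float = 5.0
    artifact_rate_per_h: float = 2.0
    true_effect: TrueEffect = field(default_factory=TrueEffect)
    confounder_betas: dict = field(default_factory=lambda: dict(DEFAULT_CONFOUNDER_BETAS))
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    intercept: float = -2.6
    patient_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.monitoring_mix <= 1:
            raise ValueError("monitoring_mix must lie in [0, 1]")
        if self.surgeries_per_patient_rate < 1:
            raise ValueError("surgeries_per_patient_rate must be >= 1")
        if self.patient_sd < 0 or self.artifact_rate_per_h < 0:
            raise ValueError("rates and SDs must be non-negative")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


@dataclass
class SyntheticCohort:
    """Cases, observed (artifact-laden) series, clean series, and truth."""

    cases: pd.DataFrame
    series: dict[str, BPSeries]
    clean_series: dict[str, BPSeries]
    truth: pd.DataFrame
    artifact_labels: pd.DataFrame
    config: SimulationConfig


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_map_trace(
    duration_min: float,
    monitoring: str,
    process: MapProcess,
    seed,
    case_id: str = "case",
) -> BPSeries:
    """One artifact-free surgery trace.

    Invasive monitoring samples every 15 s; non-invasive at uniformly
    random 3-5-min intervals. The deviation from the (dipped) mean
    follows the exact AR(1) transition of the mean-reverting process, so
    the stationary mean and SD are ``baseline`` and ``noise_sd``.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    if monitoring not in ("invasive", "non_invasive"):
        raise ValueError(f"unknown monitoring mode: {monitoring}")
    rng = _as_rng(seed)
    total_s = duration_min * 60.0
    if monitoring == "invasive":
        t = np.arange(0.0, np.floor(total_s / GRID_STEP_S) * GRID_STEP_S + 1e-9, GRID_STEP_S)
    else:
        gaps = rng.uniform(180.0, 300.0, size=int(total_s / 180.0) + 2)
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        t = t[t <= total_s]
    n = len(t)
    mean_t = process.baseline - process.dip_depth * np.exp(-t / (process.dip_tau_min * 60.0))
    theta = process.reversion_per_min / 60.0  # per second
    sd = process.noise_sd
    if sd == 0:
        dev = np.zeros(n)
    else:
        dev = np.empty(n)
        dev[0] = rng.normal(0.0, sd)
        dt = np.diff(t)
        phi = np.exp(-theta * dt) if theta > 0 else np.ones(n - 1)
        innov_sd = sd * np.sqrt(np.clip(1.0 - phi**2, 0.0, None))
        eps = rng.normal(0.0, 1.0, size=n - 1) * innov_sd
        if monitoring == "invasive" and n > 1:
            # constant dt: one linear-filter pass instead of a python loop
            p = phi[0]
            zi = np.array([p * dev[0]])
            dev[1:] = lfilter([1.0], [1.0, -p], eps, zi=zi)[0]
        else:
            for i in range(1, n):
                dev[i] = phi[i - 1] * dev[i - 1] + eps[i - 1]
    map_vals = np.clip(mean_t + dev, 25.0, None)  # physiological floor
    pp = rng.lognormal(np.log(45.0), 0.15, size=n)
    sbp = map_vals + pp * 2.0 / 3.0
    dbp = map_vals - pp / 3.0
    return BPSeries(case_id=case_id, t=t, sbp=sbp, dbp=dbp, map=map_vals,
                    source=monitoring, anesthesia_end_s=total_s)


def inject_artifacts(series: BPSeries, rate_per_h: float, seed
                     ) -> tuple[BPSeries, pd.DataFrame]:
    """Insert Poisson-rate artifact samples with ground-truth rule labels.

    Each inserted sample violates exactly one of rules 1-5 (fixed
    prototype raw values) or targets rule 6 with an extreme but
    raw-rule-safe deviation. Returns the contaminated series and a table
    (t, rule) of the insertions.
    """
    rng = _as_rng(seed)
    duration_h = series.anesthesia_end_s / 3600.0
    n_art = rng.poisson(rate_per_h * duration_h) if rate_per_h > 0 else 0
    if n_art == 0:
        return series, pd.DataFrame(columns=["t", "rule"])
    t_art = rng.uniform(0.0, series.anesthesia_end_s, size=n_art)
    # keep insertion times distinct from existing samples and each other
    taken = set(np.round(series.t, 6))
    for i in range(n_art):
        while round(float(t_art[i]), 6) in taken:
            t_art[i] += 0.001
        taken.add(round(float(t_art[i]), 6))
    rules = rng.integers(1, 7, size=n_art)
    clean_map = series.map[~np.isnan(series.map)]
    mu = float(clean_map.mean()) if len(clean_map) else 80.0
    sd = float(clean_map.std()) if len(clean_map) else 5.0
    sbp_a, dbp_a, map_a = [], [], []
    for rule in rules:
        if rule <= 5:
            s, d = _RULE_SAMPLES[int(rule)]
        else:
            offset = max(40.0, 8.0 * sd)
            m = mu + offset if (mu - offset) < 40.0 or rng.random() < 0.5 else mu - offset
            m = float(np.clip(m, 41.0, 264.0))  # keep clear of the raw-value rules
            d, s = m - 15.0, m + 30.0  # PP 45, raw-rule safe for m in (40, 260)
        sbp_a.append(s)
        dbp_a.append(d)
        map_a.append(d + (s - d) / 3.0)
    t_all = np.concatenate([series.t, t_art])
    order = np.argsort(t_all, kind="stable")
    out = BPSeries(
        case_id=series.case_id,
        t=t_all[order],
        sbp=np.concatenate([series.sbp, sbp_a])[order],
        dbp=np.concatenate([series.dbp, dbp_a])[order],
        map=np.concatenate([series.map, map_a])[order],
        source=series.source,
        anesthesia_end_s=series.anesthesia_end_s,
    )
    labels = pd.DataFrame({"t": t_art, "rule": rules}).sort_values("t", ignore_index=True)
    return out, labels


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort under ``config`` (bit-reproducible given the seed)."""
    rng = np.random.default_rng(config.seed)
    m = config.marginals
    betas = config.confounder_betas
    eff = config.true_effect

    n_pat = config.n_patients
    n_surg = 1 + rng.poisson(config.surgeries_per_patient_rate - 1.0, size=n_pat)
    patient_ids = np.repeat([f"P{i:05d}" for i in range(n_pat)], n_surg)
    n_cases = int(n_surg.sum())
    case_ids = [f"C{i:06d}" for i in range(n_cases)]

    # patient-level attributes, broadcast to that patient's surgeries
    female_p = (rng.random(n_pat) < m["female"]).astype(int)
    age_p = _truncated_normal(rng, m["age_mean"], m["age_sd"], m["age_min"], m["age_max"], n_pat)
    smoker_p = (rng.random(n_pat) < m["smoker"]).astype(int)
    comorb_p = (rng.random(n_pat) < m["comorbidity_pos"]).astype(int)
    history_p = (rng.random(n_pat) < m["history_ponv"]).astype(int)
    b_patient = rng.normal(0.0, config.patient_sd, size=n_pat)

    rep = np.repeat(np.arange(n_pat), n_surg)
    female, age, smoker = female_p[rep], age_p[rep], smoker_p[rep]
    comorbidity, history = comorb_p[rep], history_p[rep]
    b_case = b_patient[rep]

    volatile = (rng.random(n_cases) < m["volatile"]).astype(int)
    ondansetron = (rng.random(n_cases) < m["ondansetron_ppx"]).astype(int)
    dexamethasone = (rng.random(n_cases) < m["dexamethasone_ppx"]).astype(int)
    asa = rng.choice([1, 2, 3, 4], size=n_cases, p=np.asarray(m["asa_probs"]) /
                     np.sum(m["asa_probs"]))
    risk_surgery = (rng.random(n_cases) < m["risk_surgery"]).astype(int)
    postop_opioids = (rng.random(n_cases) < m["postop_opioids"]).astype(int)
    duration_min = np.clip(
        rng.lognormal(np.log(config.duration_median_min), config.duration_log_sd, n_cases),
        config.duration_min_min, config.duration_max_min)
    invasive = rng.random(n_cases) < config.monitoring_mix
    baseline = rng.normal(config.map_process.baseline, config.baseline_between_sd, n_cases)

    series: dict[str, BPSeries] = {}
    clean_series: dict[str, BPSeries] = {}
    exposures = np.empty(n_cases)
    artifact_counts = np.zeros(n_cases, dtype=int)
    label_rows = []
    for i, cid in enumerate(case_ids):
        proc = replace(config.map_process, baseline=float(baseline[i]))
        clean = simulate_map_trace(float(duration_min[i]),
                                   "invasive" if invasive[i] else "non_invasive",
                                   proc, rng, case_id=cid)
        observed, labels = inject_artifacts(clean, config.artifact_rate_per_h, rng)
        clean_series[cid] = clean
        series[cid] = observed
        artifact_counts[i] = len(labels)
        if len(labels):
            labels = labels.assign(case_id=cid)
            label_rows.append(labels)
        exposures[i] = compute_exposure(interpolate_to_grid(clean), eff.spec)

    lp = (config.intercept
          + betas["female"] * female
          + betas["age_per_decade"] * (age - 53.0) / 10.0
          + betas["smoker"] * smoker
          + betas["volatile"] * volatile
          + betas["ondansetron_ppx"] * ondansetron
          + betas["dexamethasone_ppx"] * dexamethasone
          + betas["comorbidity_pos"] * comorbidity
          + betas["risk_surgery"] * risk_surgery
          + betas["duration_per_h"] * (duration_min / 60.0 - 1.7)
          + eff.beta_nonzero * (exposures > 0)
          + eff.beta_per_unit * exposures
          + b_case)
    true_prob = expit(lp)
    ponv = (rng.random(n_cases) < true_prob).astype(int)
    severities = np.where(ponv == 1,
                          rng.choice(["Nausea", "Need_to_vomit", "Vomiting"], size=n_cases),
                          "None")

    cases = pd.DataFrame({
        "case_id": case_ids,
        "patient_id": patient_ids,
        "ponv": ponv,
        "ponv_raw": severities,
        "female": female,
        "age": age,
        "smoker": smoker,
        "volatile": volatile,
        "ondansetron_ppx": ondansetron,
        "dexamethasone_ppx": dexamethasone,
        "asa": asa,
        "comorbidity_pos": comorbidity,
        "risk_surgery": risk_surgery,
        "duration_h": duration_min / 60.0,
        "history_ponv": history,
        "postop_opioids": postop_opioids,
    }).set_index("case_id", drop=False)
    truth = pd.DataFrame({
        "case_id": case_ids,
        "true_exposure": exposures,
        "true_prob": true_prob,
        "artifact_count": artifact_counts,
    }).set_index("case_id", drop=False)
    artifact_labels = (pd.concat(label_rows, ignore_index=True)
                       [["case_id", "t", "rule"]]
                       if label_rows else pd.DataFrame(columns=["case_id", "t", "rule"]))
    return SyntheticCohort(cases=cases, series=series, clean_series=clean_series,
                           truth=truth, artifact_labels=artifact_labels, config=config)


def write_cohort_csvs(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort in the pipeline's two CSV dialects plus truth.csv."""
    from .pipeline import write_case_csv, write_timeseries_csv

    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "timeseries": os.path.join(outdir, "timeseries.csv"),
        "cases": os.path.join(outdir, "cases.csv"),
        "truth": os.path.join(outdir, "truth.csv"),
    }
    write_timeseries_csv(cohort.series, paths["timeseries"])
    write_case_csv(cohort.cases, paths["cases"])
    cohort.truth.to_csv(paths["truth"], index=False, float_format="%.10g")
    return paths
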
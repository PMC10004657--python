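"""End-to-end split-sample analysis and the file formats that feed it.

The full analysis runs: preprocess raw pressure records -> compute all
hypotension characterizations -> split patients into a shaping and an
estimation arm -> rank characterizations by cross-validated Brier score
on the shaping arm -> refit the winning model on the estimation arm and
report adjusted odds-ratio contrasts (exposure x versus no exposure)
with delta-method confidence intervals on the robust covariance ->
variable-contribution analysis. Splitting by patient keeps model
selection independent of effect estimation, so the reported OR is free
of selection-induced optimism.

File formats:

- time-series CSV: ``case_id, t_s, sbp, dbp, map, source`` (long format,
  empty cell = missing channel);
- case CSV: one row per PONV documentation entry, ``ponv_raw`` in
  {None, Nausea, Need_to_vomit, Vomiting}; a case is PONV-positive when
  any of its entries is positive (most severe entry wins, a "None" entry
  never overrides a positive one);
- report bundle: comparison.csv, contributions.csv, or_contrasts.csv,
  feature_summary.csv, artifact_report.csv, split.csv, fit JSON, run.log.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import evaluation, features, model, preprocess
from .features import CharacterizationSpec
from .model import DesignBases, GEEFit
from .simulate import MapProcess, SimulationConfig, TrueEffect, simulate_cohort

logger = logging.getLogger(__name__)

PONV_POSITIVE = {"Nausea", "Need_to_vomit", "Vomiting"}
_SEVERITY_ORDER = ["None", "Nausea", "Need_to_vomit", "Vomiting"]


# ---------------------------------------------------------------- file IO

def write_timeseries_csv(series: dict[str, preprocess.BPSeries], path) -> None:
    frames = []
    for cid in series:
        s = series[cid]
        frames.append(pd.DataFrame({
            "case_id": cid, "t_s": s.t, "sbp": s.sbp, "dbp": s.dbp,
            "map": s.map, "source": s.source,
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["case_id", "t_s", "sbp", "dbp", "map", "source"])
    out.to_csv(path, index=False, float_format="%.10g")


def read_timeseries_csv(path, anesthesia_end_s: dict[str, float] | None = None
                        ) -> dict[str, preprocess.BPSeries]:
    df = pd.read_csv(path)
    out = {}
    for cid, grp in df.groupby("case_id", sort=False):
        grp = grp.sort_values("t_s", kind="mergesort")
        end = (anesthesia_end_s or {}).get(cid, float(grp["t_s"].iloc[-1]))
        out[str(cid)] = preprocess.BPSeries(
            case_id=str(cid), t=grp["t_s"].to_numpy(float),
            sbp=grp["sbp"].to_numpy(float), dbp=grp["dbp"].to_numpy(float),
            map=grp["map"].to_numpy(float),
            source=str(grp["source"].iloc[0]), anesthesia_end_s=end)
    return out


def write_case_csv(cases: pd.DataFrame, path) -> None:
    cols = ["case_id", "patient_id", "ponv_raw", "female", "age", "smoker",
            "volatile", "ondansetron_ppx", "dexamethasone_ppx", "asa",
            "comorbidity_pos", "risk_surgery", "duration_h", "history_ponv",
            "postop_opioids"]
    cases[cols].to_csv(path, index=False, float_format="%.10g")


def dichotomize_ponv(entries: pd.Series) -> int:
    """PONV-positive if any documented entry is positive (severity max)."""
    ranked = max(entries, key=_SEVERITY_ORDER.index)
    return int(ranked in PONV_POSITIVE)


def read_case_csv(path) -> pd.DataFrame:
    """Read the case table, collapsing multiple PONV entries per case."""
    # keep_default_na=False: the severity level "None" is data, not missing
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    bad = ~df["ponv_raw"].isin(_SEVERITY_ORDER)
    if bad.any():
        raise ValueError(f"unknown ponv_raw values: {sorted(df.loc[bad, 'ponv_raw'].unique())}")
    ponv = df.groupby("case_id", sort=False)["ponv_raw"].apply(dichotomize_ponv)
    cases = df.drop_duplicates("case_id").set_index("case_id", drop=False)
    cases["ponv"] = ponv
    model.validate_case_frame(cases)
    return cases


# ---------------------------------------------------------------- split

@dataclass
class SplitPlan:
    """Patient-level allocation into shaping and estimation arms."""

    seed: int
    arm: dict[str, str]  # patient_id -> "shaping" | "estimation"

    def case_arm(self, patient_ids: pd.Series) -> pd.Series:
        return patient_ids.map(self.arm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.arm.items()), columns=["patient_id", "arm"])


def split_cohort(cases: pd.DataFrame, seed: int) -> SplitPlan:
    """Randomized patient-level split balancing procedure counts.

    Patients are shuffled, then greedily assigned to the currently
    lighter arm (by case count), so the arms differ by at most the
    largest single patient's procedure count.
    """
    counts = cases.groupby("patient_id").size()
    if len(counts) < 2:
        raise ValueError("need >= 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.asarray(sorted(counts.index)))
    totals = {"shaping": 0, "estimation": 0}
    arm = {}
    for pid in order:
        if totals["shaping"] < totals["estimation"]:
            a = "shaping"
        elif totals["estimation"] < totals["shaping"]:
            a = "estimation"
        else:
            a = "shaping" if rng.random() < 0.5 else "estimation"
        arm[pid] = a
        totals[a] += int(counts[pid])
    return SplitPlan(seed=seed, arm=arm)


# ---------------------------------------------------------------- OR contrast

@dataclass
class ORContrast:
    """Adjusted odds ratio for exposure x versus no exposure."""

    spec_label: str
    x: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    evaluated_at: float  # x after capping at the winsorization limit

    def as_row(self) -> dict:
        return {
            "characterization": self.spec_label, "x": self.x,
            "evaluated_at": self.evaluated_at, "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "log_or": self.log_or, "se_log_or": self.se_log_or,
        }


def _exposure_contrast_vector(fit: GEEFit, spec: CharacterizationSpec, x: float
                              ) -> tuple[np.ndarray, float]:
    bases: DesignBases = fit.bases
    if bases is None:
        raise ValueError("fit carries no design bases; cannot form exposure contrast")
    x_eval = min(x, bases.exposure_cap)
    if x_eval < x:
        logger.info("contrast point %g beyond winsorization cap %g; evaluated at the cap",
                    x, bases.exposure_cap)
    coords_x = bases.exposure_basis.transform(np.array([x_eval]))[0]
    coords_0 = bases.exposure_basis.transform(np.array([0.0]))[0]
    c = np.zeros(len(fit.columns))
    names = (["exp_lin"] if bases.exposure_basis.df == 1
             else [f"exp_ns{i+1}" for i in range(bases.exposure_basis.df)])
    for name, vx, v0 in zip(names, coords_x, coords_0):
        if name in fit.columns:
            c[fit.columns.index(name)] = vx - v0
    if "exp_zero" in fit.columns:
        # indicator is 1 when the (winsorized) exposure equals zero
        c[fit.columns.index("exp_zero")] = (1.0 if x_eval == 0 else 0.0) - 1.0
    return c, x_eval


def estimate_adjusted_or(fit: GEEFit, spec: CharacterizationSpec, x: float,
                         alpha: float = 0.05) -> ORContrast:
    """OR (95% CI) for exposure ``x`` versus zero exposure, all else equal.

    The log-OR is the spline contrast plus the any-exposure indicator
    jump; its variance comes from the delta method on the robust
    covariance (the contrast is linear in the coefficients, so the delta
    method is exact on the log scale).
    """
    if x < 0:
        raise ValueError("contrast point x must be >= 0")
    if not fit.converged:
        raise ValueError("fit did not converge; no contrast is reported")
    c, x_eval = _exposure_contrast_vector(fit, spec, x)
    log_or = float(c @ fit.params)
    var = float(c @ fit.cov_robust @ c)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    return ORContrast(
        spec_label=spec.label, x=x, evaluated_at=x_eval,
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        log_or=log_or, se_log_or=se,
    )


def spline_plateau_point(fit: GEEFit, tol: float = 0.01, n_grid: int = 400
                         ) -> float:
    """First exposure value where the fitted log-odds curve flattens.

    Scans the exposure spline's derivative on a dense grid up to the
    winsorization cap and returns the first point where |d log-odds / dx|
    falls below ``tol`` (per exposure unit); NaN if it never does.
    """
    bases = fit.bases
    hi = bases.exposure_cap
    if hi <= 0:
        return float("nan")
    xs = np.linspace(0.0, hi, n_grid)
    names = (["exp_lin"] if bases.exposure_basis.df == 1
             else [f"exp_ns{i+1}" for i in range(bases.exposure_basis.df)])
    beta = np.array([fit.params[fit.columns.index(n)] if n in fit.columns else 0.0
                     for n in names])
    curve = bases.exposure_basis.transform(xs) @ beta
    deriv = np.gradient(curve, xs)
    flat = np.abs(deriv) < tol
    if not flat.any():
        return float("nan")
    return float(xs[np.argmax(flat)])


def apfel_score(female: int, smoker: int, history_ponv: int, postop_opioids: int) -> int:
    """Apfel risk score 0-4: female, non-smoker, PONV/motion-sickness
    history, postoperative opioids (reporting only, never a covariate)."""
    for v in (female, smoker, history_ponv, postop_opioids):
        if v is None or v not in (0, 1):
            raise ValueError("apfel_score needs binary inputs")
    return int(female) + int(1 - smoker) + int(history_ponv) + int(postop_opioids)


# ---------------------------------------------------------------- config

DEFAULT_CONFIG = {
    "simulate": {"n_patients": 600, "seed": 0},
    "preprocess": {"step_s": 15.0},
    "features": {"specs": None},  # None -> all 24
    "split": {"seed": 1},
    # candidates: characterization labels entering the model comparison
    # (None -> every computed characterization); the desk-scale default
    # spans all four families
    "cv": {"k": 5, "reps": 5, "seed": 2,
           "candidates": ["time_under_50", "time_under_60", "sustained_lowest_1",
                           "sustained_lowest_5", "cumulative_lowest_1",
                           "cumulative_lowest_10", "fraction_under_60",
                           "fraction_under_80"]},
    "model": {"or_x": None, "plateau_tol": 0.01},
    "report": {"plots": False},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for block, vals in cfg.items():
        merged.setdefault(block, {})
        merged[block].update(vals or {})
    return merged


def _sim_config_from_block(block: dict, seed_offset: int = 0) -> SimulationConfig:
    block = dict(block)
    if "map_process" in block:
        block["map_process"] = MapProcess(**block["map_process"])
    if "true_effect" in block:
        te = dict(block["true_effect"])
        if "spec" in te:
            te["spec"] = CharacterizationSpec.from_label(te["spec"])
        block["true_effect"] = TrueEffect(**te)
    block["seed"] = int(block.get("seed", 0)) + seed_offset
    return SimulationConfig(**block)


# ---------------------------------------------------------------- stages

def preprocess_cohort(series: dict[str, preprocess.BPSeries]
                      ) -> tuple[dict[str, preprocess.MapGrid], pd.DataFrame, list[str]]:
    """Clean and grid every surgery; returns grids, the per-rule artifact
    table, and the ids of cases excluded as unusable."""
    grids, rows, excluded = {}, [], []
    for cid, s in series.items():
        try:
            grid, report = preprocess.preprocess_series(s)
        except (preprocess.EmptySeriesError, preprocess.UnusableSeriesError) as exc:
            logger.warning("case %s excluded: %s", cid, exc)
            excluded.append(cid)
            continue
        grids[cid] = grid
        for rule, count in report.counts.items():
            rows.append({"case_id": cid, "rule": rule, "count": count})
    artifact_table = pd.DataFrame(rows, columns=["case_id", "rule", "count"])
    return grids, artifact_table, excluded


def run_full_analysis(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the two-aim analysis and write the report bundle.

    Returns a dict with the in-memory results (comparison, best spec,
    estimation fit, OR contrasts, contributions). ``seed`` overrides
    every seed block for fully reproducible replays.
    """
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ioh_ponv")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_full_analysis(config, outdir, seed)
    finally:
        root.removeHandler(handler)
        handler.close()


def _resolve_seeds(config: dict, seed: int | None) -> dict:
    cfg = {k: dict(v) for k, v in config.items()}
    if seed is not None:
        cfg.setdefault("simulate", {})["seed"] = seed
        cfg.setdefault("split", {})["seed"] = seed + 1
        cfg.setdefault("cv", {})["seed"] = seed + 2
    return cfg


def _run_full_analysis(config: dict, outdir, seed: int | None) -> dict:
    cfg = _resolve_seeds({**{k: dict(v) for k, v in DEFAULT_CONFIG.items()}, **config}, seed)
    for block in DEFAULT_CONFIG:
        merged = dict(DEFAULT_CONFIG[block])
        merged.update(cfg.get(block, {}))
        cfg[block] = merged
    with open(os.path.join(outdir, "config_resolved.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    # --- stage: input ----------------------------------------------------
    if "input" in config and config["input"]:
        cases = read_case_csv(config["input"]["cases"])
        ends = dict(zip(cases["case_id"], cases["duration_h"] * 3600.0))
        series = read_timeseries_csv(config["input"]["timeseries"], anesthesia_end_s=ends)
        logger.info("input: %d cases, %d series", len(cases), len(series))
    else:
        sim_cfg = _sim_config_from_block(cfg["simulate"])
        cohort = simulate_cohort(sim_cfg)
        cases, series = cohort.cases, cohort.series
        logger.info("simulated: %d cases on %d patients", len(cases), sim_cfg.n_patients)

    # --- stage: preprocess ----------------------------------------------
    grids, artifact_table, excluded = preprocess_cohort(series)
    artifact_table.to_csv(os.path.join(outdir, "artifact_report.csv"), index=False)
    cases = cases.loc[cases["case_id"].isin(grids.keys())]
    logger.info("preprocess: %d cases usable, %d excluded, %d artifact samples removed",
                len(grids), len(excluded), int(artifact_table["count"].sum()))

    # --- stage: features -------------------------------------------------
    spec_labels = cfg["features"].get("specs")
    specs = ([CharacterizationSpec.from_label(s) for s in spec_labels]
             if spec_labels else features.default_specs())
    table = features.compute_feature_table(grids, specs).loc[cases.index]
    features.summarize_features(table).to_csv(
        os.path.join(outdir, "feature_summary.csv"), float_format="%.6g")
    logger.info("features: %d characterizations on %d cases", len(specs), len(table))

    # --- stage: split -----------------------------------------------------
    split = split_cohort(cases, seed=int(cfg["split"]["seed"]))
    split.to_frame().to_csv(os.path.join(outdir, "split.csv"), index=False)
    arm = split.case_arm(cases["patient_id"])
    shaping, estimation = cases.loc[arm == "shaping"], cases.loc[arm == "estimation"]
    logger.info("split: shaping %d cases, estimation %d cases", len(shaping), len(estimation))

    # --- stage: shaping-set model comparison ------------------------------
    plan = evaluation.make_fold_plan(shaping["patient_id"], k=int(cfg["cv"]["k"]),
                                     reps=int(cfg["cv"]["reps"]), seed=int(cfg["cv"]["seed"]))
    cand_labels = cfg["cv"].get("candidates")
    candidates = ([CharacterizationSpec.from_label(s) for s in cand_labels]
                  if cand_labels else specs)
    missing = [c.label for c in candidates if c.label not in table.columns]
    if missing:
        raise ValueError(f"candidate characterizations not computed: {missing}")
    comparison = evaluation.rank_characterizations(candidates, shaping,
                                                   table.loc[shaping.index], plan)
    comparison.to_frame().to_csv(os.path.join(outdir, "comparison.csv"),
                                 index=False, float_format="%.10g")
    best = comparison.best
    logger.info("best characterization: %s", best.label)

    # --- stage: estimation-set fit and OR contrasts -----------------------
    exp_est = table.loc[estimation.index, best.label]
    est_cases = estimation.loc[exp_est.notna()]
    exp_est = exp_est.loc[est_cases.index]
    X, bases = model.build_design(est_cases, exp_est, best)
    fit = model.fit_gee_logistic(X, est_cases["ponv"], est_cases["patient_id"], bases=bases)
    fit.save_json(os.path.join(outdir, "fit_estimation.json"))
    or_x = cfg["model"].get("or_x")
    if not or_x:
        nonzero = exp_est[exp_est > 0]
        or_x = ([float(nonzero.quantile(0.5)), float(nonzero.quantile(0.75))]
                if len(nonzero) else [float(exp_est.quantile(0.75))])
    contrasts = [estimate_adjusted_or(fit, best, float(x)) for x in or_x]
    plateau = spline_plateau_point(fit, tol=float(cfg["model"]["plateau_tol"]))
    pd.DataFrame([c.as_row() for c in contrasts]).to_csv(
        os.path.join(outdir, "or_contrasts.csv"), index=False, float_format="%.10g")
    logger.info("estimation: OR at x=%s; log-odds plateau near x=%.3g",
                [c.x for c in contrasts], plateau)

    # --- stage: variable contribution (shaping arm, same plan) ------------
    contrib = evaluation.variable_contribution(best, shaping, table.loc[shaping.index, best.label],
                                               plan)
    contrib.to_frame().to_csv(os.path.join(outdir, "contributions.csv"),
                              index=False, float_format="%.10g")

    if cfg["report"].get("plots"):
        from .plotting import plot_comparison, plot_contributions
        plot_comparison(comparison.to_frame(), os.path.join(outdir, "comparison.png"))
        plot_contributions(contrib.to_frame(), os.path.join(outdir, "contributions.png"))

    summary = {
        "n_cases": int(len(cases)),
        "n_patients": int(cases["patient_id"].nunique()),
        "ponv_rate": float(cases["ponv"].mean()),
        "best_characterization": best.label,
        "plateau_x": None if np.isnan(plateau) else plateau,  # None: no flattening below the cap
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {
        "cases": cases, "feature_table": table, "split": split,
        "comparison": comparison, "best": best, "fit": fit,
        "or_contrasts": contrasts, "contributions": contrib, "summary": summary,
    }
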
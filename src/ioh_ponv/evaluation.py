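"""Cluster-respecting repeated cross-validation and model comparison.

Model selection among the hypotension characterizations uses repeated
k-fold cross-validation in which all procedures of one patient share a
fold (the clustering that motivates the GEE also invalidates naive
row-wise folds). Within every training split the winsorization cap and
spline knots are re-learned, so no information from held-out cases
leaks into the design. Held-out predictions are pooled within each
repetition, the four performance metrics are computed on the pool, and
means/SDs are taken across repetitions.

Metrics: Brier score (mean squared error of the predicted probability),
c-statistic (concordance), discrimination slope (mean predicted risk in
events minus non-events), and calibration slope (coefficient of a
logistic fit of the outcome on the logit of the prediction).

The characterization whose model attains the smallest mean
cross-validated Brier score is selected; ties break by higher
c-statistic, then label order. Variable contributions are measured as
the increase in cross-validated Brier when one adjustment variable
group is removed, on the identical fold plan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .features import CharacterizationSpec
from .model import (DesignBases, NonConvergenceError, build_design,
                    fit_gee_logistic, predict_prob)

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Patient-to-fold assignment for k folds times r repetitions."""

    k: int
    reps: int
    assignments: list[dict]  # per repetition: patient_id -> fold index
    seed: int

    def case_folds(self, patient_ids: pd.Series, rep: int) -> np.ndarray:
        """Fold index per case for one repetition."""
        mapping = self.assignments[rep]
        return patient_ids.map(mapping).to_numpy()


def make_fold_plan(patient_ids, k: int = 10, reps: int = 40, seed: int = 0) -> FoldPlan:
    """Randomized, seeded fold plan over unique patients.

    Every patient lands in exactly one fold per repetition (so all of a
    patient's surgeries share the fold) and fold sizes differ by at most
    one patient.
    """
    patients = np.unique(np.asarray(patient_ids))
    if len(patients) < k:
        raise ValueError(f"need >= {k} patients for {k} folds, got {len(patients)}")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(reps):
        perm = rng.permutation(patients)
        folds = {}
        for fold, chunk in enumerate(np.array_split(perm, k)):
            for p in chunk:
                folds[p] = fold
        assignments.append(folds)
    return FoldPlan(k=k, reps=reps, assignments=assignments, seed=seed)


def brier_score(p: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error of predicted probabilities; 0 is perfect."""
    p, y = np.asarray(p, float), np.asarray(y, float)
    if len(p) == 0 or len(p) != len(y):
        raise ValueError("inputs must be aligned and non-empty")
    return float(np.mean((p - y) ** 2))


def c_statistic(p: np.ndarray, y: np.ndarray) -> float:
    """Concordance: share of (event, non-event) pairs ranked correctly, ties 1/2."""
    y = np.asarray(y, float)
    if y.min() == y.max():
        raise ValueError("c-statistic undefined with a single outcome class")
    return float(roc_auc_score(y, np.asarray(p, float)))


def discrimination_slope(p: np.ndarray, y: np.ndarray) -> float:
    """Mean predicted risk among events minus among non-events."""
    p, y = np.asarray(p, float), np.asarray(y, float)
    if y.min() == y.max():
        raise ValueError("discrimination slope undefined with a single outcome class")
    return float(p[y == 1].mean() - p[y == 0].mean())


def calibration_slope(p: np.ndarray, y: np.ndarray) -> float:
    """Slope of a logistic regression of the outcome on logit(p).

    1 indicates well-calibrated spread of the predictions; < 1 indicates
    overfitting (predictions too extreme).
    """
    p, y = np.asarray(p, float), np.asarray(y, float)
    if y.min() == y.max():
        raise ValueError("calibration slope undefined with a single outcome class")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predictions must lie strictly inside (0, 1)")
    logit = np.log(p / (1 - p))
    X = np.column_stack([np.ones_like(logit), logit])
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:
        raise NonConvergenceError(f"calibration-slope fit failed: {exc}") from exc
    return float(res.params[1])


@dataclass
class CVMetrics:
    """Cross-validated performance of one model, mean (SD) over repetitions."""

    spec_label: str
    brier: float
    brier_sd: float
    c_stat: float
    c_stat_sd: float
    discrimination_slope: float
    discrimination_slope_sd: float
    calibration_slope: float
    calibration_slope_sd: float
    n_reps_used: int
    n_reps_failed: int

    def as_row(self) -> dict:
        return {
            "characterization": self.spec_label,
            "brier": self.brier, "brier_sd": self.brier_sd,
            "c_statistic": self.c_stat, "c_statistic_sd": self.c_stat_sd,
            "discrimination_slope": self.discrimination_slope,
            "discrimination_slope_sd": self.discrimination_slope_sd,
            "calibration_slope": self.calibration_slope,
            "calibration_slope_sd": self.calibration_slope_sd,
            "n_reps_used": self.n_reps_used, "n_reps_failed": self.n_reps_failed,
        }


def cross_validate(
    spec: CharacterizationSpec,
    cases: pd.DataFrame,
    exposure: pd.Series,
    plan: FoldPlan,
    drop_groups: tuple[str, ...] = (),
    collect_caps: bool = False,
) -> CVMetrics | tuple[CVMetrics, list[dict]]:
    """Repeated grouped k-fold CV of one characterization's model.

    Per fold: winsorization cap and spline knots are learned on the
    training folds, the GEE is fitted there, and the held-out fold is
    predicted with the stored bases. Held-out predictions are pooled per
    repetition; each metric is averaged over repetitions. Repetitions
    with a non-convergent fold or a single-class training outcome are
    excluded and counted. ``collect_caps`` additionally returns the
    per-(rep, fold) winsorization caps (leakage diagnostics).
    """
    keep = exposure.reindex(cases.index).notna()
    cases = cases.loc[keep]
    exposure = exposure.reindex(cases.index)
    per_rep: list[dict] = []
    caps: list[dict] = []
    n_failed = 0
    for rep in range(plan.reps):
        folds = plan.case_folds(cases["patient_id"], rep)
        pooled_p = np.full(len(cases), np.nan)
        try:
            for fold in range(plan.k):
                test = folds == fold
                train = ~test
                if not test.any():
                    continue
                y_tr = cases.loc[train, "ponv"].to_numpy(float)
                if y_tr.min() == y_tr.max():
                    raise NonConvergenceError("single-class training outcome")
                X_tr, bases = build_design(cases.loc[train], exposure.loc[train],
                                           spec, drop_groups=drop_groups)
                fit = fit_gee_logistic(X_tr, y_tr, cases.loc[train, "patient_id"])
                if collect_caps:
                    caps.append({"rep": rep, "fold": fold, "cap": bases.exposure_cap})
                X_te, _ = build_design(cases.loc[test], exposure.loc[test],
                                       spec, bases=bases, drop_groups=drop_groups)
                pooled_p[test] = predict_prob(fit, X_te)
        except NonConvergenceError as exc:
            n_failed += 1
            logger.warning("rep %d of %s excluded: %s", rep, spec.label, exc)
            continue
        got = ~np.isnan(pooled_p)
        y = cases.loc[got, "ponv"].to_numpy(float)
        p = pooled_p[got]
        per_rep.append({
            "brier": brier_score(p, y),
            "c_stat": c_statistic(p, y),
            "discrimination_slope": discrimination_slope(p, y),
            "calibration_slope": calibration_slope(p, y),
        })
    if not per_rep:
        raise NonConvergenceError(f"all {plan.reps} repetitions failed for {spec.label}")
    df = pd.DataFrame(per_rep)
    sd = df.std(ddof=1).fillna(0.0) if len(df) > 1 else df.iloc[0] * 0.0
    metrics = CVMetrics(
        spec_label=spec.label,
        brier=float(df["brier"].mean()), brier_sd=float(sd["brier"]),
        c_stat=float(df["c_stat"].mean()), c_stat_sd=float(sd["c_stat"]),
        discrimination_slope=float(df["discrimination_slope"].mean()),
        discrimination_slope_sd=float(sd["discrimination_slope"]),
        calibration_slope=float(df["calibration_slope"].mean()),
        calibration_slope_sd=float(sd["calibration_slope"]),
        n_reps_used=len(df), n_reps_failed=n_failed,
    )
    if collect_caps:
        return metrics, caps
    return metrics


@dataclass
class ComparisonResult:
    """Per-characterization CV metrics, ranked ascending by Brier score."""

    metrics: list[CVMetrics]
    best: CharacterizationSpec
    tie_broken: bool = False
    excluded: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((m.as_row() for m in self.metrics),
                      key=lambda r: (r["brier"], -r["c_statistic"], r["characterization"]))
        df = pd.DataFrame(rows)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df


def rank_characterizations(
    specs: list[CharacterizationSpec],
    cases: pd.DataFrame,
    exposure_table: pd.DataFrame,
    plan: FoldPlan,
) -> ComparisonResult:
    """Cross-validate every candidate characterization on a shared fold plan.

    The winner minimizes the mean cross-validated Brier score; exact
    ties break by higher c-statistic, then lexical label.
    """
    if len(specs) < 2:
        raise ValueError("need >= 2 candidate characterizations to compare")
    all_metrics: list[CVMetrics] = []
    excluded: list[str] = []
    for spec in specs:
        try:
            metrics = cross_validate(spec, cases, exposure_table[spec.label], plan)
        except NonConvergenceError as exc:
            logger.warning("model for %s excluded from comparison: %s", spec.label, exc)
            excluded.append(spec.label)
            continue
        all_metrics.append(metrics)
        logger.info("CV %s: brier=%.5f c=%.4f", spec.label, metrics.brier, metrics.c_stat)
    if not all_metrics:
        raise NonConvergenceError("no candidate model converged; comparison impossible")
    ordered = sorted(all_metrics, key=lambda m: (m.brier, -m.c_stat, m.spec_label))
    tie = len(ordered) > 1 and ordered[0].brier == ordered[1].brier
    if tie:
        logger.info("Brier tie between %s and %s broken by c-statistic/label",
                    ordered[0].spec_label, ordered[1].spec_label)
    return ComparisonResult(
        metrics=all_metrics,
        best=CharacterizationSpec.from_label(ordered[0].spec_label),
        tie_broken=tie,
        excluded=excluded,
    )


def univariate_screen(
    specs: list[CharacterizationSpec],
    cases: pd.DataFrame,
    exposure_table: pd.DataFrame,
) -> pd.DataFrame:
    """Convenience wrapper: unadjusted association of each characterization.

    Fits, per characterization, a GEE logistic model containing only the
    exposure terms (spline / linear fallback plus any-exposure indicator)
    and reports a Wald chi-square test of those terms being jointly zero.
    Reporting-only; model selection always uses the adjusted models.
    """
    from scipy import stats as _stats

    rows = []
    for spec in specs:
        exposure = exposure_table[spec.label]
        keep = exposure.reindex(cases.index).notna()
        sub, e = cases.loc[keep], exposure.loc[keep]
        X, bases = build_design(sub, e, spec)
        exp_cols = [c for c in X.columns if c.startswith("exp_")]
        X_uni = X[["intercept"] + exp_cols]
        try:
            fit = fit_gee_logistic(X_uni, sub["ponv"], sub["patient_id"], bases=bases)
        except NonConvergenceError as exc:
            logger.warning("univariate screen for %s failed: %s", spec.label, exc)
            rows.append({"characterization": spec.label, "wald_chi2": np.nan,
                         "df": len(exp_cols), "p_value": np.nan})
            continue
        idx = [fit.columns.index(c) for c in exp_cols]
        beta = fit.params[idx]
        cov = fit.cov_robust[np.ix_(idx, idx)]
        chi2 = float(beta @ np.linalg.solve(cov, beta))
        rows.append({"characterization": spec.label, "wald_chi2": chi2,
                     "df": len(exp_cols),
                     "p_value": float(_stats.chi2.sf(chi2, len(exp_cols)))})
    return pd.DataFrame(rows)


@dataclass
class ContributionResult:
    """Brier-score increase when one variable group leaves the model."""

    spec_label: str
    full_brier: float
    deltas: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "variable": list(self.deltas),
            "brier_delta": list(self.deltas.values()),
        })
        return df.sort_values("brier_delta", ascending=False, kind="mergesort",
                              ignore_index=True)


def variable_contribution(
    spec: CharacterizationSpec,
    cases: pd.DataFrame,
    exposure: pd.Series,
    plan: FoldPlan,
    groups: tuple[str, ...] = ("exposure", "sex", "age", "smoker", "volatile",
                               "ondansetron", "dexamethasone", "asa",
                               "comorbidity", "risk_surgery", "duration"),
) -> ContributionResult:
    """CV-Brier increase from omitting each variable group.

    Omitting sex or age also omits the age-sex interaction. All reduced
    models reuse the full model's fold plan so deltas are paired.
    """
    full = cross_validate(spec, cases, exposure, plan)
    result = ContributionResult(spec_label=spec.label, full_brier=full.brier)
    for group in groups:
        try:
            reduced = cross_validate(spec, cases, exposure, plan, drop_groups=(group,))
        except NonConvergenceError as exc:
            logger.warning("reduced model without %s failed: %s", group, exc)
            result.deltas[group] = float("nan")
            continue
        result.deltas[group] = reduced.brier - full.brier
    return result
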
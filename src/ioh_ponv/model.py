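"""Marginal logistic models of PONV risk with patient clustering.

Each model relates the binary outcome (postoperative nausea and
vomiting in the PACU) to one hypotension characterization plus a fixed
adjustment set: comorbidity flag, PONV-risk surgery type, smoking, sex,
volatile anesthetics, ondansetron and dexamethasone prophylaxis, ASA
class, surgery duration, age, and the age-by-sex interaction. Exposure,
age, and duration enter as natural cubic splines (3 df); zero-inflated
exposure families additionally carry a binary any-exposure indicator;
exposures are winsorized at the 99th percentile.

Fitting is by generalized estimating equations (binomial family, logit
link) with the patient as the cluster and an exchangeable working
correlation; inference uses the robust (sandwich) covariance. All
data-dependent preprocessing (winsorization cap, spline knots) is
learned on the fitting data and stored so held-out data can be mapped
into an identical design.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import CharacterizationSpec
from .splines import SplineBasis, natural_spline_basis

logger = logging.getLogger(__name__)

#: support required to spend 3 spline df on a zero-inflated exposure;
#: below either bound the exposure enters linearly (events-per-variable
#: logic: the spline shape is identified by the exposed stratum only)
MIN_NONZERO_FOR_SPLINE = 40
MIN_NONZERO_EVENTS_FOR_SPLINE = 20

#: covariate columns every case table must provide
CASE_COLUMNS = [
    "patient_id", "ponv", "female", "age", "smoker", "volatile",
    "ondansetron_ppx", "dexamethasone_ppx", "asa", "comorbidity_pos",
    "risk_surgery", "duration_h",
]

#: design-column groups removed together in the variable-contribution
#: analysis (sex/age omissions also drop the age-sex interaction)
VARIABLE_GROUPS = {
    "exposure": ("exp_",),
    "sex": ("female", "agefem_"),
    "age": ("age_", "agefem_"),
    "smoker": ("smoker",),
    "volatile": ("volatile",),
    "ondansetron": ("ondansetron_ppx",),
    "dexamethasone": ("dexamethasone_ppx",),
    "asa": ("asa_",),
    "comorbidity": ("comorbidity_pos",),
    "risk_surgery": ("risk_surgery",),
    "duration": ("dur_",),
}


@dataclass
class SurgeryCase:
    """Covariates, outcome, and cluster id for one procedure."""

    case_id: str
    patient_id: str
    ponv: int
    female: int
    age: float
    smoker: int
    volatile: int
    ondansetron_ppx: int
    dexamethasone_ppx: int
    asa: int
    comorbidity_pos: int
    risk_surgery: int
    duration_h: float
    history_ponv: int = 0
    postop_opioids: int = 0

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError(f"case {self.case_id}: age must be >= 18")
        if self.asa not in (1, 2, 3, 4):
            raise ValueError(f"case {self.case_id}: ASA must be in 1..4")
        if self.duration_h <= 0:
            raise ValueError(f"case {self.case_id}: duration_h must be positive")


def validate_case_frame(cases: pd.DataFrame) -> None:
    missing = [c for c in CASE_COLUMNS if c not in cases.columns]
    if missing:
        raise ValueError(f"case table missing columns: {missing}")
    if (cases["age"] < 18).any():
        raise ValueError("case table contains age < 18")
    if ~cases["asa"].isin([1, 2, 3, 4]).all():
        raise ValueError("case table contains ASA outside 1..4")
    if (cases["duration_h"] <= 0).any():
        raise ValueError("case table contains non-positive duration_h")


def winsorize_99(values: np.ndarray, cap: float | None = None, q: float = 99.0
                 ) -> tuple[np.ndarray, float]:
    """Cap values at the empirical ``q``-th percentile.

    The cap is computed on the data being fit (linear-interpolation
    percentile) and returned so held-out data reuse it.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) < 2:
        raise ValueError("winsorization needs >= 2 finite values")
    if cap is None:
        cap = float(np.percentile(finite, q))
    return np.minimum(values, cap), cap


@dataclass
class DesignBases:
    """Training-derived preprocessing state for design construction."""

    spec_label: str
    exposure_cap: float
    exposure_basis: SplineBasis
    age_basis: SplineBasis
    duration_basis: SplineBasis
    dropped_columns: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "spec_label": self.spec_label,
            "exposure_cap": self.exposure_cap,
            "exposure_basis": self.exposure_basis.to_dict(),
            "age_basis": self.age_basis.to_dict(),
            "duration_basis": self.duration_basis.to_dict(),
            "dropped_columns": list(self.dropped_columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignBases":
        return cls(
            spec_label=d["spec_label"],
            exposure_cap=d["exposure_cap"],
            exposure_basis=SplineBasis.from_dict(d["exposure_basis"]),
            age_basis=SplineBasis.from_dict(d["age_basis"]),
            duration_basis=SplineBasis.from_dict(d["duration_basis"]),
            dropped_columns=tuple(d.get("dropped_columns", ())),
        )


def _named(prefix: str, mat: np.ndarray) -> dict[str, np.ndarray]:
    if mat.shape[1] == 1:
        return {f"{prefix}_lin": mat[:, 0]}
    return {f"{prefix}_ns{i + 1}": mat[:, i] for i in range(mat.shape[1])}


def build_design(
    cases: pd.DataFrame,
    exposure: pd.Series,
    spec: CharacterizationSpec,
    bases: DesignBases | None = None,
    drop_groups: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, DesignBases]:
    """Assemble the model matrix for one characterization.

    With ``bases=None`` the winsorization cap and all spline knots are
    learned from ``cases``/``exposure`` (fitting data); passing a stored
    ``bases`` reproduces the training design on held-out data.
    ``drop_groups`` removes the named :data:`VARIABLE_GROUPS` (used by
    the variable-contribution analysis). Rows with undefined exposure
    must be removed by the caller beforehand.
    """
    validate_case_frame(cases)
    exposure = exposure.reindex(cases.index)
    if exposure.isna().any():
        raise ValueError("exposure column has missing values; drop undefined cases first")
    x = exposure.to_numpy(dtype=float)

    if bases is None:
        x_w, cap = winsorize_99(x)
        nonzero = x_w[x_w > 0]
        nonzero_events = (cases.loc[x_w > 0, "ponv"].sum()
                          if spec.zero_inflated and "ponv" in cases.columns
                          else len(nonzero))
        if spec.zero_inflated and (len(nonzero) < MIN_NONZERO_FOR_SPLINE
                                   or nonzero_events < MIN_NONZERO_EVENTS_FOR_SPLINE):
            # too few exposed cases/events to support 3 spline df next to
            # the any-exposure indicator (overfit/separation risk): linear
            logger.info("only %d nonzero exposures (%s events) for %s: linear exposure term",
                        len(nonzero), nonzero_events, spec.label)
            exp_basis = SplineBasis(knots=np.array([x_w.min(), x_w.max()]),
                                    linear_fallback=True)
            exp_coords = exp_basis.transform(x_w)
        else:
            exp_basis, exp_coords = natural_spline_basis(
                x_w, interior_from=nonzero if spec.zero_inflated and len(nonzero) >= 2 else None)
        age_basis, age_coords = natural_spline_basis(cases["age"].to_numpy(float))
        dur_basis, dur_coords = natural_spline_basis(cases["duration_h"].to_numpy(float))
    else:
        x_w, cap = winsorize_99(x, cap=bases.exposure_cap)
        exp_basis = bases.exposure_basis
        exp_coords = exp_basis.transform(x_w)
        age_basis = bases.age_basis
        age_coords = age_basis.transform(cases["age"].to_numpy(float))
        dur_basis = bases.duration_basis
        dur_coords = dur_basis.transform(cases["duration_h"].to_numpy(float))

    female = cases["female"].to_numpy(float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cases))}
    cols.update(_named("exp", exp_coords))
    if spec.zero_inflated:
        cols["exp_zero"] = (x_w == 0).astype(float)
    for name in ("female", "smoker", "volatile", "ondansetron_ppx",
                 "dexamethasone_ppx", "comorbidity_pos", "risk_surgery"):
        cols[name] = cases[name].to_numpy(float)
    asa = cases["asa"].to_numpy(int)
    for level in (2, 3, 4):  # ASA 1 is the reference
        cols[f"asa_{level}"] = (asa == level).astype(float)
    cols.update(_named("age", age_coords))
    cols.update(_named("dur", dur_coords))
    agefem = female[:, None] * age_coords
    cols.update(_named("agefem", agefem))

    X = pd.DataFrame(cols, index=cases.index)

    if drop_groups:
        unknown = set(drop_groups) - set(VARIABLE_GROUPS)
        if unknown:
            raise ValueError(f"unknown variable groups: {sorted(unknown)}")
        to_drop = [c for c in X.columns for g in drop_groups
                   if any(c == p or c.startswith(p) for p in VARIABLE_GROUPS[g])]
        X = X.drop(columns=sorted(set(to_drop)))

    if bases is None:
        # constant non-intercept columns (e.g. everyone exposed -> exp_zero
        # all zero) are unidentifiable next to the intercept: drop and record
        dropped = [c for c in X.columns if c != "intercept" and X[c].nunique() == 1]
        # binary columns separating the outcome (a zero cell in the 2x2
        # table, e.g. a small ASA-4 group with no events) have no finite
        # MLE and send the GEE to overflow; drop them for this fit
        if "ponv" in cases.columns:
            y = cases["ponv"].to_numpy(float)
            for c in X.columns:
                if c in dropped or c == "intercept":
                    continue
                col = X[c].to_numpy()
                if set(np.unique(col)) <= {0.0, 1.0}:
                    e1, n1 = y[col == 1].sum(), (col == 1).sum()
                    e0, n0 = y[col == 0].sum(), (col == 0).sum()
                    if min(e1, n1 - e1, e0, n0 - e0) == 0:
                        dropped.append(c)
        if dropped:
            logger.info("dropping constant design columns: %s", dropped)
            X = X.drop(columns=dropped)
        # exposure columns can be exactly collinear in sparse splits (one
        # distinct nonzero value makes x a combination of intercept and the
        # zero indicator): resolve by dropping, anything else is an error
        offending = _rank_deficient_columns(X)
        while offending and all(c.startswith("exp_") for c in offending):
            logger.info("dropping collinear exposure columns: %s", offending)
            dropped += offending
            X = X.drop(columns=offending)
            offending = _rank_deficient_columns(X)
        if offending:
            raise ValueError(
                f"design matrix is rank deficient; offending columns: {offending}")
        out_bases = DesignBases(spec.label, cap, exp_basis, age_basis, dur_basis,
                                dropped_columns=tuple(dropped))
    else:
        X = X.drop(columns=[c for c in bases.dropped_columns if c in X.columns])
        out_bases = bases
    return X, out_bases


def _rank_deficient_columns(X: pd.DataFrame) -> list[str]:
    """Columns making the matrix rank deficient (pivoted-QR localization)."""
    mat = X.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank >= X.shape[1]:
        return []
    from scipy.linalg import qr

    _, _, piv = qr(mat, pivoting=True, mode="economic")
    return [X.columns[i] for i in piv[rank:]]


@dataclass
class GEEFit:
    """Result of one exchangeable-GEE logistic fit."""

    columns: tuple[str, ...]
    params: np.ndarray
    cov_robust: np.ndarray
    exchangeable_corr: float
    n_cases: int
    n_clusters: int
    converged: bool
    bases: DesignBases | None = None
    cov_naive: np.ndarray | None = None  # model-based covariance, for diagnostics

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "params": self.params.tolist(),
            "cov_robust": self.cov_robust.tolist(),
            "exchangeable_corr": self.exchangeable_corr,
            "n_cases": self.n_cases,
            "n_clusters": self.n_clusters,
            "converged": self.converged,
            "bases": self.bases.to_dict() if self.bases else None,
            "cov_naive": self.cov_naive.tolist() if self.cov_naive is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GEEFit":
        return cls(
            columns=tuple(d["columns"]),
            params=np.array(d["params"], dtype=float),
            cov_robust=np.array(d["cov_robust"], dtype=float),
            exchangeable_corr=float(d["exchangeable_corr"]),
            n_cases=int(d["n_cases"]),
            n_clusters=int(d["n_clusters"]),
            converged=bool(d["converged"]),
            bases=DesignBases.from_dict(d["bases"]) if d.get("bases") else None,
            cov_naive=(np.array(d["cov_naive"], dtype=float)
                       if d.get("cov_naive") is not None else None),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load_json(cls, path) -> "GEEFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class NonConvergenceError(RuntimeError):
    """GEE failed to converge; the model is excluded, never retained."""


def fit_gee_logistic(
    design: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    clusters: np.ndarray | pd.Series,
    bases: DesignBases | None = None,
    maxiter: int = 60,
    ctol: float = 1e-6,
) -> GEEFit:
    """Fit the marginal logistic model by GEE with exchangeable correlation.

    Coefficients carry the robust (sandwich) covariance. When every
    cluster has one case the estimates coincide with an ordinary
    logistic fit. Raises :class:`NonConvergenceError` on failure.
    """
    y = np.asarray(outcome, dtype=float)
    groups = np.asarray(clusters)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 clusters")
    if y.min() == y.max():
        raise ValueError("outcome is constant")
    cov_struct = sm.cov_struct.Exchangeable()
    X = design.to_numpy(float)
    # standardize columns for the IRLS (cubic spline columns are badly
    # scaled when knots are skewed); exact reparametrization, mapped back
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(y, X / scale, groups=groups,
                           family=sm.families.Binomial(), cov_struct=cov_struct)
            res = model.fit(maxiter=maxiter, ctol=ctol)
        params = np.asarray(res.params, dtype=float) / scale
        cov = np.asarray(res.cov_params(), dtype=float) / np.outer(scale, scale)
        cov_naive = np.asarray(res.cov_naive, dtype=float) / np.outer(scale, scale)
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
            raise NonConvergenceError("non-finite GEE estimates")
    except NonConvergenceError:
        raise
    except Exception as exc:  # statsmodels raises various linalg errors
        raise NonConvergenceError(f"GEE fit failed: {exc}") from exc
    n_iter = len(res.fit_history["params"])
    converged = n_iter < maxiter
    if not converged:
        raise NonConvergenceError(f"GEE did not converge within {maxiter} iterations")
    dep = float(np.atleast_1d(cov_struct.dep_params)[0])
    return GEEFit(
        columns=tuple(design.columns),
        params=params,
        cov_robust=cov,
        exchangeable_corr=dep,
        n_cases=len(y),
        n_clusters=len(np.unique(groups)),
        converged=converged,
        bases=bases,
        cov_naive=cov_naive,
    )


def predict_prob(fit: GEEFit, design: pd.DataFrame) -> np.ndarray:
    """Inverse-logit of the linear predictor; open interval (0, 1)."""
    if tuple(design.columns) != fit.columns:
        raise ValueError(
            f"design columns {list(design.columns)} do not match fit columns {list(fit.columns)}")
    lp = design.to_numpy(float) @ fit.params
    lp = np.clip(lp, -35.0, 35.0)  # overflow guard; expit(±35) is inside (0,1)
    return 1.0 / (1.0 + np.exp(-lp))
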
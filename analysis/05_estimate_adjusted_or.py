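"""Estimate the adjusted hypotension-PONV odds ratio on the estimation arm.

Refits the model with the characterization selected in step 04 on the
independent estimation arm (GEE, exchangeable working correlation) and
reports adjusted odds-ratio contrasts "exposure x versus no exposure"
with delta-method 95% CIs on the robust covariance, plus the point
where the fitted exposure log-odds curve flattens.
"""

import pathlib

import pandas as pd

from ioh_ponv import features, model, pipeline

ROOT = pathlib.Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

if __name__ == "__main__":
    cases = pipeline.read_case_csv(ROOT / "scratch" / "data" / "cases.csv")
    ends = dict(zip(cases["case_id"], cases["duration_h"] * 3600.0))
    series = pipeline.read_timeseries_csv(ROOT / "scratch" / "data" / "timeseries.csv",
                                          anesthesia_end_s=ends)
    grids, _, _ = pipeline.preprocess_cohort(series)
    cases = cases.loc[cases["case_id"].isin(grids)]

    best_label = pd.read_csv(RESULTS / "comparison.csv")["characterization"].iloc[0]
    best = features.CharacterizationSpec.from_label(best_label)
    table = features.compute_feature_table(grids, [best]).loc[cases.index]

    split_df = pd.read_csv(RESULTS / "split.csv")
    est_patients = set(split_df.loc[split_df["arm"] == "estimation", "patient_id"])
    estimation = cases.loc[cases["patient_id"].isin(est_patients)]
    exposure = table.loc[estimation.index, best.label].dropna()
    estimation = estimation.loc[exposure.index]
    print(f"estimation arm: {len(estimation)} cases, characterization {best.label}")

    X, bases = model.build_design(estimation, exposure, best)
    fit = model.fit_gee_logistic(X, estimation["ponv"], estimation["patient_id"], bases=bases)
    fit.save_json(RESULTS / "fit_estimation.json")

    nonzero = exposure[exposure > 0]
    xs = sorted({round(float(nonzero.quantile(q)), 2) for q in (0.5, 0.75, 0.9)}) or [1.0]
    rows = [pipeline.estimate_adjusted_or(fit, best, x).as_row() for x in xs]
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "or_contrasts.csv", index=False, float_format="%.10g")
    for r in rows:
        print(f"OR at {best.label} = {r['x']:g}: {r['odds_ratio']:.3f} "
              f"(95% CI {r['ci_low']:.3f}-{r['ci_high']:.3f})")
    plateau = pipeline.spline_plateau_point(fit)
    print(f"fitted log-odds curve flattens near x = {plateau:.2f}"
          if plateau == plateau else "fitted log-odds curve does not flatten below the cap")
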
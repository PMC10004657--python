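"""Split the cohort and rank characterizations on the shaping arm.

Patient-level split into shaping/estimation halves, then grouped
5-fold x 5-repetition cross-validation of one GEE model per candidate
characterization on the shaping arm; ranking by mean cross-validated
Brier score. Writes comparison.csv (+ bar chart) and split.csv.
"""

import pathlib

from ioh_ponv import evaluation, features, pipeline
from ioh_ponv.plotting import plot_comparison

ROOT = pathlib.Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

CANDIDATES = pipeline.DEFAULT_CONFIG["cv"]["candidates"]

if __name__ == "__main__":
    cases = pipeline.read_case_csv(ROOT / "scratch" / "data" / "cases.csv")
    ends = dict(zip(cases["case_id"], cases["duration_h"] * 3600.0))
    series = pipeline.read_timeseries_csv(ROOT / "scratch" / "data" / "timeseries.csv",
                                          anesthesia_end_s=ends)
    grids, _, _ = pipeline.preprocess_cohort(series)
    cases = cases.loc[cases["case_id"].isin(grids)]
    specs = [features.CharacterizationSpec.from_label(s) for s in CANDIDATES]
    table = features.compute_feature_table(grids, specs).loc[cases.index]

    split = pipeline.split_cohort(cases, seed=12)
    split.to_frame().to_csv(RESULTS / "split.csv", index=False)
    arm = split.case_arm(cases["patient_id"])
    shaping = cases.loc[arm == "shaping"]
    print(f"shaping arm: {len(shaping)} cases "
          f"({shaping['patient_id'].nunique()} patients)")

    plan = evaluation.make_fold_plan(shaping["patient_id"], k=5, reps=5, seed=13)
    comparison = evaluation.rank_characterizations(specs, shaping,
                                                   table.loc[shaping.index], plan)
    df = comparison.to_frame()
    df.to_csv(RESULTS / "comparison.csv", index=False, float_format="%.10g")
    plot_comparison(df, RESULTS / "comparison.png")
    print(df[["rank", "characterization", "brier", "c_statistic"]].round(5).to_string(index=False))
    print(f"selected characterization: {comparison.best.label}")
    if comparison.excluded:
        print("excluded (non-convergent):", comparison.excluded)
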
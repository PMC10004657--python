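"""Generate the default synthetic perioperative cohort.

Writes the two pipeline input tables (long-format blood-pressure
time series and the case/covariate table) plus the generator's ground
truth under scratch/data/, and prints the cohort's headline descriptives.
"""

import pathlib

from ioh_ponv.simulate import SimulationConfig, simulate_cohort, write_cohort_csvs

DATA = pathlib.Path(__file__).resolve().parent.parent / "scratch" / "data"

if __name__ == "__main__":
    cfg = SimulationConfig(n_patients=1000, seed=11)
    cohort = simulate_cohort(cfg)
    paths = write_cohort_csvs(cohort, DATA)
    cases, truth = cohort.cases, cohort.truth
    print(f"cohort: {len(cases)} surgeries on {cases['patient_id'].nunique()} patients")
    print(f"PONV rate: {cases['ponv'].mean():.1%} "
          f"(mean generative probability {truth['true_prob'].mean():.1%})")
    print(f"female {cases['female'].mean():.1%}, smoker {cases['smoker'].mean():.1%}, "
          f"volatile {cases['volatile'].mean():.1%}")
    print(f"median surgery duration {cases['duration_h'].median():.2f} h")
    exposed = (truth['true_exposure'] > 0).mean()
    print(f"any time under 50 mmHg (true exposure): {exposed:.1%} of surgeries")
    print(f"injected artifact samples: {truth['artifact_count'].sum()}")
    print("wrote:", ", ".join(str(p) for p in paths.values()))
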
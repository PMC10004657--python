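# Methods

## Problem and outcome

The pipeline estimates the association between intraoperative
hypotension (IOH) and postoperative nausea and vomiting (PONV) in the
post-anesthesia care unit. PONV is a binary per-surgery outcome; in the
case-table reader it is dichotomized from raw severity entries
("None", "Nausea", "Need_to_vomit", "Vomiting") by taking the most
severe entry per case, so a documented "None" never overrides a
positive entry. Patients contribute several surgeries, so all inference
is clustered by patient.

## Blood-pressure cleaning

Raw records mix invasive sampling (every 15 s or 2 min) and
oscillometric cuff readings (every 3–5 min). Six artifact rules are
applied per surgery: (1) SBP ≥ 300, (2) SBP ≤ 20, (3) DBP ≤ 5,
(4) DBP ≥ 225, (5) SBP ≤ DBP + 5 mmHg, (6) any channel (SBP, DBP, MAP)
outside the surgery's mean ± 3 SD. Rules 1–5 are pointwise predicates
on raw values and are idempotent. Rule 6 runs as a single pass (not
iterated) on the samples surviving rules 1–5, per channel, with
**leave-one-out moments**: the sample being judged is excluded from the
mean/SD it is compared against. With inclusive moments a record of n
samples caps the attainable z-score at (n−1)/√n, so a gross artifact in
a short cuff record could never be flagged; leave-one-out removes that
ceiling and is numerically indistinguishable from pooled moments at
realistic sample counts. Rule 6 is a blunt screen: it also censors
genuine extremes (the deepest induction dips), which attenuates
measured exposure relative to truth; the synthetic generator's defaults
are calibrated so that post-cleaning exposure distributions look like a
real cohort's (below).

MAP is the recorded channel when present (oscillometric and invasive
monitors measure it directly); otherwise DBP + (SBP − DBP)/3. Cleaned
MAP is linearly interpolated onto t = 0, 15, 30, … s up to anesthesia
end; before the first and after the last observation the nearest value
is held constant, so no hypotension is manufactured outside the
observed span. Surgeries with fewer than two usable samples are
excluded and logged. Each grid point accounts for one 15-s slot, so a
grid of n points spans n/4 minutes.

## Exposure characterizations

Four families, 24 metrics (parameters k in minutes, t in mmHg):

- `sustained_lowest_k`: min over all windows of 4k+1 consecutive grid
  points (spanning exactly k minutes) of the window maximum — the
  lowest ceiling MAP stayed at or below for k contiguous minutes.
  Scanning longer windows cannot lower this value (verified by oracle).
- `cumulative_lowest_k`: the ⌈4k⌉-th smallest grid value — the lowest
  observed value v with at least k total minutes at or below v.
- `time_under_t`: 0.25 × #{points with MAP strictly < t} minutes.
- `fraction_under_t`: time_under_t divided by the record span.

"Under" is strict `<`; the sustained/cumulative ceiling is inclusive
`≤`. Records shorter than k minutes yield an undefined (NaN) value and
drop out of that characterization's model only. The two families obey
`cumulative_lowest_k ≤ sustained_lowest_k` and a duality with
`time_under`: time under t reaches k minutes iff the k-minute
cumulative ceiling lies below t (for t not equal to a grid value).
These invariants are enforced by property tests.

## Risk models

Each characterization enters one marginal logistic model with a fixed
adjustment set: female sex, age, smoking, volatile anesthetics,
ondansetron prophylaxis, dexamethasone prophylaxis, Charlson-positive
comorbidity flag, PONV-risk surgery type, ASA class (dummies vs ASA 1),
surgery duration, and female × age-spline interaction. Age, duration,
and the exposure are represented by natural cubic splines with 3 df
(truncated-power natural basis; boundary knots at the observed min/max,
interior knots at the 33.3/66.7 percentiles — of the nonzero values for
zero-inflated exposures). Zero-inflated families (time/fraction under)
additionally carry a binary any-exposure indicator, and the exposure
column is winsorized at its empirical 99th percentile. Postoperative
opioid use is deliberately absent: it is a post-exposure covariate. The
Apfel score (female, non-smoker, PONV history, postoperative opioids)
is computed for reporting only.

Fitting is by GEE (binomial family, logit link) with patient clusters
and an exchangeable working correlation; inference uses the robust
sandwich covariance. Convergence tolerance is 1e-6 on the mean
coefficient change with at most 60 iterations; a non-convergent model
is excluded with a logged reason, never silently retained. Internally
the design columns are standardized for the IRLS and the coefficients
and covariance mapped back — an exact reparametrization that removes
the ~1e4 scale ratios cubic spline columns can reach.

Two desk-scale estimability guards apply during design construction,
are logged, and are replayed verbatim onto held-out data via the stored
bases: (i) a zero-inflated exposure enters linearly instead of with a
spline when the exposed stratum is too thin to identify a curve
(< 40 exposed cases or < 20 events among them — events-per-variable
logic; cohorts of tens of thousands always engage the spline);
(ii) binary design columns whose outcome 2×2 table has a zero cell
(e.g. a 10-case ASA-4 group with no events) are dropped for that fit,
since their MLE is infinite. Exactly collinear exposure columns
(possible when a sparse split leaves one distinct nonzero value) are
dropped the same way; any other rank deficiency is an error naming the
offending columns.

All data-dependent state — winsorization cap, spline knots, dropped
columns — is learned on the fitting data and frozen into the fit
artifact, so held-out designs are built identically and train/test
leakage is structurally impossible. The fit artifact serializes to
JSON.

## Cross-validation and model selection

Model selection uses repeated k-fold cross-validation over *patients*:
every patient's surgeries share a fold, folds are balanced to within
one patient, and the plan is seeded and shared across all candidate
models so comparisons are paired. Within each training split the
winsorization cap and all knots are re-learned. Held-out predictions
are pooled within a repetition, then four metrics are computed per
repetition and averaged (SD across repetitions):

- Brier score: mean (p − y)².
- c-statistic: concordance probability, ties counted ½ (computed via
  ROC-AUC; an O(n²) pair-enumeration oracle checks it in tests).
- discrimination slope: mean p in events − mean p in non-events.
- calibration slope: slope of a logistic fit of y on logit(p); 1 is
  well calibrated, < 1 overfit.

The winning characterization minimizes mean cross-validated Brier
score; exact ties break by higher c-statistic, then lexical label
(deterministic, logged). A repetition containing a non-convergent fold
or a single-class training outcome is excluded and counted. Variable
contributions are the Brier increase when one variable group is
removed — removing sex or age also removes the age × sex interaction —
on the identical fold plan.

The full-scale protocol (10 folds × 40 repetitions) is a config
flag; the package default is 5 × 5, which keeps a full analysis on a
~1300-case desk cohort around a minute on one CPU.

## Split-sample estimation

Patients are shuffled and greedily assigned to the lighter arm by case
count, so shaping and estimation arms are balanced to within the
largest single patient's procedure count and share no patients (audited
from the report bundle). The winning model is refitted on the
estimation arm; the exposure effect is reported as OR(x) = exp{[s(x) −
s(0)]ᵀβ + 1[x>0]β₀} with a delta-method CI (exact on the log scale,
since the contrast is linear in the coefficients). Contrast points
beyond the winsorization cap are evaluated at the cap with a note.
Because "the odds are higher for at least x minutes" phrasings
correspond to a plateau of the fitted curve, the artifact also reports
the first exposure value at which |d log-odds/dx| falls below a
configurable tolerance (default 0.01 per unit), rather than hard-coding
any landmark.

## Synthetic cohort generator

The generator defines the study conditions for every test:

- **MAP process**: deviation from a dipped mean follows the exact AR(1)
  transition of a mean-reverting process — stationary mean = per-case
  baseline ~ N(79, 5²) mmHg, stationary SD 7 mmHg, reversion 0.05/min
  (slow intra-operative wandering), induction dip 20 mmHg decaying with
  τ = 8 min, floor 25 mmHg. Invasive cases sample every 15 s,
  non-invasive at U(180, 300)-s intervals (20% invasive). SBP/DBP are
  MAP-linked through a lognormal pulse pressure (median 45 mmHg):
  SBP = MAP + ⅔PP, DBP = MAP − ⅓PP, so rule-5 filtering is meaningful
  and DBP + (SBP−DBP)/3 reproduces MAP exactly.
  These values were calibrated once against the post-cleaning exposure
  distributions a real cohort shows (≈10% of surgeries with any time
  under 50 mmHg; median fraction under 80 ≈ 0.6; median 5-min sustained
  lowest ≈ 66 mmHg); with a faster-reverting, tighter process the
  pipeline's own rule 6 misclassified most genuine dips as artifacts.
- **Artifacts**: Poisson(rate × hours) inserted samples (default
  2/hour), each violating exactly one of rules 1–5 via fixed prototype
  values, or targeting rule 6 with a large but raw-rule-safe deviation;
  ground-truth labels are returned.
- **Covariates**: surgeries per patient = 1 + Poisson(0.37); female
  54.5%, smoker 32.5%, volatile 64.4%, risk surgery 17.7%, ASA
  48/26/24/2%, comorbidity 35%, duration lognormal (median 100 min,
  log-SD 0.45, clipped 20–480). Sex, age, smoking, comorbidity, and
  PONV history are patient-level.
- **Outcome**: conditional log-odds = intercept (−2.6) + confounder
  terms (female +0.9, age −0.05/decade, smoker −0.35, volatile +0.3,
  each prophylaxis −0.3, comorbidity +0.1, risk surgery +0.55, duration
  +0.25/h) + exposure effect + patient intercept ~ N(0, 0.5²). The
  default exposure effect acts on time under 50 mmHg: a +0.2 any-
  exposure jump plus +0.05 per minute, chosen so the odds ratio at
  ~1.8 min is ≈ 1.34, a realistic effect size for this outcome. The
  per-case true exposure is computed from the clean gridded trace with
  the same characterization code the pipeline uses, and the realized
  event probability is stored.

What the generator does *not* emulate: vasopressor/fluid responses to
hypotension, beat-to-beat waveform artifacts, drift between repeated
surgeries of one patient, informative monitoring choice, or covariate-
dependent exposure (confounding of the exposure itself). Passing tests
therefore demonstrate that the statistical machinery is correct under
the stated generative assumptions, not that the clinical association
holds in real data.

## Marginal vs conditional effects

Generation is conditional on a Normal patient intercept; the GEE
estimates population-averaged coefficients. Recovery tests compare the
estimated contrast with the conditional truth shrunk by the standard
logit-normal attenuation factor √(1 + 0.346σ²) (≈ 4% at σ = 0.5); the
residual approximation error is an order of magnitude below the bias
tolerances used. Recovery experiments feed the model the exposure
computed from the clean trace, isolating estimation from the rule-6
censoring described above, and evaluate the contrast at a point inside
the bulk of the exposed distribution (points near zero are weakly
identified next to the any-exposure indicator).

## Numerical and scale choices

Problem sizes in the test suite are chosen for a single CPU: recovery
uses 100 cohorts of 1000 patients; selection-consistency uses 20
cohorts of 500 patients (~680 cases) with 8 candidate characterizations
under 5 × 5 cross-validation — at the default effect size the ranking
needs ≳650 cases to be informative, and smaller cohorts lose the
signal; pipeline-determinism runs the default 600-patient config twice.
Exposure oracle checks run on 1000 random-walk grids spanning 20–300
minutes. All seeds are fixed constants or derive from a single CLI
seed; identical seeds give byte-identical cohorts, fold plans, and
report CSVs.
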
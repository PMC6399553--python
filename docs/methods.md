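# Methods

This note documents the model, the synthetic-data assumptions, the numerical
choices, and the design decisions taken where the design was genuinely open.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

The outcome is a binary SSI label per patient undergoing gastrointestinal
surgery; the predictors are preoperative blood-test series — for each of 14
common tests, zero or more values per day over an observation interval of 60
(default), 30 or 15 days before surgery, plus age and sex. Day indexing is
"days before surgery": day 0 is the day of surgery and the interval
`[obs_days, 0]` is closed on both ends. Two distinct sources of signal are
modelled: the level/trend of the values, and the sampling pattern (clinicians
test more when they are worried, so counts proxy expert suspicion).

## Temporal abstraction

**Daily grid.** Measurements are averaged per patient × test × day. The
observed/missing mask of this grid is frozen before imputation: all count-
and abnormality-type features are computed from the mask and raw values, so
imputation can never manufacture testing-pattern signal.

**Imputation** fills values for the mean/slope features only:

* *LOCF* — carry the latest earlier value forward in time (from day
  `obs_days` toward day 0). Cells before a series' first observation take the
  per-test cohort mean of observed values: a finite, signal-neutral fill the
  downstream regression requires. A test never observed cohort-wide falls
  back to its reference-range midpoint (with a logged warning).
* *KNN* (k = 5 default) — neighbours are ranked per test by the mean absolute
  difference of standardized values over the pair's jointly observed days;
  a missing cell takes the mean of its raw value among the k nearest patients
  that observed it. Cross-test information is deliberately not used: the
  within-test distance keeps each test on its own scale and avoids imposing a
  cross-test correlation model the data pipeline has no basis for. Patients
  sharing no observed day rank last (used only when closer donors run out);
  with no donors at all the per-test cohort mean is used.
* *Hybrid* (pipeline default) — the farthest column (day = `obs_days`) is
  filled by carrying each series' earliest available observation backward,
  standing in for patient history reaching beyond the interval; KNN
  everywhere else.

**Windows.** Each test's interval is partitioned into S = `[2, 0]`,
M = `[15, 3]`, L = `[obs_days, 16]` by default, overridable per test via
configuration; the boundaries are constrained to s_hi ∈ [0, 2] and
m_hi ∈ [13, 18]. A 15-day interval uses a single window labelled `W`. A
single documented default (rather than per-test hand-tuning from plots)
keeps runs reproducible; the `windowsearch` module exists to choose
boundaries from data instead.

**Feature kinds.** Six per test × window in the full set (FLM): `mean`,
`slope`, `nmbr_test`, `prop_nmbr_test`, `high_abn_prop`, `low_abn_prop`.
The slope's time axis runs *toward* surgery (t = −day), so a value rising as
surgery approaches has a positive sign, matching clinical reading;
single-day windows get slope 0. `prop_nmbr_test` divides the window's
observed-day count by the patient's total over the whole interval (0 when
the total is 0), so the three window proportions of a test sum to 1 for any
patient with at least one observation. Abnormality proportions use the
window's observed count as denominator (0 for empty windows); a value counts
high when strictly above `ref_high`, low when strictly below `ref_low`.
The basic set (BLM) keeps three kinds — `mean`, `slope` and the combined
`abn_prop` — the unique 3-kind reading consistent with a 126-feature
value-only matrix over 14 tests × 3 windows; the published description of
that feature set names four quantities but its own count forces three, so
the count was taken as authoritative. The CRP baseline uses the three CRP
window means. All sets append age and sex.

## Model

L1-penalized logistic regression with per-feature penalty factors:
minimize `(1/N) Σ ℓ(yᵢ, β₀ + βᵀxᵢ) + λ Σⱼ vⱼ|βⱼ|`. Price-derived factors
follow `vⱼ = r_max / rⱼ`. Note the direction this implies: the *most
expensive* test has v = 1 (least penalized) and the cheapest the largest
factor (glucose: 58/23 ≈ 2.52). That is the published formula, and it is
consistent with the observation that price penalization shrinks the model by
letting single dearer tests replace several cheaper ones; prose summaries of
the same scheme sometimes state the opposite direction, which would be
`vⱼ = rⱼ / r_max`. `PenaltySpec` is an explicit vector, so either convention
is one line of user code. Unknown prices in the default catalog (only
leukocytes/thrombocytes at 58 NOK and glucose at 23 NOK are public) default
to evenly spaced values on [23, 58] in catalog order and can be overridden
from JSON.

**Solver.** Features are standardized to zero mean/unit variance inside the
solver and coefficients reported on the original scale. The path runs over
100 log-spaced λ from λ_max (= maxⱼ |x̃ⱼᵀ(y − ȳ)| / (n vⱼ), at which all
penalized coefficients are exactly zero) down to 10⁻³ λ_max, warm-started.
Each λ is solved by IRLS around cyclic coordinate descent on the penalized
weighted least-squares subproblem, with an active-set strategy (iterate the
nonzero set, re-verify with a full sweep). Working weights are floored at
10⁻⁵; convergence is declared when the largest weighted squared coefficient
change in a sweep falls below `tol` (10⁻⁷ default; tests use down to 10⁻¹³).
A relative guard of 10⁻¹⁰ in the soft threshold prevents float round-up at
`|gradient| = λvⱼ` from epsilon-activating a coefficient, so λ ≥ λ_max
returns the exact null model. Solutions satisfy the KKT conditions to
solver tolerance, and a v-penalized fit equals the unit-penalty fit on
columns xⱼ/vⱼ with coefficients divided by vⱼ (both are test invariants,
cross-checked against sklearn's saga L1 solver and the unpenalized
statsmodels MLE).

**λ selection and p_max.** Stratified 10-fold CV (default) scores each λ by
validation AUC (models are tuned for AUC; mean deviance is available);
ties take the largest λ, preferring the sparser model. The cap `p_max`
truncates the candidate grid before the first λ whose *full-data* fit
exceeds `p_max` nonzero features — counting the full-data fit (not per-fold
fits) is what makes the cap a hard guarantee on the returned model.
`p_max = 0` degenerates to the intercept-only model predicting the training
prevalence.

**ROSE.** Class rebalancing by smoothed bootstrap: equal numbers of
synthetic rows per class, each a within-class resample plus Gaussian noise
with per-feature bandwidth `(4/((p+2)n_c))^{1/(p+4)} · sd_c` (Silverman-style
per class, scaled by a `shrink` parameter; 0 = plain duplication). Off by
default: rebalancing was reported to cost a little AUC in the motivating
analysis, and the synthetic experiments here do not need it.

## Evaluation harness

Stratified 80/20 holdout repeated `n_repeats` times (100 default; validation
size ⌊0.2 n⌋, giving 181 patients per repeat at n = 909 and hence 18,100
validation evaluations over 100 repeats). Stratification keeps the ~20%
prevalence in both halves; a split that loses a class is retried with the
next derived seed and logged. The classification threshold maximizes
Youden's J on *training* predictions (candidates: observed scores and
midpoints, ties to the lowest threshold, so separated classes give the gap
midpoint); AUC is the Mann–Whitney statistic (ties ½) and AUPRC the area
under the precision–recall step curve, both via scikit-learn. Aggregates are
means with 95% t-distribution CIs over repeats (the CI method is a package
choice; the source analysis does not state one). Selection frequency counts
repeats with a nonzero coefficient per feature, with the modal sign.

**Cost accounting** uses the most conservative reading of "costs of all
tests recorded": per validation patient, every recorded measurement (within
the observation interval) of every test appearing in that repeat's
selected-feature set is billed at the catalog price; totals are summed over
repeats and variants compared as `1 − cost_B / cost_A`.

## Window-partition search

Daily group-mean curves (cases vs controls) are computed per test from the
daily grid with normal-approximation 95% CIs; days with no observation in a
group are linearly interpolated. The per-day contrast is
`|mean_case − mean_ctrl| / (√(hw_case² + hw_ctrl²) + ε)` with ε = 10⁻⁹;
a window's distance is its mean daily contrast, and a partitioning's score
the product of its window distances (a sum is available — the score and
distance are pluggable by design, as the underlying procedure only sketches
them). Candidates are all C(n, k) unordered selections of k cut days from
the n non-surgery days, the convention that reproduces the published
candidate count (34,220 for n = 60, k = 3); a cut day is the oldest day of
its window and the oldest window absorbs any older residual days, so
distinct selections can map to the same geometry — the enumeration counts
selections. The two-step search takes the argmax within each k ≤ k_max and
then across k; ties prefer smaller k, then lexicographically earliest cuts.
Note that a product score rewards *splitting* a contiguous signal region
into several high-contrast windows rather than isolating it in one; the sum
score does not. Exhaustive enumeration is O(C(n, k)) and intentionally
unpruned.

## Synthetic cohorts

The generator encodes the study conditions the analysis assumes; real
hospital data remains out of reach, so these are stand-ins constrained by
published summary statistics and the reported sign structure.

* **Sampling process.** Per patient and test, the number of values on each
  day is Poisson with piecewise-constant intensity, day weights 3 : 1.5 : 1
  over S/M/L, normalized so the expected count over the 30 days closest to
  surgery equals the test's published mean (`rate30`, from 5.37/30 d for
  hemoglobin down to 1.04 for ALP). Poisson multiplicity produces occasional
  same-day duplicates (probability ≈ λ²/2 per day), exercising the
  daily-mean path without biasing the rate calibration. Resulting daily
  missingness is ~86% (hemoglobin) to ~97% (ALP); the most frequent tests
  land slightly below the ~90% seen in hospital grids because a constant
  long-window intensity is an idealization of history that actually thins
  out further from surgery.
* **Values** are Gaussian around the reference-range midpoint with sd a
  sixth of the range width (reference intervals are standard adult values in
  conventional units). No distributional form is published; Gaussian around
  mid-range is the neutral choice.
* **Planted effects** (defaults chosen once as a realistic signal strength):
  cases get a +1.0 sd CRP shift in the medium window (inflammation), a 1.5×
  medium-window sampling-intensity boost for leukocytes, sodium, hemoglobin
  and thrombocytes (physician suspicion — boosting the medium window, not
  the whole interval, is what produces the reported positive
  `nmbr_test_M`/`prop_nmbr_test_M` signs together with a negative
  short-window proportion), and a 0.1 probability that a leukocyte or
  potassium value is drawn above the upper reference bound. Case count is
  exactly `round(n × prevalence)` (prevalence default 20.13%).
* **Demographics.** Age uniform on [40, 85] (the colorectal-surgery
  demographic), sex Bernoulli(½), both label-independent by default.

**What passing tests do and do not show.** The synthetic cohort has
independent tests, Gaussian values, stationary within-window intensities and
exactly the planted effects — no comorbidity structure, no correlated test
panels, no informative missingness beyond the planted count signal, no
postoperative data. Recovery of the planted structure and the FLM > BLM >
CRP ordering therefore validates the *pipeline* (that testing-pattern
features add signal when such signal exists and that the solver finds it),
not the clinical effect sizes; headline real-cohort metrics are not
reproducible and are not claimed.

## Scale of the shipped experiments

The test suite exercises the harness at n = 909 (bookkeeping, 100 repeats of
a 5-feature baseline), n = 500 (solver optimality on the full 254-column
matrix) and n = 1000 (recovery study, 50 repeats × three feature sets,
10-fold CV) — sizes chosen to match the study's cohort scale while keeping a
full run in the order of ten minutes on one CPU.

## Known limitations

* KNN neighbour ties at equal distance are broken by partition order
  (deterministic for a given input, but not a documented ordering).
* The LOCF leading fill and the KNN cohort-mean fallback inject the cohort
  mean, slightly shrinking between-patient variance for sparsely observed
  tests.
* The hybrid scheme's carry-back at the farthest day uses future values of
  the same series; it emulates "patient history" that the truncated interval
  cannot contain and should not be read as a causal imputation.
* Penalty factors assume every test-derived feature inherits its test's full
  price; marginal-cost reasoning (a test already ordered for another feature
  is free) is handled at the cost-report level, not in the penalty.
* The window-partition enumeration counts cut-day selections, not distinct
  window geometries (see above); with the product score and k_max > 2 the
  optimum tends to subdivide strong signal regions.
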
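# Methods

## Scope and model

`vurscore` builds and evaluates an integer risk score for severe (grade 4–5)
vesicoureteral reflux from patient-level binary predictors. The statistical
model is deliberately simple and fully determined by 2×2 counts:

* **Association screen.** For each candidate predictor, a Pearson chi-square
  test (1 df) on the exposure × outcome table and the cross-product odds
  ratio OR = ad/bc with a Woolf interval,
  exp(log OR ± z₀.₉₇₅ √(1/a + 1/b + 1/c + 1/d)). The continuity correction
  defaults **off**: the uncorrected statistic reproduces the reference
  significance pattern, and the correction is exposed as a flag. A zero cell
  makes the OR undefined; the Haldane–Anscombe rule (+0.5 to every cell) is
  applied when enabled (the default) and recorded in the result.
* **Selection.** Significance gate (p < α, default α = 0.05), then one
  variable per *collinearity group*: within each group the highest-OR
  significant member is kept, ties going to the variable listed first. The
  default groups are the three logically nested chains — ultrasound
  (abnormal USG ⊇ hydronephrosis ⊇ UTD-P3), scintigraphy (any scar ⊇
  multiple scars), infection (UTI ⊇ recurrent UTI, ⊇ non-E. coli) — with
  age < 2 years and male sex as singletons. Grouping the infection variables
  is this package's design choice: they are nested exactly like the imaging
  chains, and without the group a large cohort would anchor the weights on
  the weak recurrent-UTI odds ratio (≈1.2) rather than on a model variable.
  On the reference counts the infection group changes nothing (UTI and
  recurrent UTI fail the gate; non-E. coli is kept either way).
* **Weights.** w = clamp(round_half_up(OR / min OR), 1, ceiling), ceiling 2
  by default. Round-half-up means a ratio of exactly 1.5 becomes 2. Both
  full-precision and display-rounded ORs yield {1,1,1,2,2} on the reference
  counts. The rule is scale-invariant and monotone in the OR, which the
  property tests assert.
* **Scoring.** S = Σ w·x over selected variables; a predictor that is
  *undefined* for a patient (scar variables when no DMSA scan was done)
  contributes 0, so such patients face a capped maximum (5 of 7 under the
  reference weights). Missing is a distinct state end to end — in CSV
  (`NA`), in memory (`None`), and in every 2×2 (pairwise exclusion) — never
  conflated with "no scar".
* **Risk bands.** A single Youden maximization yields one cutoff, but the
  reference stratification has two. The construction adopted here:
  `lower_cut = argmax_t J(t)` (ties → smallest t) and `upper_cut` = smallest
  threshold above it with specificity ≥ a floor, default 0.97. On the
  reference score table this gives 3 and 5 (J = 0.623 at t = 3 narrowly
  beats 0.620 at t = 4; specificity first clears 97 % at t = 5). The floor
  is configurable, and an unreachable floor raises an error carrying the
  full threshold sweep. This two-cutoff rule is an interpretation — the most
  conservative one we found that reproduces the reference bands — and is the
  package's most consequential free choice next to the weight rounding rule.
* **Evaluation.** On a discrete score, AUC is computed from grouped counts
  as the Mann–Whitney probability of correct ranking with ties counted ½,
  identical to the trapezoid area over integer thresholds (asserted against
  a brute-force all-pairs oracle). The default interval is the Hanley–McNeil
  normal approximation; a DeLong structural-component variance is available
  (`ci_method="delong"`). Band and threshold diagnostics follow the 2×2
  identities, with OR intervals by Woolf; degenerate margins produce NaN
  plus an `undefined` flag, never a silent 0.

## Reference counts and the reconstructed cohort

The packaged fixtures carry the reference cross-tabulations: per-variable
exposure counts by outcome group (with the reduced DMSA denominators,
68/439 of 86/958), the per-score outcome distribution over scores 0–7
(958 + 86 = 1044 patients), the three risk bands, and the no-DMSA subgroup
(537 patients, 18 severe; 9/24 severe at the capped top score vs 9/513
below it).

`reconstruct_reference_cohort()` expands a frozen predictor-pattern table
(plain-text package data) into a deterministic 1044-record cohort whose
score distribution matches the packaged score table **exactly** and whose
per-variable margins match the packaged screening counts — with one forced
exception. The printed severe-group margins are arithmetically inconsistent
with the printed score distribution: under weights {1,1,1,2,2} the severe
margins sum to 337 weighted units while the severe scores sum to 365. No
cohort can satisfy both. The reconstruction therefore keeps the score table
(the basis of every band and threshold quantity) and every other margin
exact, and absorbs the 28 missing weighted units in the single severe
UTD-P3 margin (57 instead of 43) — the unique minimal-deviation solution
confined to one margin. Consequence: odds ratios *screened from the
reconstructed cohort* match the fixture-derived ones for every variable
except UTD-P3 (≈11.7 vs 5.9); quantitative screening statements should be
computed from the fixture counts, which is what the pipeline's
`screen_counts` path and the acceptance script do. The pattern table was
solved once as an integer program and frozen; reconstruction at run time is
table expansion, no solver involved.

Two display values in the reference tables are not recoverable from their
own counts and are treated as approximate: the non-E. coli OR (displayed
2.6; the counts give 2.16) and the AUC (displayed 0.901; the half-tie
statistic on the score table gives 0.898). Similarly the displayed
recurrent-UTI p-value (0.117) disagrees with its count chi-square (≈0.49);
only the significance pattern is asserted.

## Synthetic-cohort generator

`generate_cohort` emulates the study conditions: n = 1044, severe-VUR
prevalence 86/1044 ≈ 8.2 %, DMSA missing in 537/1044 ≈ 51.4 % of patients,
and per-outcome-group predictor frequencies equal to the reference
screening counts. Sampling order: outcome first; then each nested chain
from its most specific member (UTD-P3, multiple scars, non-E. coli +
recurrent UTI), with implied ancestors forced and residual probabilities
derived so every marginal matches its target exactly in expectation, e.g.
P(hydronephrosis | group) = p_utd + (1 − p_utd)·r. Infeasible marginal sets
(a child more likely than its ancestor) are rejected before sampling.

What the generator does **not** emulate:

* dependence between predictors beyond the forced implications — within an
  outcome group everything else is conditionally independent, which is the
  simplest joint law consistent with all the marginal targets but certainly
  not the truth (age, sex and imaging findings are correlated in real
  congenital reflux);
* outcome-dependent DMSA missingness. In the reference data the no-DMSA
  subgroup has *lower* prevalence (3.3 % vs 8.2 %), i.e. scanning was not
  random. The default keeps missingness independent of outcome;
  `dmsa_missing_rate_severe` exposes an outcome-dependent rate for
  sensitivity studies;
* continuous age, longitudinal UTI recurrence, and VUR grade levels.

Passing tests on synthetic cohorts therefore demonstrate the pipeline's
correctness under the stated marginal structure, not its clinical
performance on real populations.

## Known limitation: weight recovery at n = 5000

The test suite includes a pipeline parameter-recovery property: weights
{1,1,1,2,2} recovered from calibrated synthetic cohorts of n = 5000 in at
least 90 % of 20 seeds. Under the calibration itself this bound is not
attainable, and the test is expected to fail: the male and non-E. coli odds
ratios sit at ≈1.24× the age odds ratio, only ~0.19 log-units below the
weight rule's 1.5 rounding boundary, i.e. ≈1.2 standard errors of the
log-OR difference at this sample size (the SE is dominated by the ~100
age-negative severe cases). Per-seed recovery is ≈⅔; the observed rate and
the analysis are reported rather than the conditions being altered. The
property would hold at n ≳ 30 000, or under a weight rule whose 1→2
boundary lies at ratio 2 — but the round-half-up rule is fixed by the
boundary behaviour documented above.

## Numerical conventions and test design

* Display rounding is one decimal, half away from zero (`round_half_away`);
  all internal values stay at full precision. Every reference CI reproduces
  at one decimal under this convention.
* χ² p-values are asymptotic upper-tail probabilities. The test suite
  validates them against a fixed-margin permutation oracle using the
  classical correspondence: the Yates-corrected p tracks the permutation
  tail probability even on an 8-subject table (within 0.01), while the
  uncorrected Pearson p tracks the permutation *mid*-p once expected cell
  counts are moderate. The uncorrected p is not, and should not be expected
  to be, close to the raw permutation tail probability on tiny tables
  (0.157 vs 0.486 on the 8-subject example).
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit parameters; identical seed + parameters give bitwise-identical
  cohorts and byte-identical report bundles.
* Problem sizes in the default test run: 200 seeded cohorts of n = 1044 for
  the prevalence calibration, 20 cohorts of n = 2000 for the null-AUC
  check, 20 cohorts of n = 5000 for weight recovery, and 100 random small
  score distributions (≤ 200 patients) for each evaluation oracle; the
  whole suite runs in well under a minute.
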
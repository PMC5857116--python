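# Methods notes

This note records the statistical conventions, numerical choices and design
decisions behind the package, in the order the pipeline runs them.

## Data model and accounting

Responses live in a persons × items float matrix with cells 0/1/NaN; a single
NaN sentinel represents missingness, and the CSV reader accepts the spellings
"", "NA", "NaN" (case-insensitive).  Malformed cells become missing and are
counted, never silently repaired.  Person order is preserved by every filter
so row indices stay joinable without keys.  Endorsement tables keep the full
analysed N as the percentage denominator even when an item has missing cells,
matching the reporting convention of the validation study.  Likert sources
(1–4) are dichotomised at a configurable threshold, default 3 ("quite a
bit"), the conventional clinical-relevance cut for these instruments; a
threshold of 1 is rejected because it maps every observed value to 1.

## Scoring

The screening rule is scored exactly as fielded: with early exit enabled, a
positive immediate screen-in answer classifies the person positive and the
scale total is undefined (the remaining items are never administered).
Without early exit the 7-item unweighted sum is compared against the
cut-score.  Missing scale answers at scoring time follow one of two explicit
policies: `zero` (count as 0, flag — a field tool must degrade gracefully) or
`strict` (raise).  The diagnostic-accuracy analyses use the complete-case
7-item sum for **all** retained persons, including those positive on a
screen-in item: whether such persons should be excluded is not decidable from
the published account, so the scorer exposes the choice
(`scale_scores(..., complete_only=...)` plus row selection) and the pipeline
defaults to include.

## Conditional maximum likelihood Rasch estimation

Difficulties maximise the conditional likelihood given raw-score margins.
Elementary symmetric functions γ_r and their first/second partials are
evaluated with the log-domain summation recursion (numerically safe for any
difficulty spread; exact against brute-force pattern enumeration for m ≤ 10,
which is a test oracle).  Newton iterations use the analytic gradient and
Hessian, the first item fixed during iteration for identification, a step cap
of 3 logits for stability, and convergence at gradient ∞-norm < 1e−8
(typically 4–6 iterations).  Estimates are reported sum-zero; standard errors
come from the observed information via the delta method to the centred
parameterisation.  Items with zero or full endorsement among non-extreme
persons raise an error naming the item.  Persons with missing cells are
excluded from estimation (complete-case CML); persons with zero or perfect
raw scores carry no conditional information and are excluded from estimation
and fit statistics.

Abilities are ML per raw score (solving Σ_i σ(θ − β_i) = r by bisection),
with SE = 1/√(Σ p(1−p)).  Extreme-score abilities are undefined under ML; for
the uses that need finite values (reliability, null simulation) they are
assigned by natural-cubic-spline extrapolation of θ(r) to r = 0 and r = m —
the convention of the standard conditional-ML software.

**Item fit.**  Standardized residuals z = (x − E)/√(E(1−E)) with E from the
raw-score ability; outfit = mean z², infit = Σ(x−E)²/ΣE(1−E); t statistics by
the Wilson–Hilferty cube-root transformation with the kurtosis-based variance
(Bernoulli fourth central moment W(1−3W)).  Per-item χ² = Σz² with
df = (non-extreme n) − 1 — the df convention is an assumption recorded here,
as the published df column is garbled in the source — and the p-value is
Bonferroni-multiplied by the number of items.  Flag bands: mean squares
outside (0.60, 1.40) or |t| > 2.50.

**Reliability.**  PSI = (var(θ̂) − mean SE²)/var(θ̂), clipped to [0,1], with
the variance over all complete-case persons (extremes at their extrapolated
abilities) and the mean squared SE over non-extreme persons.  This is the
separation-reliability convention of the reference R implementation, and it
is not optional: restricting the variance to non-extreme persons roughly
halves the index on score distributions typical of a ~30%-endorsement
screening scale — arithmetic on the published per-cutoff SN/SP cells (which
fix the case and non-case score distributions) gives ≈ 0.37 instead of the
published 0.75.  The mean inter-item correlation is the average
pairwise-complete Pearson correlation, the small-scale complement to PSI
(optimal range 0.20–0.40; the study itself reported 0.46).

## Dimensionality and local dependence

**Modified parallel analysis.**  Statistic: second eigenvalue of the
inter-item tetrachoric matrix.  Tetrachorics are ML on each 2×2 table
(thresholds from the margins, correlation solved by bisection), with a 0.5
continuity correction on empty cells; bivariate normal rectangle
probabilities use Owen's T function (checked against an independent
multivariate-normal CDF to 5e−7).  A non-positive-semidefinite matrix is
repaired by clipping negative eigenvalues, with a warning.  The null
distribution simulates from the fitted Rasch model (not a 2PL — the original
procedure's generator is ambiguous, and the Rasch fit is what the pipeline
has; recorded in report metadata) using each person's estimated ability,
extremes at anchor abilities solved for expected scores 0.3 and m − 0.3.
p = (1 + #{null ≥ observed})/(n_mc + 1); the add-one convention avoids p = 0.
Default 2000 Monte-Carlo samples (the study's figure); tests use 100–150 for
speed, which the calibration test shows is already uniform under the null.

**Ponocny's T1.**  For each item pair the statistic counts persons answering
both items identically; one-sided toward excess agreement (positive local
dependence).  The reference distribution is sampled by an MCMC over 2×2
checkerboard swaps, which exactly preserve all row and column margins and
connect the whole fixed-margin reference set, so larger alternating
rectangles are unnecessary for correctness (they would only speed mixing).
Rows are put in canonical (lexicographic) order before the chain starts —
the pair statistics ignore person order, and a canonical start makes the
p-values exactly invariant to person reordering.  Sampler defaults: burn-in
1000 sweeps, thinning 16, 500 samples (one sweep = n proposals); these are
conservative for a 185 × 7 matrix, where the test-suite GOF check shows far
smaller chains already sample the reference set uniformly.  A degenerate
matrix with no admissible swap emits the observed matrix with a warning.

## Differential item functioning

Logistic-regression method, matching on the total scale score including the
studied item (purification is deliberately not applied — the published
analysis gives no indication of it).  Default is the joint df = 2 test
(uniform + non-uniform DIF); a pure-uniform df = 1 variant is available.
Effect size: Nagelkerke ΔR² between the group-augmented and score-only
models, clipped at 0 against numerical noise, classified negligible/<0.035,
moderate/≤0.07, large/>0.07.  Complete separation falls back to an
L1-penalized likelihood and flags the result.  BH adjustment is applied per
grouping variable across the seven items (eight families of seven); the
family choice is configurable.  Covariate dichotomizations follow the study
(age at the median split, origin as Southern Asia vs other) and are carried
as plain categorical columns, so any two-level labelling works.

## Diagnostic accuracy

ROC points are computed at every observed threshold of the integer score
("positive" ⟺ score ≥ c) plus the (0,0)/(1,1) endpoints; the trapezoid AUC
then equals the Mann–Whitney concordance estimator exactly (ties get half
credit), which a brute-force pairwise oracle verifies.  The AUC interval is
DeLong's, Wald-type, clipped to [0,1].  Optimism correction follows Harrell:
refit the univariable logistic model caseness ~ score on each of 200
bootstrap resamples and subtract the mean of (boot-sample AUC − original-
sample AUC of the boot model).  With a single monotone predictor the model's
ranking equals the score's, so the correction measures pure sampling
optimism; single-class resamples are redrawn and counted.  The per-cutoff
table uses Clopper–Pearson intervals for proportions and log-method Wald
intervals for likelihood ratios (the study's CI method is unstated; the
choice is recorded in the output).  Youden's statistic is reported both as
the published sum SN + SP and as the conventional SN + SP − 1; the optimal
cutoff is the argmax (ties to the lower cutoff), and the
sensitivity-privileged cutoff is the **highest** cutoff with SN ≥ floor
(default 0.90) — the rule that reproduces the published preference for
cut-score 2 over the Youden-optimal 3.

## Synthetic cohorts

The generator implements the measurement model the analyses assume: caseness
~ Bernoulli(0.33); distress θ from a two-component normal mixture; item
endorsement Bernoulli(σ(θ − β)) at the published sum-zero difficulties;
screen-in items from caseness-conditional rates (0.35 | case, 0.05 |
non-case — ansatz values, since no generative account of these items was
published); covariates from the published marginal frequencies; optional
uniform DIF as a per-group difficulty shift; optional second latent factor
for an item subset; MCAR missingness last (per-cell rate; 0.004 reproduces
the ~3.6% incomplete records of the study).  The caseness→trait link is a
mixture rather than a logistic link on θ because it is directly tunable to
the published score separation.

Trait defaults (non-case mean −2.6, case mean +0.9, SD 1.55) were solved
once from the published tables, jointly matching five printed anchors:
prevalence 33%, mean endorsement ≈ 30%, the case/non-case score
distributions implied by the per-cutoff SN/SP column (case mean score ≈ 4.3,
non-case ≈ 1.0), scale-score AUC ≈ 0.91, PSI ≈ 0.75 and mean inter-item
r ≈ 0.46.  A narrower 2-logit separation at unit SD — the naive first guess —
cannot satisfy the endorsement, AUC and PSI anchors simultaneously.

What the generator does **not** emulate: covariate dependence beyond
marginal frequencies (covariates are mutually independent and independent of
θ unless DIF is injected), informative missingness, item-specific
guessing/discrimination, and any administration effects (interpreter,
administrator).  Passing tests therefore demonstrate correctness of the
*procedures* under the stated measurement model, not robustness of the
instrument to violations of it.

## Problem sizes in the test suite

Calibration experiments run at sizes chosen to keep Monte-Carlo error well
inside the asserted bands while the full suite stays fast: parallel-analysis
uniformity at 150 replicates × 100 null samples (KS at the 1% level); T1
null rejection over 100 replicates × 10 pairs; DIF type-I over 400
replicates at n = 400 and power over 50 replicates at n = 1000; optimism
bound over 100 simulations at 200 resamples; difficulty recovery over 20
replicates at n = 1000.  All random draws are seeded; the suite is fully
deterministic.

## Known limitations

* CML here is complete-case; missing-data CML via subgroup ESFs is not
  implemented (the study also analysed complete cases only).
* The published moderate-DIF finding (ΔR² = 0.04 for the fearful item by
  support agency) depends on the original data and is not a reproduction
  target; the pipeline demonstrates type-I calibration and power for the
  method instead.
* Tetrachoric estimation uses the two-step threshold-then-correlation ML,
  not full trivariate ML; differences are far below the Monte-Carlo noise of
  the parallel-analysis null.
* CART split ties are broken by the seeded deterministic splitter of the
  tree backend rather than an explicit lowest-index rule; retained sets are
  reproducible and person-order invariant, which is what the cascade needs.
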
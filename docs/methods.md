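# Methods

## The model

The package implements the Analytic Hierarchy Process (AHP) for eliciting
patient preferences over clinical endpoints of antihypertensive treatment.
A respondent compares criteria pairwise on the multiplicative Saaty scale
(the 17 values 1/9, 1/8, …, 1/2, 1, 2, …, 9), producing a positive
reciprocal judgment matrix *A* with *a<sub>ij</sub>* ≈ *w<sub>i</sub>* /
*w<sub>j</sub>*. The priority weights *w* are the normalized principal
right eigenvector of *A* (Perron–Frobenius guarantees a unique positive
one). For a perfectly transitive respondent the principal eigenvalue
λ<sub>max</sub> equals the matrix order *n*; the excess is summarized by

- consistency index CI = (λ<sub>max</sub> − *n*) / (*n* − 1),
- consistency ratio CR = CI / RI,

where RI is the mean CI of random Saaty-scale reciprocal matrices of the
same order. A matrix is called consistent at Saaty's classical bound
CR ≤ 0.1, or at the relaxed bound CR ≤ 0.2 appropriate for complex
surveys that cannot be revised mid-interview; the relaxed bound is the
individual-level threshold throughout, the strict bound applies to group
matrices.

The endpoint hierarchy has two levels: five first-level criteria
(mortality, myocardial infarction, stroke, heart failure, aggregated
adverse events) and four adverse events (pain, dyspnea, cough, edema)
below the adverse-events criterion. A child's global weight is its local
weight times the parent's global weight; leaf globals sum to one.

Group weights use geometric means, which are the consistency-preserving
mean for ratio judgments. Two routes exist:

- **AIP** (aggregation of individual priorities): component-wise geometric
  mean of the respondents' priority vectors, renormalized. This is the
  default, because the bundled study data consist of priority vectors.
- **AIJ** (aggregation of individual judgments): element-wise geometric
  mean of the judgment matrices (automatically reciprocal), then the
  eigenvector. Available when raw matrices exist (simulated cohorts, raw
  judgment CSVs); coincides with AIP exactly when every respondent is
  perfectly consistent.

Because the study's raw matrices were never published, group weights
recomputed by AIP from the printed individual vectors differ from the
published group rows by up to ~0.017 on single components (the published
rows were evidently AIJ-derived); orderings and the subgroup
rank-reversal pattern reproduce exactly. The acceptance tests keep the
±0.01 comparison and two of them fail for this reason; this is a property
of the available data, not of the implementation.

The fourth analysis phase regresses the dichotomized individual
consistency verdict (CR > 0.2) on VAS utility, gender, age, treatment
duration and treatment scheme with a binary logistic model. Since the
source analysis's reference coding is unknown, the reproduction targets
are the coding-invariant summaries: −2 log-likelihood, Cox–Snell
R² = 1 − exp(−χ²/n), Nagelkerke R² (Cox–Snell rescaled by its maximum
1 − L₀^(2/n)), and the omnibus likelihood-ratio test. These reproduce the
published values to three decimals on the bundled cohort.

## Numerical choices

- **Eigenvector**: power iteration from the uniform vector, renormalizing
  to sum 1 each step, stopping when successive iterates differ by less
  than 1e-10 in max-norm (cap 10 000 iterations, never reached for valid
  matrices); λ<sub>max</sub> is the mean of the component-wise Rayleigh
  ratios (*Aw*)<sub>i</sub>/*w*<sub>i</sub>. Agreement with a dense
  eigensolver is tested to 1e-8.
- **CR edge cases**: reciprocal matrices of order ≤ 2 are always
  transitive, so CR is defined as 0 there (no division by RI = 0); tiny
  negative CI from floating-point residue is clamped to 0.
- **RI table**: CR uses the classical published values (0.58, 0.90, 1.12,
  … up to order 10). The Monte-Carlo generator (`random_index`) draws
  upper-triangle entries uniformly from the 17 Saaty values and averages
  CI over ≥ 1000 matrices. At 100 000 samples it reproduces the classical
  table within 0.02 for orders 4 and 5 but yields ≈ 0.52 for order 3 —
  matching modern recomputations, which disagree with the classical 0.58
  at that order. CR results are unaffected since they use the classical
  table.
- **Fixture renormalization**: printed weight rows are 3-dp rounded;
  every row is renormalized to sum 1 before use. Rows deviating from 1 by
  more than 0.01 (one corrupted level-2 row in the bundled table, which
  sums to 2.008 as printed) are additionally flagged with a logged
  warning; the printed cells are never silently altered.
- **Consistency flags**: the bundled table's verdicts follow the source's
  explicit markings rather than recomputing from the 2-dp printed CRs,
  because two respondents print CR exactly 0.20 and rounding at the
  boundary is ambiguous. An explicit threshold argument recomputes flags
  from CRs when wanted.
- **Logistic fit**: statsmodels GLM with binomial family (IRLS, deviance
  tolerance 1e-8, cap 50 iterations). Wald CIs use ±1.96·SE. No
  penalization at n = 26; instead the result carries a small-sample flag,
  and quasi-separation (|coef| > 30 or SE > 1000 or non-convergence) is
  flagged rather than raised. P-values are reported but never used for
  selection — the analysis is exploratory.
- **VIF**: statsmodels' variance inflation factor on the 0/1-encoded
  design; exact collinearity reports `inf` instead of raising.
- **Rank reversal**: a pair counts as reversed only when both weightings
  order it strictly and the orders differ; ties never count.

## The synthetic-data generator

`simulate_respondent` draws each upper-triangle entry as
(*w<sub>i</sub>*/*w<sub>j</sub>*)·exp(ε), ε ~ Normal(0, σ²), then rounds
to the nearest Saaty value in log space (noise is multiplicative because
the scale is); reciprocals are filled in. `simulate_cohort` draws
covariates with fixture-matched marginals — age ~ Normal(61, 12²)
truncated to [18, 100], duration ~ Normal(9.8, 6.9²) truncated at 0, VAS
resampled from the 26 bundled values, 50% male, 65% combination therapy —
and gives respondent *i* the noise scale σ<sub>i</sub> = σ·exp(Σ β<sub>c</sub>
z<sub>c</sub>), with z standardized continuous covariates and centered
binary indicators, so inconsistency is covariate-linked with an
interpretable ground truth. One generator seed reproduces a cohort bit
for bit; the draw order (covariates first, then per respondent the
level-1 followed by the level-2 matrix) is part of the contract and is
cross-checked against an independently coded generator in the tests.

Defaults are the study conditions: n = 26, true weights equal to the
published group weights, and σ = 0.9, calibrated once on a
4000-respondent pilot so that ≈ 46% of respondents exceed CR 0.2 at the
first level, the study's observed rate.

What the generator does *not* emulate: ordinal response heuristics,
anchoring, interviewer and social-desirability effects, or any systematic
(non-random) intransitivity. Passing pipeline tests on simulated cohorts
therefore demonstrates correctness of the computational chain under the
stated noise model, not validity of AHP elicitation for real respondents.
Note also that the Saaty discretization alone produces small nonzero CR
whenever true weight ratios fall between scale values, so the exact
noise-free identity (σ = 0 ⇒ CR = 0 and recovery of truth) holds only
for truths whose ratios are representable on the scale; tests of that
identity use such truths.

## Problem sizes

All fixture-based results are exact recomputations on the 26-respondent
cohort and run in milliseconds. Simulation-backed tests use cohorts of
10–2000 respondents and the Monte-Carlo random-index check uses 100 000
matrices per order — sizes at which Monte-Carlo error is well inside the
asserted tolerances while the whole suite stays fast.

## Known limitations

- Exact reproduction of the published group weight rows is impossible
  from published data (raw matrices unavailable); see above.
- No fuzzy or interval AHP, no incomplete-matrix completion, no
  row-geometric-mean prioritization, no treatment alternatives below the
  criteria (the survey design has none).
- The inconsistency regressions on n = 26 are exploratory by
  construction; odds ratios are displayed but only likelihood-invariant
  summaries are asserted anywhere.
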
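# Methods

## Score construction

The SDDS is a fixed-weight composite: every item is mapped to [0, 1] with 0
at the most advantaged response and 1 at the most disadvantaged, and the
total is an unweighted mean. Two constructions are implemented because both
appear in the composite-index literature:

- `item_mean` (default): mean of all item scores, so domains contribute in
  proportion to their item counts (5 economic items out of 17 give economic
  stability weight 5/17);
- `domain_mean`: mean of the five domain means, weighting domains equally
  regardless of item count.

The two coincide only when every domain has the same item count; the
package exposes the mode rather than taking a position on which is
preferable.

Choices inside the scoring rules:

- **Intermediate categories** are equally spaced (`k/(K−1)`). Only the
  endpoints are pinned by the construction; equal spacing is the minimal
  assumption absent category weights, and it keeps the score invariant to
  merging-free relabelings.
- **Continuous items** rescale on the instrument's *theoretical* bounds from
  the codebook, not the sample min/max, so scores are comparable across
  cohorts. Out-of-range values raise errors rather than clamp: a value
  outside the instrument's bounds is a data error, not a tail observation.
- **Reverse-coded instruments** (walkability, safety, cohesion, support —
  all scored advantage-high by their instruments) are flipped after
  rescaling.
- **Employment** is coded with "employed for wages" as the advantaged
  category, following the usual deprivation-index convention. Note that in
  an all-comers research cohort with many retirees this item can correlate
  *negatively* with the other economic items (affluent retirees are not
  employed for wages); its default generator loading is correspondingly
  small (0.2).
- **Missing data**: two policies run in parallel. `available` averages the
  observed items (any number ≥ 1; `n_items_observed` is reported so users
  can impose their own coverage threshold), `complete` is missing as soon as
  any item is. No imputation is attempted — the missing-indicator analysis
  (below) is the principled alternative when missingness is informative.

**Quintiles** are equal-count rank groups. When the non-missing count is not
divisible by 5, the remainder is assigned one participant each to the
most-advantaged (lowest-score) groups, and ties break by stable input
order; 117,783 scores therefore split 23,557/23,557/23,557/23,556/23,556.
This makes the partition deterministic even with heavily tied scores.

## Variable reduction

Exploratory factor analysis on the unit-scored items, complete-case (the
dropped-row count is logged and exposed as `n_dropped_rows_`):

- **Extraction**: principal-axis factoring. Communalities start at squared
  multiple correlations (ridge-free; a max-correlation fallback covers
  singular correlation matrices) and iterate on the reduced correlation
  matrix to a 1e-6 communality tolerance, max 200 iterations.
- **Factor count**: Kaiser criterion (eigenvalues of the correlation matrix
  > 1) when `n_factors="auto"`; a fixed count can be supplied.
- **Rotation**: varimax via pairwise Kaiser sweeps with the analytic
  per-pair angle. The gradient-projection/SVD formulation was rejected: on
  near-symmetric two-factor structures it converges sublinearly and stalls
  visibly short of the optimum, while pairwise sweeps reach the same
  solution as a grid search over rotation angles in a handful of sweeps.
  Factors are then ordered by explained variance and signed so each
  factor's largest-magnitude loading is positive, making results
  deterministic and orientation-stable.
- **Selection**: items with max |loading| > 0.4 (threshold configurable) are
  grouped by dominant factor; a group is retained only if its Cronbach's
  alpha exceeds 0.7. Alpha is undefined for single-item groups, which are
  therefore dropped — a one-item "factor" has no internal consistency to
  attest. The alternative SDDS is the available-case mean of the selected
  items.

Cronbach's alpha is computed from the raw variance decomposition
`(k/(k−1))(1 − Σ var_i / var_total)` with sample (ddof=1) variances; a
zero-variance row sum raises an error rather than returning ±inf.

## Association models

- **Logistic fits** use maximum likelihood (Newton, BFGS fallback). A
  constant outcome, non-convergence, or non-finite standard errors (the
  signature of complete separation) raise a `FitFailureError`; the battery
  catches per-cell failures and marks them `FIT_FAILED` instead of
  aborting.
- **Exposure forms**: quintile contrasts with Q1 as the reference row (OR
  fixed at 1, no CI); per-10% (the exposure enters the design divided by
  0.1, so `exp(β̂)` is the per-0.1-unit OR — identical by ML invariance to
  `exp(0.1·β̂)` on the native scale); and quintile-plus-missing, where
  quintiles are cut among complete-score participants and everyone else
  forms the sixth "Missing" category. When no one is missing, the indicator
  column would be identically zero and is dropped, collapsing to the plain
  quintile form.
- **Covariates**: Model 1 none; Model 2 age, sex at birth, race, ethnicity,
  birthplace, marital status, smoking, alcohol; Model 3 adds type 2
  diabetes and obesity; the HCC cell additionally gets an HBV/HCV-adjusted
  variant. Age is continuous in years; all other covariates are
  dummy-coded with fixed, most-prevalent-advantaged reference levels
  (White, Male, Not Hispanic or Latino, USA, Married, No, Never) for
  reproducibility. "Unavailable" is retained as an explicit category for
  categorical covariates; rows missing a continuous covariate are dropped
  with a logged count.
- **CIs** are 95% Wald on the log-odds scale throughout. No
  multiple-testing adjustment is applied; the battery reports two-sided
  p-values as-is.
- **Ordinal model**: proportional-odds (cumulative logit) on the condition
  count (0/1/2/3plus) via BFGS. The design is rescaled to unit variance
  internally — the age column otherwise dominates the curvature and slows
  convergence badly — and the exposure coefficient is transformed back.
  The implementation was cross-checked against R's `MASS::polr` (agreement
  to four decimals on a common dataset).
- **Stratified analyses** (age < 65 / ≥ 65 at survey, female / male) reuse
  whole-cohort quintile cutpoints rather than re-deriving them per stratum,
  so contrasts stay comparable across strata.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real survey's content:

- **Items**: a single latent standard-normal disadvantage factor; each
  item's propensity is `λ·Z + √(1−λ²)·ε` (standard normal marginals),
  thresholded at equal-probability cutpoints into ordered categories or
  mapped through the normal CDF onto the instrument's range. Default
  loadings (0.2–0.75) make the economic items the strongest markers of
  disadvantage, mirroring their role in published deprivation indices.
- **Covariates**: age is normal with mean decreasing in Z (−2.5 years per
  latent SD; disadvantage skews younger in volunteer cohorts); categorical
  covariates follow latent-shifted multinomials (more female, Black,
  Hispanic, unmarried, smoking at higher Z; less frequent alcohol use).
- **Missingness** is MAR given the latent factor: per-item probability
  `expit(logit(base) + slope·Z)` with base 0.03 and slope 0.7, which yields
  roughly 40% of participants missing at least one of 17 items and makes
  the missing group more disadvantaged than complete cases — the pattern
  the missing-indicator analysis is designed to surface.
- **Outcomes**: eight non-mutually-exclusive conditions, each Bernoulli
  with `logit p = b0_c + log(OR_c)·(SDDS/0.1) + γ·L`, where `L` is a shared
  standard-normal liability (γ = 0.8) producing realistic multi-condition
  counts. Default per-10% ORs: SLD 1.25, MASH 1.27, ALD 1.15, cirrhosis
  1.31, HCC 1.35, HBV 1.24, HCV 1.40, hepatic failure 1.35. Per-condition
  prevalence weights follow the relative case frequencies of a large
  EHR-based cohort, and a single global scale is solved (Brent root
  finding on the expected union) so the eight-category union prevalence
  hits the 9.17% target; intercepts are then solved per condition on the
  realized linear predictors. Calibration is part of the generative model
  and is deterministic given the seed.
- Participants also receive benign unmapped condition codes at rate 0.15 to
  exercise the mapping step's ignore-unknown behaviour.

What the generator does **not** emulate: real item marginals (unit scores
are uniform by construction, so cohort mean SDDS is ≈ 0.5 rather than the
left-skewed distributions real instruments produce), item-specific
missingness patterns, covariate–outcome confounding (covariates depend on
Z only, so Models 2–3 shift estimates little), visit-level EHR structure,
and dated diagnoses. Passing recovery tests therefore demonstrates that the
estimators recover what was planted under the assumed structure — not that
real data satisfy that structure.

For parameter-recovery checks a *clean* configuration is used: one
condition, no shared liability, no missingness, so the planted per-10% OR
is exactly the logistic estimand and the computed score equals the true
score. Recovery under the full default configuration is still exercised,
but marginal estimates there are not expected to equal the conditional
planted values (unobserved-heterogeneity non-collapsibility).

## Determinism and problem sizes

All randomness flows from a single integer seed through named
`SeedSequence` streams; output CSVs are written with a fixed float format,
so a pipeline re-run with the same config is bit-identical. The shipped
tests and the acceptance script use cohorts of 10,000–100,000 and
50–100 replicates for coverage-style checks — sizes at which Monte-Carlo
error is comfortably inside the asserted tolerances while the whole suite
runs in a few minutes on one CPU.

## Known limitations

- Unit scoring assumes categories are ordinal and roughly equally spaced;
  strongly non-linear category effects would need item-specific weights,
  which the construction deliberately avoids.
- Principal-axis factoring on Pearson correlations treats the (bounded,
  sometimes binary) unit scores as interval data; polychoric correlations
  are out of scope.
- The proportional-odds model's common-slope assumption is not tested
  internally.
- The missing-indicator category mixes missingness mechanisms; its OR is
  interpretable as excess risk of the missing group, not a causal effect
  of missingness.
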
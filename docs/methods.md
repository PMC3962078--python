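# Methods

## Scope and model

The package builds linear models ŷ = **X**b + b₀ for a continuous
property of *n* compounds described by *m* molecular descriptors, in the
regime typical of QSPR/QSAR work: *m* comparable to or much larger than
*n*, strong collinearity, and no mechanistic knowledge of which
descriptors matter. Estimation is PLS1; evaluation is repeated double
cross-validation; variable selection is a separate, explicitly suboptimal
step whose products are judged only by held-out prediction error.

## PLS1 algorithm

PLS is less strictly defined than OLS — several algorithmic variants
exist that differ in deflation and normalization. This package implements
the NIPALS variant with X-deflation and y-deflation: for each component,
the weight vector w ∝ Xᵀy maximizes the empirical covariance yᵀt/(n−1) of
the scores t = Xw with the property, X and y are deflated by the fitted
component, and the procedure repeats. Consequences relied on elsewhere:

- score vectors are mutually orthogonal;
- for full-rank X with m < n, the m-component model equals the OLS fit
  (used as an algorithm-independent oracle in the tests);
- training RSS is non-increasing in the component count.

Coefficients for every component count a = 1..A_max are folded back to
the original variable scale (b = W(PᵀW)⁻¹q, rescaled), so a fitted model
is just a table of (b(a), b₀(a)) vectors.

Variables are always mean-centred. Autoscaling (unit variance) is an
explicit flag: it changes the covariance criterion's weighting and is
required when standardized coefficients must be compared across
descriptors (the coefficient-ranking selector). Standardized coefficients
are defined as b_j·sd(x_j) — the coefficients that multiply unit-variance
variables; y is left on its original scale, which rescales all of them by
one common factor and leaves rankings unchanged.

Component extraction stops early when the weight- or score-vector norm
falls below 1e-12 of the initial X norm (degenerate residual matrix); the
model records the number of components actually extracted. A_max is
always capped at min(n−1, m).

## Error measures

All measures derive from residuals e = y − ŷ. SEP is the *bias-corrected*
sample standard deviation of test-set residuals (divisor z−1, mean
subtracted); the bias is reported alongside so that total-error measures
remain recoverable via MSE = bias² + SEP²·(z−1)/z. The same statistic on
calibration residuals is labelled SEC and is always optimistic. R² is the
squared Pearson correlation of y and ŷ, reported as NaN (with a warning)
when either vector is constant. For model-size comparisons during
selection, BIC = n·ln(RSS/n) + m·ln(n) and AIC = n·ln(RSS/n) + 2m with
natural logarithms; m counts selected variables, not the intercept — the
constant offset is irrelevant within one data set, and the absolute
values are meaningless across data sets.

## rdCV conventions

- Segments: random permutation splits into s near-equal parts (sizes
  differ by at most 1). Defaults s_outer = 4, s_inner = 5, r = 50
  repetitions, A_max = 10 — all configurable, since sensible values vary
  with n.
- One-standard-error rule (default for A_OPT): with a* the minimizer of
  the CV-MSE curve, pick the smallest a whose mean MSE is within one
  standard error of MSE(a*); the standard error is the standard deviation
  of segment-wise MSE values at a*, divided by √s_inner. The global
  minimum is available as an alternative rule.
- Per repetition, SEP pools all n test-set residuals of that double-CV
  pass. A_FINAL is the most frequent A_OPT over all r·s_outer estimates,
  ties broken toward the smaller value (parsimony).
- Reproducibility: one master seed spawns one independent RNG stream per
  repetition (`numpy.random.SeedSequence`), so results are bit-identical
  for a given seed and independent of execution order.
- Leakage auditing: the engine accepts a recorder callback that receives
  every (calibration, test) index pair, so tests can verify that no
  object is ever predicted by a model whose training data contained it.
- A_max is reduced (with a warning) when a training fold is too small to
  support it; folds with fewer than 3 objects are an error.

## Variable selection

All operators return positional boolean masks and never reorder columns.

- **Almost-constant filter**: after rounding to 6 decimals (default), a
  variable is dropped if its most frequent value occurs in ≥ n−k objects
  (default k = 3). This is the only cleaning step.
- **Correlation with y**: keep the m_sel variables with the largest
  squared Pearson correlation with y, or drop those below a threshold.
  Zero-variance columns score 0 with a warning.
- **Pairwise correlation elimination**: the m×m squared-correlation
  matrix is computed once; offending pairs (R² above the limit) are
  processed in descending R² order, skipping pairs with an
  already-deleted member; the deleted member is the one with the larger
  sum of squared correlations to all other variables, with sums fixed
  from the full matrix and ties going to the larger column index. The
  fixed-sum variant makes the procedure deterministic and order-stable,
  and gives limit-monotone survivor sets.
- **PLS-coefficient ranking**: rdCV on autoscaled data fixes A_FINAL, one
  model on all n objects is fitted with that many components, and the
  m_sel variables with the largest |standardized coefficient| are kept.
- **Stepwise BIC**: greedy search from the empty model (the full model is
  infeasible when m > n), adding — and in "both" mode also removing — one
  variable per step, accepting the move with the lowest BIC while BIC
  improves. Additions are scored incrementally against an orthonormal
  basis of the current design (one O(n·m) pass per step for all
  candidates); removals refit by least squares, which is cheap because
  selected sets stay small. Near-collinear candidates (residual norm
  below 1e-10 of the column scale) are skipped with a trace note. A
  perfect fit (RSS below 1e-12 of TSS, where BIC is undefined) is
  accepted as the final move and the search stops. Step and time budgets
  are normal stop conditions recorded in the trace, not errors; model
  size is capped at n−2 by default.

Selection-time statistics (BIC, univariate R²) are calibration-set
quantities and are never reported as model performance.

## Synthetic data

The generator emulates the statistical structure of descriptor matrices,
not their chemistry: blocks of collinear descriptors built from shared
latent factors (x = √ρ·f + √(1−ρ)·u gives pairwise correlation ρ in
expectation), independent near-noise columns, and
y = offset + Σβ_j x_j + ε with ε ~ N(0, σ²). The true support and
coefficients are returned for recovery tests. All randomness flows from
one seed through named substreams, so X is bit-identical across runs
differing only in σ. What it does *not* emulate: skewed or integer-valued
descriptor distributions, heteroscedastic measurement error, and
structure–property nonlinearity — so passing tests demonstrate correct
algorithmic behaviour, not chemical validity on real data.

### Problem sizes in the tests

The noise-floor study uses n = 100 objects with 5 informative descriptors
(β = 2, within-block ρ = 0.5) and 95 uninformative descriptors arranged
in five collinear blocks (ρ = 0.99), σ = 1. The block structure is
essential, not cosmetic: with 95 *mutually independent* unit-variance
noise descriptors at n = 100, no PLS variant reaches the σ floor — the
best cross-validated SEP is ≈ 1.8–1.9 (verified also with an independent
PLS implementation), because estimating weights for ~95 free noise
dimensions from ~75 calibration objects adds irreducible estimation
error. Collinear noise blocks keep the effective dimension low, which is
exactly the structure real descriptor matrices have, and there rdCV's
median SEP lands at ≈ 1.0–1.2. The perfect-signal (σ = 0) check uses
m = 20 < n_cal with A_max = m, the regime where the OLS limit makes exact
recovery possible; with m > n_cal the linear system is underdetermined
and no estimator can drive test error to zero. The selection-comparison
study uses n = 80, m = 40 with a 3-variable planted signal — small enough
to run in seconds, large enough that stepwise selection reliably recovers
the support.

## Diagnostics

SEP distributions are summarized as boxplot statistics: quartiles by
linear interpolation (the common "type 7" convention — the underlying
description does not pin one down), whiskers at the most extreme observed
values within 1.5·IQR of the quartiles, points beyond them listed as
outliers. A_OPT histograms report counts per component number and the
modal value with the same small-A tie-break used for A_FINAL.
Predicted-vs-observed tables carry one row per object with every
repetition's prediction and their mean; averaging across repetitions
reduces split-to-split variance. Plot rendering is a thin optional layer;
everything tested is numeric.

## Data formats

Dragon 6.0 exports are read from their three-file form (values, names,
objects); the values file is parsed as whitespace/tab-delimited with no
header, and any token that fails numeric parsing ("NA", "na", "-", …)
becomes a missing value (NaN). The exact Dragon dialect is not formally
specified, so parsing is tolerant but dimension checks are strict, and
every import error names the offending file. Model-fitting operations
reject tables containing missing values — no imputation policy is
assumed. The canonical on-disk format is a CSV with objects as rows
(first column the object name, optional `y` column); masks serialize to
JSON with their provenance string. Duplicate variable names are
disambiguated with numeric suffixes (masks are positional; names matter
only for reporting).

## Known limitations

- Single-response PLS1 only; no PLS2, PCR, or kernel variants.
- No applicability-domain estimation: SEP describes compounds similar to
  the training distribution.
- No significance testing between SEP distributions; the package reports
  distributions and leaves testing to the user.
- Coefficient-level agreement with other PLS software is not guaranteed
  (variant differences); contract-level equivalences (OLS limit, score
  orthogonality) are what the tests pin down.
- Stepwise BIC is greedy and suboptimal by construction; exhaustive
  subset search is infeasible beyond a few tens of variables.
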
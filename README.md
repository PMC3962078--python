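# rdcvpls

Multivariate linear QSPR/QSAR modelling with PLS regression, rigorously
evaluated by **repeated double cross-validation (rdCV)**, plus the basic
variable-selection operators used with molecular-descriptor matrices.

## Who this is for

Chemoinformaticians and chemometricians who model a continuous property
*y* (a GC retention index, a solubility, an activity) from a descriptor
matrix **X** (*n* compounds × *m* descriptors, typically *m* ≫ *n* and
heavily collinear), and who want honest, distributional estimates of
prediction error instead of a single optimistic number.

## The model and its evaluation

The fitted model is always an ordinary linear equation

    ŷ = b₁x₁ + b₂x₂ + … + b_m x_m + b₀

estimated by **PLS1** (NIPALS with X-deflation): latent components
*t* = **X** *p* are extracted to maximize the covariance between the
scores and *y*, and the number of components *A* controls model
complexity. Performance is measured by **SEP**, the standard deviation of
test-set residuals (in *y* units); ±2·SEP is an approximate 95% tolerance
interval for future predictions.

**rdCV** separates complexity optimization from performance estimation:

- an *inner* CV loop (default 5 segments) estimates the optimal component
  count A_OPT per calibration set — by the global MSE minimum or the
  one-standard-error rule;
- an *outer* CV loop (default 4 segments) provides test-set predictions
  for every object from models that never saw them;
- the whole double CV is repeated *r* times (default 50) with fresh random
  splits, yielding *r* SEP estimates (a boxplot, not a point) and
  *r*·s_outer estimates of A_OPT, whose mode becomes A_FINAL;
- the final model uses all *n* objects with A_FINAL components, with no
  further tuning; its calibration-set SEC is only a plausibility check.

Variable-selection operators (almost-constant filter, correlation-with-*y*
screens, pairwise-correlation elimination, PLS-coefficient ranking,
stepwise BIC search) each return a boolean mask over the *m* variables.
Selection uses all *n* objects; the resulting subsets are then *judged*
by rdCV on held-out objects only.

## Worked example

A synthetic descriptor table with collinear blocks and a sparse true
signal stands in for a real Dragon export (for real data, start with
`rdcvpls import --values … --names … --objects …`):

```
$ rdcvpls simulate --fixture blocks --out demo.csv
fixture 'blocks': 60 x 18 -> demo.csv

$ rdcvpls select --table demo.csv --method stepwise --mode both --out sel.json
stepwise: kept 3/18 variables -> sel.json

$ rdcvpls rdcv --table demo.csv --mask sel.json --r 20 --s-outer 4 \
      --s-inner 5 --a-max 8 --seed 1 --out report.json
all_variables: median SEP 0.5553, A_FINAL 3
sel: median SEP 0.4423, A_FINAL 2

$ rdcvpls finalize --table demo.csv --mask sel.json --a-final 2 \
      --sep 0.4423 --out model.json
final model (A=2): SEC 0.4107 -> model.json
```

Reading the numbers: the stepwise subset (3 of 18 descriptors) predicts
held-out compounds with a median SEP of 0.44 *y*-units versus 0.56 for
the full variable set — variable selection reduced both model size and
prediction error. The fixture's *y*-noise is σ = 0.5, so the subset model
sits essentially at the noise floor. The final model's SEC (0.41) is
smaller than the rdCV SEP, as training-set statistics always are; the SEP
is the number to quote for future use, with predictions expected within
about ±0.9 (±2·SEP) of the truth 95% of the time.

The same workflow is available as library calls (`rdcv`, `stepwise_bic`,
`final_model`, …); see `docs/methods.md` for the underlying procedures
and conventions.

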
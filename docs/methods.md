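# Methods

`viperpanel` analyzes subject-by-analyte plasma concentration panels in
which every measurement is constrained to an analyte-specific detection
window, and derives a small survival-risk score from the panel.  This note
records the statistical models, the synthetic cohort the test suite
validates against, and the numerical and design choices a maintainer would
want to know about.

## Detection limits and value rules

A multiplex electrochemiluminescence panel reports, per analyte, a lower
and upper limit of detection (LOD) and optionally the lowest
standard-curve point.  Cells are classified `below` / `within` / `above` /
`missing`; missing (empty) cells are never imputed and never conflated
with below-LOD cells.  Three value rules serve three uses:

* **analysis** — above-LOD cells are set to `upper_lod * 1.1` on the
  concentration scale (before log transform); below-LOD cells are kept as
  *left-censored observations* at `log(lower_lod)` for regression.
* **display** — below-LOD cells become 0 before the within-marker 0–100
  normalization, so heavily censored analytes pin at the bottom of a
  heatmap.
* **ratio** — below-LOD cells are replaced by
  `min(curve_min, lowest detected value of that analyte)`, so ratios are
  computable for every subject while never exceeding any detected value.

All concentrations are natural-log transformed; a regression coefficient
`b` on that scale reports as a percent concentration change
`(e^b − 1)·100`.

## Left-censored (Tobit) regression

For log concentration `y* = x'β + σε`, `ε ~ N(0,1)`, observed only when
`y* ≥ c` with `c = log(lower_lod)`, the likelihood is

```
L(β, σ) = ∏_obs φ((y − x'β)/σ)/σ · ∏_cens Φ((c − x'β)/σ)
```

maximized over `(β, log σ)` by BFGS with the analytic gradient, started
from OLS on threshold-substituted values (gradient tolerance 1e-8; the
optimizer is never allowed to end below its starting likelihood).  The
coefficient covariance is the inverse observed information, obtained by
central differences of the analytic gradient; CIs are Wald.  With zero
censoring the estimates equal OLS (with the maximum-likelihood σ̂² =
RSS/n) to machine precision, and on left-censored data the fit matches R's
`survival::survreg(dist="gaussian")` to ~1e-4 relative (tested).  Fits
with all observations censored are rejected as non-identifiable;
rank-deficient designs are rejected.  Above-LOD cells are treated as
observed at `upper_lod * 1.1` by the standard preprocessing, but the
fitter also accepts right-censoring flags (the likelihood gains
`log Φ((x'β − c)/σ)` terms) for sensitivity analyses where that
substitution is not wanted.

Panel-level models: trauma-vs-control (univariable), age-adjusted
(mean-centered age, controlling for group), sex-adjusted (optionally with
a sex×group interaction), and one-hot categorical models within the trauma
arm with fixed reference levels (trauma level 4, mechanism "other",
location "peripheral", wound "soft_tissue", COVID negative) so coefficient
signs are reproducible.

### Directional false discovery control

For each term, one-sided Wald p-values toward each direction are
Benjamini–Hochberg adjusted *separately within the positive and the
negative family* across analytes, giving `q_pos` and `q_neg`.  A term is
declared significant when `min(q_pos, q_neg) < α/2`; the α/2 split is what
makes the overall directional FDR equal α — each family alone has FDR α/2,
and a true null can only be discovered in one direction at a time, so the
union stays at α.  Under a global null of 59 analytes the empirical FDP is
≈0.010 at α = 0.01 (validated over hundreds of simulated panels; the
Benjamini–Hochberg step-up values are tested against a brute-force
enumeration).  A Storey-type π₀ rescaling (λ = 0.5) is available per
directional family but is deliberately not the default: with 59 tests the
π₀ estimate is too unstable to pay for its power gain.

### Below-LOD prevalence

Whether trauma changes the *probability* of being below LOD is tested per
analyte with Fisher's exact conditional test on the 2×2 (below vs
detected) × (trauma vs control) table, BH-adjusted across analytes; the
test p-values are verified against direct hypergeometric enumeration.

## Ratio screening

Per-subject concentration ratios use ratio-mode values.  The all-pairs
screen compares deceased vs discharged-home subjects (all other discharge
dispositions are excluded from every outcome contrast): for each ordered
pair the group summary of per-subject log ratios is the *median on the log
scale* — identical to the median ratio for odd group sizes, and exactly
antisymmetric in floating point, so `log fold(a:b) = −log fold(b:a)` holds
bit-for-bit (a geometric-mean summary is available).  The fold-change
matrix is the elementwise exp of the difference of group summaries.  A
two-analyte ratio is evaluated as a continuous ROC score with the
orientation flipped (and recorded) whenever low ratio means high risk.

## Permutation importance

Importance is measured out-of-bag on a bagged ensemble of
feature-subsampled decision trees — i.e. a random forest whose bootstrap
membership is directly inspectable.  Defaults: 200 trees, `max_features=3`
per split, `min_samples_leaf=20`, class-weight balanced; 10 independent
ensemble iterations; 3 permutation repeats per feature per iteration.  For
every tree, each feature's score drop is measured on that tree's own
out-of-bag subjects using the AUC of leaf probabilities, and a feature's
raw importance is the total drop averaged over all trees — so trees that
never split on a feature contribute zero, and the score reflects the trees
that actually rely on the feature rather than the ensemble's ability to
vote around the damage.  Within each iteration raw importances are scaled
so the largest reads exactly 100; features are summarized by the median
relative importance across the 10 iterations and selected above 10.

Why these choices: with 2.5% deaths (or 50 controls against 1000
patients), hard-label accuracy is almost piecewise-constant under
single-feature permutation and plain train-set permutation importance
degenerates to zero for every feature once deep trees memorize the sample;
rank-based out-of-bag scoring degrades smoothly and is the configuration
under which the importance stage is reproducible at 25 events.  200
trees/3 repeats (rather than, say, 500/5) keep a 20-cohort validation
study on one CPU while leaving the medians stable; `max_features=3`
spreads reliance across correlated informative features so mid-strength
markers are not starved of splits.  Analyte features enter as display-mode
values (log concentration, 0 when below LOD — the censoring pattern itself
is informative), z-scored; age is z-scored and sex one-hot where
covariates are included.

## ROC, AUC, and operating points

The empirical ROC is traced over all distinct thresholds; AUC is the
trapezoidal area and equals the normalized Mann–Whitney statistic with
ties counted ½ — both routes are implemented and asserted equal.  AUC CIs
use the DeLong placement-variance estimator, with a stratified percentile
bootstrap (2000 resamples) when a class has fewer than 3 members or the
variance degenerates.  Sensitivity and specificity at an operating point
(Youden by default; a max-sensitivity-then-specificity rule is provided,
ties resolving to the lower threshold) get 95% Wilson score intervals; for
9 events with perfect sensitivity the Wilson lower bound is
`n/(n+z²) = 9/12.84 = 0.7009`, the interval form consistent with published
sensitivity bounds of this kind.

## The VIPER score

The five-analyte survival score is derived by a four-stage funnel on the
deceased-vs-discharged-home contrast: (1) analytes appearing in the 30
largest-|log fold| ordered ratio pairs; (2) analytes with median relative
importance > 10; (3) their intersection; (4) single-analyte ROC pruning —
candidates ranked by AUC (CI width breaking ties) and the top five kept.
The default score is a logistic model linear in the five log
concentrations (ratio-mode substitution for below-LOD cells, used
identically at fit and scoring time), fit by maximum likelihood with a
ridge-stabilized fallback on separation.  A `custom_expression` slot
evaluates a user-supplied algebraic formula over concentrations instead of
fitting, for transcribing an externally published equation without
re-deriving it.  Evaluation is by ROC overall and within trauma levels 1
and 4; the default protocol is stratified 5-fold cross-validation
(pooled out-of-fold scores), which preserves the rare deceased class in
every fold; resubstitution is available and is, on average, optimistic by
construction.

## Synthetic cohort

The generator draws log-normal concentrations per analyte with additive
log-shifts for trauma, death, age (per mean-centered year), sex, and a
sex×trauma interaction, plus an optional shared latent factor (off by
default; the generator otherwise has no inter-analyte correlation, a
deliberate simplification).  Censoring statuses are derived from the LODs
*after* all shifts, so below-LOD prevalence differs by group.  Mortality
uses the marginal construction: deceased status is Bernoulli(2.5%) and the
deceased shift is added afterwards.  Because equal-variance Gaussian class
conditionals imply a logistic posterior, this *is* a logistic outcome
model with true weights `δ/σ²` (recorded in the truth table) while keeping
exact control of each analyte's marginal deceased-vs-survivor shift; an
explicit logistic mode (weights supplied, intercept solved numerically for
the target death rate) exists for studying the weights themselves, with
the caveat that strong joint weights saturate the tilt and attenuate
marginal shifts.

The default 59-analyte configuration emulates the structure of a large
trauma cohort: 1000 trauma patients, 50 healthy controls; 9 trauma-up and
23 trauma-down analytes (named by the cytokines they emulate), the
anchor magnitudes being IL-10 +23.1% (= ln 1.231), IL-2 −97.8%
(= ln 0.022) and MCP-4 −29.1%; heavy censoring (>75% below LOD) for
several analytes and a ~46-point trauma-control below-LOD gap for IL-2;
one sex-interaction analyte (IL-8: lower in healthy women, higher in
female trauma patients) and two age-linked analytes (YKL-40 up, TRAIL
down); 2.5% mortality linked to five analytes — IL-6, VEGF-A and IL-10 up
in the deceased, IL-29 and IL-21 up in survivors — with standardized
deceased shifts of 1.45–1.55 (single-analyte AUC ≈ 0.85), plus M-CSF as a
deliberately weak sixth candidate (AUC ≈ 0.65) that reaches the candidate
stages and is dropped by ROC pruning.  Trauma-up/down shifts other than
the three anchors are set in the 1.4–2.2× (up) and 0.45–0.7× (down) range
so they are detectable against 50 controls; the handful of sub-2% effects
a 1000-patient study can print are unpowerable at this control-arm size
and are not emulated.  Covariate distributions (age gamma with median ~38,
71.8% male, trauma-level and mechanism frequencies, survivor discharge
dispositions, COVID testing rates) follow the cohort structure described
above.  Randomness is split one stream per analyte keyed by position, so
appending analytes never perturbs earlier columns and identical configs
are bitwise reproducible.

What passing tests on this generator do **not** show: robustness to
inter-analyte correlation, plate/batch effects, non-lognormal tails,
informative missingness, or longitudinal structure — none of which the
generator emulates.

## Validation studies and problem sizes

The `validation` module (run by `scripts/acceptance.py` and asserted by
the acceptance tests) uses these problem sizes, chosen to give each
Monte-Carlo quantity a comfortable margin on one CPU: OLS-limit check at
n = 500; censored-effect recovery with 200 replicates of n = 1000 (30%
censoring, effect ln 1.231, σ = 0.5); directional-FDR calibration over 500
all-null panels of 59 analytes at n = 120 each; AUC route-equivalence over
1000 random tied-score instances; panel recovery over 20 independent
default cohorts with 5-fold cross-validated scoring; generator-anchor
recovery (IL-10 percent change, IL-2 below-LOD gap) on a 60,000 + 6,000
cohort so the Monte-Carlo error of each anchor is well under its
magnitude.  The anchor cohort is generated with mortality switched off:
with deaths present, the univariable trauma-vs-control contrast estimates
the survivor/deceased mixture shift (the configured trauma effect plus
2.5% of the deceased shift), not the configured trauma effect that the
anchor is defined by.

## Numerical notes and degenerate inputs

* `φ/Φ` ratios in the censored likelihood use `log_ndtr` to avoid
  underflow deep in the left tail.
* Constant vectors normalize to all zeros (with a warning) in the 0–100
  display map; an importance iteration with no positive raw importance
  scales to zeros with a warning rather than dividing by zero.
* Wilson bounds at 0/n and n/n are snapped to their analytic endpoints.
* Percent-change CIs use the exact normal quantile (1.959964), not 1.96.
* Subjects missing any score analyte are skipped (and logged), never
  imputed, when scoring.

## Known limitations

Wald CIs (not profile likelihood) are used throughout, matching standard
censored-regression reporting but slightly undercovering at very small n
or extreme censoring.  The directional-FDR procedure assumes roughly
independent tests across analytes; the generator's default independence
makes its calibration check a best case.  The candidate funnel is tuned
for ~59 analytes and tens of events; with far fewer events the
importance stage loses stability before the ratio stage does.  The
published algebraic equation for the score is supported only through the
`custom_expression` transcription slot — its exact coefficients are not
reproduced here, and the fitted logistic form is this package's default.
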
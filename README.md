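# viperpanel

Statistical pipeline for multiplex plasma-protein panels with assay
detection limits, built around a trauma-survival use case: given
concentrations of ~59 cytokines/chemokines in ~1000 trauma patients and
~50 healthy controls — many values censored below the assay's limit of
detection (LOD) — quantify how injury shifts each analyte, find
analytes and analyte *ratios* that separate patients who die from those
discharged home, and condense them into a five-analyte survival score
(VIPER, "Vital Injury Protein Evaluation for Recovery").

It is written for biostatisticians and immunologists working with
MSD-style multiplex panels who need censoring handled correctly rather
than by substitution, and ships a synthetic cohort generator with a full
truth table so every estimator can be validated end to end without any
patient data.

## The statistics

**Left-censored (Tobit) regression.** Log concentration is modeled as
`y* = x'β + σε`, observed only above the detection threshold
`c = log(lower LOD)`; the censored-Gaussian likelihood

&nbsp;&nbsp;`Σ_obs [log φ((y−x'β)/σ) − log σ] + Σ_cens log Φ((c−x'β)/σ)`

is maximized over `(β, log σ)`; coefficients are reported as percent
concentration change `(e^β − 1)·100` with Wald 95% CIs. Significance uses
*directional q-values*: one-sided p-values toward each direction,
Benjamini–Hochberg adjusted separately per direction, controlling the
directional FDR at 0.01. A companion exact (Fisher) test compares the
*probability* of being below the LOD between groups.

**Screening and scoring.** All `k(k−1)` ordered analyte-ratio pairs are
ranked by deceased-vs-discharged fold change of the median ratio;
out-of-bag random-forest permutation importance (rescaled 0–100 within
each of 10 iterations, median > 10 to select) ranks single analytes; the
intersection is pruned by single-analyte ROC to a five-analyte panel, on
which a logistic-linear score is fit and evaluated by stratified
cross-validated ROC (AUC = Mann–Whitney probability, DeLong CIs, Wilson
intervals on sensitivity/specificity). Full details and every numerical
choice are in [docs/methods.md](docs/methods.md).

## Worked example

```python
import viperpanel as vp

# simulate a study-like cohort: 59 analytes, 1000 trauma + 50 controls
config = vp.default_paperlike_config(seed=1)
panel, subjects, truth = vp.generate(config)

# censored regression per analyte, trauma vs control, directional FDR 0.01
processed = vp.apply_lod_rules(panel, mode="analysis")
fits = vp.fit_panel(processed, subjects, model="univariable_group")
vp.directional_fdr(fits, alpha=0.01)
il10 = next(f for f in fits if f.analyte == "IL-10")
pct, lo, hi = vp.percent_change(il10.beta[1], il10.se[1])

# below-LOD prevalence, panel derivation, score evaluation
prev = {p.analyte: p for p in vp.lod_prevalence_compare(panel, subjects)}
derivation = vp.derive_panel(panel, subjects, seed=1)
model = vp.fit_viper(panel, subjects, derivation.final_panel, seed=1)
rocs = vp.evaluate_by_level(model, panel, subjects, seed=1)
```

Printing the pieces above gives:

```
significant at FDR 0.01: 4 up, 22 down
IL-10 trauma effect: +74.5% (95% CI 23.8 to 146.2)
IL-2 below LOD: trauma 99.9% vs control 56.0% (q = 5.6e-29)
derived panel: ['IL-10', 'IL-29', 'IL-6', 'VEGF-A', 'IL-21']
VIPER AUC, stratum all: 0.988 (95% CI 0.970-1.000)
VIPER AUC, stratum 1: 0.990 (95% CI 0.971-1.000)
VIPER AUC, stratum 4: 0.998 (95% CI 0.994-1.000)
```

Reading this: of the 32 analytes the generator truly shifts, the
regression recovers those detectable against 50 controls (4 up-regulated
and 22 down-regulated at directional FDR 0.01 in this cohort — small
effects are unpowerable at that control-arm size, by design). The IL-10
point estimate (+74.5%) is one draw around its true +23.1% shift, with
the CI reflecting the 50-control bottleneck; IL-2's near-total censoring
in trauma against 56% in controls reproduces the configured ~46-point
prevalence gap. The derivation funnel returns exactly the five embedded
outcome-linked analytes, and the cross-validated score separates deceased
from home-discharged patients with AUC ≈ 0.99 overall and within trauma
levels 1 and 4.

The same pipeline runs from the shell on CSV inputs
(`viperpanel simulate`, `preprocess`, `tobit`, `screen`, `importance`,
`derive`, `score`, `evaluate`, `run-all`); `viperpanel run-all --seed 1
--outdir out/` writes tidy CSVs, JSON summaries, and a run log.

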
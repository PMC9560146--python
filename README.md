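# dscfrac

Volume-based analysis of dynamic susceptibility contrast (DSC) perfusion
MRI for treated glioblastomas, built around the fractional
hypervascularization statistic **%rCBV>x** and its use in separating
**pseudoprogression** (treatment-related enhancing-lesion growth that
later regresses) from **true tumour progression** on the early
post-chemoradiotherapy follow-up MRI.

It is a library for neuroimaging researchers who want a tested, fully
scriptable version of this pipeline: from the raw 4D DSC signal series
to leakage-corrected cerebral blood volume (CBV) maps, per-patient
metrics, and the cohort-level discrimination statistics — plus digital
phantoms with exact ground truth to validate every step.

## The method

For each voxel the signal drop during bolus passage is converted to the
transverse relaxation rate change, ΔR2\*(t) = −ln(S(t)/S₀)/TE, and CBV
(arbitrary units) is the trapezoidal time-integral of ΔR2\*. Contrast
extravasation in enhancing tumour is removed with the unidirectional
(Boxerman-type) leakage model, fit per voxel against the whole-brain
reference curve ΔR̄2\* by ordinary least squares:

    ΔR2*_voxel(t) ≈ K1·ΔR̄2*(t) − K2·∫₀ᵗ ΔR̄2*(τ) dτ

with the corrected curve adding back K2 times the running reference
integral. Normalization divides by the mean CBV of three contralateral
white-matter ROIs, giving rCBV. Two lesion summaries are computed:

* **rCBVmax, hot-spot method** — best mean over small (50 mm²) circular
  ROIs inside the enhancing lesion, found by exhaustive search rather
  than visual placement;
* **rCBVmax, volume method** — voxelwise maximum over the whole
  segmented lesion;

and the fractional statistic

    %rCBV>x = 100 · #{lesion voxels with rCBV > x} / #{lesion voxels}

at thresholds x ∈ {1.5, 1.75, 2, 2.25, 2.5, 2.75, 3}, with the necrotic
core included by default and an exclusion variant alongside. Cohort
analysis treats pseudoprogression as the positive class with *lower*
%rCBV>2 indicating positivity, and reports Mann-Whitney comparisons,
empirical ROC curves with stratified-bootstrap AUC confidence intervals,
the Youden-optimal cutoff, logistic models with Hosmer-Lemeshow
calibration, and agreement statistics (Bland-Altman, Spearman,
consistency ICC, Cohen's kappa).

## Worked example

`examples/03_pseudoprogression_discrimination.py` runs the cohort
analysis on the packaged per-patient fixture (11 pseudoprogression vs 14
progression %rCBV>2 values on the early follow-up MRI):

```
variant A (necrosis included):
  PsP %rCBV>2 median [IQR]: 22.1 [9.9-37.4]  (n=11)
  TP  %rCBV>2 median [IQR]: 51.8 [39.6-64.6]  (n=14)
  Mann-Whitney p:           0.00062
  AUC [95% CI]:             0.909 [0.779-0.994]
  Youden cutoff:            %rCBV>2 < 41.5% -> PsP (sens 100%, spec 71%)
```

Reading: pseudoprogressing lesions have less than half the
hypervascularized fraction of progressing ones; calling pseudoprogression
whenever %rCBV>2 falls below 41.5% catches all 11 pseudoprogression
cases while misclassifying 4 of the 14 progressions. The other examples
cover phantom generation and leakage correction (`01`), per-patient
metric extraction (`02`), and inter-observer agreement (`04`). A thin
CLI (`dscfrac simulate|cbv|metrics|cohort`) wraps the same functions for
shell use.

## Layout

* `src/dscfrac/synthetic.py` — phantoms with exact ground truth; canonical fixtures
* `src/dscfrac/cbv.py` — ΔR2\*, leakage correction, CBV maps
* `src/dscfrac/metrics.py` — hot-spot / volume rCBVmax, %rCBV>x, mask tools
* `src/dscfrac/stats.py` — outcome labelling, ROC/Youden, tests, agreement
* `src/dscfrac/pipeline.py`, `cli.py` — orchestration and command line
* `docs/methods.md` — modelling assumptions, parameter choices, limitations
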
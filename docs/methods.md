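# Methods notes

This note records the models behind `dscfrac`, the defaults and why they
were chosen, the numerical conventions, and what the phantom-based tests
do and do not establish about real patient data.

## Signal model and ΔR2* conversion

A DSC series is gradient-echo EPI signal S(x,t) acquired during the
first pass of a gadolinium bolus. The package assumes the standard
mono-exponential T2\* relationship S(t) = S₀·exp(−TE·ΔR2\*(t)) and
inverts it voxelwise with S₀ estimated as the mean over the baseline
window. Default acquisition parameters are a 3T protocol: TE 20 ms,
TR 1.71 s, 45 dynamic frames (~90 s), 2×2×4 mm voxels. Voxels with
non-positive signal anywhere in the time course are flagged invalid and
excluded from maps rather than imputed; signal overshoot above baseline
(the T1 leakage signature) produces negative ΔR2\* and is deliberately
not clipped, since the leakage fit needs it.

Bolus arrival is detected on the brain-mean curve: with frames 0–7 as a
provisional baseline, arrival is the first frame below (mean − 5·SD),
and the baseline window ends 3 frames earlier as a safety margin. A
series whose brain-mean never crosses the threshold — including one
whose bolus arrives inside the provisional baseline, which corrupts the
threshold itself — is rejected rather than silently processed.

## Leakage correction

The unidirectional two-parameter model regresses each voxel curve on the
whole-brain reference curve and its running time-integral over the
post-baseline frames (ordinary least squares, closed-form 2×2 normal
equations). K1 scales the intravascular component; K2 (1/s) is the
leakage rate. The corrected curve is the measured curve plus K2 times
the running reference integral; corrected CBV is its trapezoidal
integral from bolus arrival to the last frame. No recirculation cut or
gamma-variate refit is applied — the simplest defensible window — and
both the baseline and integration windows are arguments for anyone who
wants alternatives. Negative fitted K1 is physically meaningless and is
reported (flagged via `LeakageFit.physical`), never clamped.

A noise floor worth knowing about: at baseline SNR 50 the per-frame
ΔR2\* noise is σ/(TE·S) ≈ 1.0–1.6 s⁻¹, and with a realistic reference
bolus (peak ΔR2\* ≈ 10 s⁻¹) the Fisher information of a single 45-frame
voxel curve bounds the per-voxel relative error of any corrected-CBV
estimator at roughly 2.5–3% (median). Per-voxel CBV at this SNR is
intrinsically noisy at the few-percent level; the fractional statistic
is robust to it because thresholding at 2 only misclassifies voxels
whose true ratio sits within the noise band of the threshold.

## Perfusion metrics

* **White-matter reference**: mean of the per-ROI means of three 50 mm²
  discs placed contralaterally at the lesion's superior/middle/inferior
  slices. The same reference normalizes both rCBVmax methods so that
  differences between them reflect ROI selection only.
* **Hot-spot rCBVmax**: the operator's visual hot-spot search is
  replaced by exhaustive maximization — every lesion voxel whose 50 mm²
  disc (the midpoint of the conventional 40–60 mm² range; membership by
  pixel-centre-in-disc) lies fully inside the enhancing lesion is a
  candidate; up to 4 non-overlapping discs are kept. This is
  deterministic and upper-bounds what a reader could find, removing
  inter-observer variability by construction. Hot-spot candidates
  exclude necrosis, since hot-spots are read off enhancing tissue.
* **Volume rCBVmax**: voxelwise maximum over the full segmented volume.
  It always dominates the hot-spot value (a disc mean ≤ the maximum).
* **%rCBV>x**: strict inequality at the threshold (boundary voxels do
  not count), necrosis included in the denominator by default; the
  necrosis-excluded variant is computed alongside. Fractions are
  invariant to any common rescaling of map and reference.
* **Mask transfer**: rigid co-registration of real scanners is out of
  scope; masks move between grids by nearest-neighbour resampling
  through the affine composition, which is exact when grids match.

## Phantoms

A phantom is an ellipsoidal brain of reference tissue (true normalized
CBV 1) with a spherical lesion whose voxels split into a hypervascular
fraction f drawn from (2.25, 4.5) and a low-perfusion remainder from
(0.25, 1.75), around a near-avascular necrotic core (ratio 0.05, 15% of
the lesion volume by default). The two ranges deliberately leave a band
around the threshold 2 — they model distinctly hyper- versus
hypo-perfused tissue compartments, not a continuum. f is defined over
*all* lesion voxels, necrosis included, to match the primary
necrosis-included analysis; noise-free and leak-free, measured %rCBV>2
equals 100·f exactly, which is the construction-equals-measurement
anchor of the test suite.

Each voxel's ΔR2\* is its true ratio times a gamma-variate bolus
(arrival 10·TR, shape α=3, scale β=1.5 s, amplitude 2.2 → reference peak
ΔR2\* ≈ 9.7 s⁻¹, a realistic white-matter-level response), minus, in
enhancing voxels, K2 times the running bolus integral (default K2 =
0.02 s⁻¹). Noise is additive Gaussian on the signal at SD 2% of baseline
(SNR 50). Everything is deterministic given the seed.

Cohort generation draws f per case from truncated normals on
[0.02, 0.95] — pseudoprogression-like mean 0.22 (SD 0.14),
progression-like mean 0.52 (SD 0.17), calibrated to the packaged group
summaries of %rCBV>2; this is a calibration, not a claim about the true
distribution of fractions. Because necrotic voxels cannot be
hypervascular, a draw can exceed the enhancing rim's capacity
(f ≳ 0.85 with default geometry, <~3% of progression-like draws); such
draws are rejected and redrawn, i.e. f is conditioned on geometric
feasibility.

What the phantoms do **not** emulate: realistic anatomy, arterial input
function dispersion and delay, recirculation, motion, susceptibility
artefacts, partial-volume mixing, or spatially correlated noise. Passing
recovery tests therefore demonstrates correctness of the numerics and
estimators under the stated model, not clinical performance.

## Canonical cohort fixtures

Patient-level data are not redistributable, so the cohort statistics run
on packaged synthetic per-patient %rCBV>2 values (11 pseudoprogression,
14 progression) constructed by constraint satisfaction to match the
published group summaries: medians and Moore-McCabe quartiles
(22.1 [9.9–37.4] vs 51.8 [39.6–64.6]), zero cross-group ties, exactly
14 of 154 discordant pairs (AUC 140/154 = 0.909), all pseudoprogression
values below 41.5 and exactly 4 progression values below it (sensitivity
100%, specificity 10/14 → 71%); the necrosis-excluded variant has 18
discordant pairs (AUC 0.883). Every constraint is re-verified by brute
force in the test suite. The published brackets are treated as
interquartile ranges — they cannot be full ranges, since the reported
AUC (< 1) and specificity (71%) require the groups to overlap.

## Statistical conventions

* Quartiles: Moore-McCabe (median-exclusive halves); this convention
  reproduces the fixture brackets and is stated wherever IQRs appear.
* ROC: pseudoprogression is positive; lower %rCBV>2 is positive.
  Empirical ROC over all distinct cutoffs; trapezoid AUC (equals
  pairwise concordance with half-credit for ties — asserted in tests);
  95% CI by class-stratified bootstrap percentile, B = 2000, seeded.
* Youden cutoff: candidates are midpoints between adjacent distinct
  pooled values plus one extreme on each side; positive call when the
  score is strictly below the cutoff; ties in J break toward higher
  sensitivity, then the lower cutoff. Specificity is reported both as a
  fraction and as integer-rounded percent.
* Mann-Whitney: exact p when min(n,m) ≤ 8 and tie-free, otherwise
  normal approximation with tie and continuity corrections; the
  perfectly symmetric case U = nm/2 reports p = 1.
* Logistic model: IRLS (tolerance 1e-8, ≤ 100 iterations); complete
  separation is detected and reported as non-converged.
  Hosmer-Lemeshow uses deciles of risk with tie-collapsed bins,
  df = bins − 2, and requires ≥ 3 populated bins.
* ICC: two-way ANOVA consistency, single measure — ICC(C,1) =
  (MS_subjects − MS_error)/(MS_subjects + MS_error) for two raters —
  with an F-distribution CI. Cohen's kappa defines the degenerate
  both-raters-constant-and-equal case as 1.
* Outcome labelling: true progression when a new lesion appears outside
  the radiation field, on rapid clinical decline, or when the enhancing
  volume grows ≥ 25% from the first to the second follow-up; otherwise
  pseudoprogression (≥ 50% regression or stabilisation — any non-TP
  change counts, with both bounds exposed as arguments). TP criteria
  take precedence and inclusion requires growth at the first follow-up.

## Problem sizes used in the packaged checks

The recovery suites use 1,000 synthetic voxel curves for the leakage
fits, 20 default-size phantom cases (64×64×16×45 at SNR 50) for
fraction recovery, and the 25-case fixtures for all cohort statistics;
these sizes make the whole suite comfortably reproducible on a single
CPU while keeping Monte-Carlo noise well inside the asserted margins.

## Known limitations

* Absolute quantification (mL/100 g), AIF deconvolution, CBF/MTT are out
  of scope; CBV is in arbitrary units and only ratios are interpreted.
* The leakage model is the linear unidirectional one; bidirectional
  exchange and pre-load protocols are not modelled.
* The exhaustive hot-spot search is an idealized reader; real hot-spot
  values are operator-dependent and typically lower.
* Per-voxel corrected CBV at SNR 50 carries an irreducible few-percent
  noise floor (see above); quantities that average over voxels or
  threshold well away from the noise band are the reliable outputs.
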
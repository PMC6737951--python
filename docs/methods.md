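# Methods

`cardiomap` implements a multiparametric quantitative CMR tissue-
characterization pipeline for the mouse left ventricle — pixelwise T1, T2
and T2\* relaxometry, 12-segment regional analysis, histogram phenotyping,
semiquantitative histopathology scoring and map-to-histology correlation —
validated end to end by parameter recovery on seeded digital phantoms. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic validation does and does not demonstrate.

## Signal models and fitting

**Look-Locker T1.** Magnitude inversion-recovery data are modeled as
S(TI) = |A − B·exp(−TI/T1\*)| and fitted per pixel by three-parameter
nonlinear least squares, followed by the Look-Locker correction
T1 = T1\*·(B/A − 1). Inversion times are restricted to integer multiples of
the R-R interval (~100 ms in the mouse), reflecting R-wave-triggered
acquisition; 20 TIs by default. The absolute-value model is fitted directly
(no polarity restoration); the ambiguity near the null point is absorbed by
the three-parameter fit. Pixels with B ≤ A, failed convergence, or
non-positive corrected T1 are flagged invalid rather than raising.

The forward simulator uses the same model with A = PD,
B = A·(1 + efficiency) and T1\* = T1·A/(B − A), which makes the corrected
estimate return the generating T1 exactly — the property the recovery tests
and the acceptance checks rely on. For perfect inversion (efficiency 1,
B = 2A) this reduces to T1\* = T1. Inversion efficiency defaults to 0.95
and is configurable; whether the original acquisition was magnitude or
phase-restored is unknown, so both the efficiency and the SNR are exposed
as configuration rather than guessed.

**T2 and T2\*.** Multi-echo spin-echo (TE = 2.74, 5.49, 8.23, 10.98,
13.72 ms) and multi-echo UTE (TE = 0.37, 1.5, 2.2, 3.0 ms) magnitude data
are modeled as S(TE) = S0·exp(−TE/T) and fitted per pixel by two-parameter
nonlinear least squares, initialized by a log-linear regression over the
positive samples. If the nonlinear solver fails, the log-linear estimate is
retained with `converged=False`. Constant (non-decaying) pixels are flagged
invalid with no exception.

**Optimizer.** Trust-region reflective least squares (analytic Jacobians,
positivity bounds, parameter/function/gradient tolerances 1e-8, at most 200
iterations per parameter). On noiseless series all three fits recover the
generating parameter to ≤1e-6 relative error at every myocardial pixel —
the oracle-equivalence property test.

**Noise model.** Magnitude MRI noise is Rician: a true signal s is observed
as √((s+σg₁)² + (σg₂)²) with independent standard-normal g₁, g₂. SNR is
defined as the mean myocardial proton density divided by σ, the per-channel
SD of the underlying complex Gaussian — the standard convention for
magnitude images. Noise correctness is asserted distributionally
(Kolmogorov-Smirnov against the Rician CDF at n = 10⁵, α = 0.001) and via
the closed-form noncentral-chi mean bias.

**Rician bias is quantified, not corrected.** The fits deliberately apply
no Rician bias correction. At SNR 30 this matters only for T2: with echoes
reaching just 0.48·T2 at the control value (28.5 ms), the per-pixel
nonlinear estimator is right-skewed and its *mean* across pixels carries a
reproducible +2–3% bias (the median is within ~1%); Monte-Carlo shows the
same bias for log-linear and weighted log-linear alternatives, so it is a
property of uncorrected mono-exponential estimation at this SNR and echo
range, not of the implementation. The tests assert the quantified behavior
(T2 mean within 4% and median within 2% of truth; T1 mean within 2%; T2\*
mean within 3%).

## Phantom generator

The phantom is an ideal annulus (no papillary muscles, no right ventricle):
default endocardial/epicardial radii 1.2/2.2 mm on a 64×64 raster of 164 µm
pixels, chosen so that the 12-segment mid-slice partition yields per-segment
pixel counts inside the 36±5 envelope reported for real mid-slices. Healthy
myocardium defaults to T1 = 1505 ms, T2 = 28.5 ms (the control-group global
values at 9.4 T); the control T2\* is not reported by the source
measurements, so the healthy preset uses 8.0 ms, typical for mouse
myocardium at this field strength. The "treated" preset (1128 / 27 /
3.7 ms) encodes the global values measured in hemorrhagic myocarditis.

Pathology enters through disc or wedge lesions carrying 0–1 severity levels
for edema, infiltration and fibrosis, and a non-negative iron
concentration:

* edema adds +150 ms to T1 and +10 ms to T2 at severity 1; fibrosis adds
  +100 ms to T1 (additive shifts before iron);
* iron acts linearly on rates, 1/T_eff = 1/T_shifted + r·c, with
  r2\* ≥ r2 ≥ r1 so T2\* is the most iron-sensitive index. The default
  relaxivities are anchored so that unit concentration maps the healthy
  preset exactly onto the treated one (r1 = 1/1128 − 1/1505,
  r2 = 1/27 − 1/28.5, r2\* = 1/3.7 − 1/8 per ms per unit);
* RBC extravasation severity is tied to the iron field
  (severity = min(1, 1.5·c)), reflecting that extravasated erythrocytes
  precede and exceed the footprint of hemosiderin deposition.

Pixelwise invariants asserted by tests: 1/T2\*_eff ≥ 1/T2_eff and
T1_eff ≥ T2_eff; all pathology fields zero outside the myocardium;
increasing iron never increases any relaxation time; identical
configuration and seed give bitwise-identical rasters.

The generator emulates co-registered, motion-free, single-slice magnitude
series with spatially uniform noise. It does **not** emulate B1/inversion-
efficiency inhomogeneity, susceptibility artefacts near the lung, flow or
motion artefacts, partial-volume papillary anatomy, or inter-animal
anatomical variability. Passing recovery tests therefore demonstrates the
correctness of the estimation and analysis chain under the stated models,
not robustness to those real-world confounds.

## Segmentation

Epicardial and endocardial contours are polygons (≥64 vertices; on
phantoms, sampled analytically from the true circles as a stand-in for
manual tracing). Transmural depth is defined in polar convention — along
the ray from the contour centroid, 0 at the endocardial and 1 at the
epicardial contour, with contour radii interpolated periodically between
vertices — because "innermost 5%" has no unique operational definition for
arbitrary contours; the convention is oracle-tested per pixel.

The mid/basal wall is divided into six equal angular sectors
(counter-clockwise from the configurable anterior reference angle, named A,
AS, IS, I, IL, AL), four at the apex. Pixels are assigned by pixel-center
angle, ties toward the lower label id. The innermost 5% of the wall is
excluded first (blood-pool guard), then each sector is split at transmural
depth 0.5 into subepicardial (labels 1–6) and subendocardial (labels 7–12)
halves. Applying the rim exclusion before the split follows the reading
that the split halves the analyzed wall; the alternative cut at
(0.05+1)/2 = 0.525 differs by less than one pixel ring in the default
geometry. On the T2 path, pixels exceeding the slice median by more than
z = 5 robust (MAD) SDs are excluded as stagnant-blood brightness.

Per-segment statistics are mean, SD, median and pixel count over valid
pixels, with a Shapiro-Wilk p recorded per segment to document the
normality assumption behind reporting segment means. Empty segments yield
an n = 0 NaN row plus a warning — never a silent drop.

## Histology scoring

The macroscopic rubric maps the lesion-covered fraction of the epicardial
surface to 0–4 (0: none; 1: <10%; 2: 10–30%; 3: 30–50%; 4: >50%); boundary
fractions 0.10/0.30/0.50 fall in the lower-inclusive bins as stated. The
surface fraction is computed raster-only (flood-fill outer background;
boundary pixels carrying iron or RBC count as covered), making it exactly
invariant under 90° image rotation.

Per-segment 0–3 scores (none/mild/moderate/severe) for infiltration,
fibrosis, RBC and iron derive from segment-mean severities via three
cutpoints, default (0.05, 0.35, 0.65) — the verbal rubric fixes only the
labels, so the cutpoints are configuration with documented defaults. Each
of 4 cross-sections is scored; with probability `scorer_noise_p` a
section's score is perturbed ±1 (clipped), emulating inter-observer
variation; sections aggregate by mean, rounded back to the ordinal scale
(the aggregation rule is configuration; mean across sections is the
default). With zero scorer noise the scoring is a deterministic function of
the phantom and cutpoints.

## Statistics

* Regional histograms: 20 equal-width bins over [min, max] of the pooled
  valid pixels of the selected segments (per-region range, since no global
  range is defined); mean, median, skewness; smoothing by Savitzky-Golay,
  window 5 (two bins each side), order 2, which reproduces quadratic bin
  profiles exactly (kernel [−3, 12, 17, 12, −3]/35).
* Mann-Whitney U for ordinal scores: midrank ties; exact p by full
  permutation enumeration over midrank sums when C(n1+n2, n1) ≤ 20 000
  (valid under ties), exact DP null distribution for tie-free problems with
  n1·n2 ≤ 400, tie-corrected continuity-corrected normal approximation
  otherwise. Two-sided p = min(1, 2·min(P(U≤u), P(U≥u))).
* Student t-tests, paired or unpaired (Welch by flag), two-sided by
  default; zero-variance equal-mean comparisons return t = 0, p = 1.
* Pooled Pearson correlation: one (segment mean, segment score) pair per
  segment per animal, pooled across animals and experiments, 12
  sub-segments per animal by default. Within-animal dependence of segments
  is acknowledged and deliberately not corrected, and ordinal scores enter
  as integers — both choices mirror how such pooled correlations are
  reported in practice. No multiple-testing correction is applied.

## Pipeline and reproducibility

`run_pipeline` executes simulate → fit → segment → score → statistics for a
control plus treated synthetic cohort (default 3+3 animals; treated animals
receive two randomized iron/RBC deposits — one surface-reaching — with
co-localized inflammation, plus an iron-free inflammatory wedge). The
single top-level seed fans out as `default_rng([seed, stage, animal])`, so
any stage can be re-run independently and a re-run is byte-identical. A
stage failure aborts with a stage-named error and a FAILED marker next to
the partial outputs. Problem sizes throughout (64×64 rasters, ~384
myocardial pixels per animal, 1000-pixel recovery experiments, 3+3 cohorts)
are the package's chosen desk-scale defaults: large enough that recovery
tolerances are meaningful, small enough to iterate quickly.

## Known limitations

* The annular geometry cannot probe contour-tracing error or atlas
  misregistration; contours are exact by construction.
* Mean-based T2 recovery inherits the documented +2–3% skew bias at SNR 30;
  studies needing unbiased T2 at this SNR should report medians or model
  the Rician likelihood.
* The scorer-noise model is symmetric ±1 and independent across sections;
  real inter-observer error is likely correlated and asymmetric.
* Correlations treat segments as independent observations (by design, for
  comparability); clustered-error or mixed-effects modeling is out of
  scope.
* k-space effects (radial trajectories, gridding, coil sensitivities) are
  not simulated; series are generated directly in image space.
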
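# Methods

This note documents the models, estimators and numerical choices behind
`hemilat`, what the synthetic cohort does and does not emulate, and the
design decisions taken where the methodology leaves room.

## Data model and geometry

All computation happens on masked `time × voxel` matrices tied to a
`HemisphereGeometry`: a voxel grid with a NIfTI affine, an analysis mask
(gray matter, cerebellum excluded, in the intended application), per-voxel
hemisphere labels, and the structural mirror of each voxel (x → −x in
template mm, nearest voxel center). Voxel storage order is row-major over
the (x, y, z) array axes restricted to the mask and is relied on wherever a
deterministic tie-break is needed (seed argmax, cluster peaks, feature
order).

A voxel is MIDLINE exactly when the |x| of its center is below half an
x-voxel width; midline voxels belong to neither hemisphere, are excluded
from the hemisphere totals Hi/Hc, and receive no AI value. On grids with an
even x dimension centered on the midsagittal plane (the synthetic default)
no midline voxels exist. The mirror index is undefined (−1) when the
mirrored point leaves the mask; only the generator and symmetry tests use
it — the metrics themselves never do.

## Temporal denoising

Order is fixed: confound regression → bandpass → scrubbing (regression
before filtering, so regressor and signal spectra still match; scrubbing
last so filtering never sees missing rows).

* **Confounds**: intercept, linear trend, the Friston 24 expansion
  [m, m², m(t−1), m(t−1)²] of the six rigid-body parameters (lagged rows
  zero-padded at t = 0), and WM/CSF mean signals when available.
  Least-squares residuals; a rank-deficient design falls back to the
  pseudoinverse with a logged warning.
* **Bandpass**: 0.01–0.1 Hz, order-4 Butterworth applied
  forward–backward (zero phase). The contract is spectral — passband
  amplitude preserved within 5%, ≥90% attenuation at twice the band
  edges — so any realization meeting the probe-sinusoid test is
  conforming. `low_hz = 0` degrades gracefully to a lowpass.
* **Scrubbing**: Power-style framewise displacement (sum of absolute
  backward differences, rotations converted on a 50 mm sphere), default
  threshold 0.5 mm, rows deleted (not interpolated), `kept_frames`
  updated. The original toolchain's exact scrubbing variant is not
  documented; deletion is the most common period practice and is
  configurable. At least 10 frames must survive.

## Autonomy index

`AI(v) = Ni/Hi − Nc/Hc`, with Ni/Nc the ipsilateral/contralateral counts
of voxels u with `r(v,u) > .25` **and** two-sided correlation-test
`p < .001`, where `t = r·√((T−2)/(1−r²))` with T the subject's
post-scrubbing frame count. Because the t-test is monotone in r, both
conditions collapse into one effective cutoff `max(.25, r_crit(p, T))`;
at typical T (~150) the p-condition is binding (r_crit ≈ .26) and this is
logged. Thresholding is one-sided positive: anticorrelations never count
(configurable in principle; the formulation counts "significant
correlation" above a positive r threshold).

Two choices deserve emphasis:

* **The self-correlation counts in Ni.** Counting runs uniformly over all
  hemisphere voxels, so r(v,v)=1 contributes 1 to Ni. This adds the same
  1/Hi to every voxel of a hemisphere (cancelling in group contrasts) and
  preserves the exact null: on mirror-duplicated data each entry of Ni is
  matched by its mirror in Nc — including the self, matched by the mirror
  voxel at r = 1 — giving AI ≡ 0 identically. Excluding the self would
  leave Nc = Ni + 1 there and a spurious −1/H offset.
* **Hemisphere-role exchange.** Relabeling the hemispheres together with
  their totals is a mathematical no-op (each voxel keeps the same
  companions). The meaningful symmetry is exchanging the
  ipsilateral/contralateral *roles*, exposed as
  `compute_ai_map(swap_hemisphere_roles=True)`, which negates the map
  exactly and is checked as such.

Zero-variance voxels (possible in synthetic data) correlate with nothing,
count nowhere, and get NaN.

## CFH: functionally homotopic connectivity

Seed definition pools **all** participants: per-subject correlation
matrices are Fisher-transformed (r clipped to 1−10⁻⁷ before atanh, logged),
averaged over subjects where both voxels have variance, and inverse
transformed. For each hemispheric voxel the contralateral argmax of this
pooled mean FC becomes its seed — a single voxel, ties broken by smallest
storage index with the tie count recorded, the relation not required to be
symmetric. Raw-r averaging and restricted subject sets (per-group,
leave-one-out) are available as arguments for sensitivity analyses, since
pooling lets group structure leak into seed choice; the pooled default
follows the method being reimplemented, and the selection bias it induces
is identical in both groups, so group contrasts stay centered (verified by
a null-cohort test).

CFH(v) is then the plain Pearson correlation with the seed voxel's series;
seedless or zero-variance voxels get NaN and are excluded from statistics.

## Smoothing

Masked Gaussian smoothing with σ = FWHM/2.3548 per axis in mm: the map
and a 0/1 weight volume are filtered identically and divided, so constants
are preserved, nothing bleeds across the mask edge, and NaN voxels
(midline AI) keep zero weight and stay NaN. Default FWHM 8 mm, applied to
individual AI and CFH maps before group statistics.

## Group inference

Two-sample pooled-variance t (patients − controls), df = n₁+n₂−2; voxels
NaN in any subject or with zero pooled variance are excluded. Cluster
inference replaces the parametric Gaussian-random-field correction with a
label-permutation max-cluster-extent procedure at the same error target
(voxel p < 10⁻⁴ two-sided, cluster α = .05): suprathreshold voxels are
clustered with 26-connectivity (6/18 selectable), separately for positive
and negative excursions; the null of the maximum extent over both signs is
built from full group relabelings (all distinct relabelings enumerated when
fewer than `n_perm` exist, which is logged); and

    p_corrected(cluster) = (1 + #{null max extent ≥ observed extent}) / (n_perm + 1).

This is exact for exchangeable maps without any smoothness estimation; the
price is discreteness (attainable p values are multiples of 1/(n_perm+1)),
which makes the test mildly conservative on barely-smooth maps. Peak
coordinates are voxel-center mm of the max-|t| voxel (first in storage
order on ties).

Sphere extraction (default radius 3.5 mm around cluster peaks) averages
in-mask voxels whose centers fall inside the sphere; classification
features default to full cluster means instead, because a 3.5 mm sphere
degenerates to a single voxel on coarse synthetic grids — the `roi_form`
config switches between the two.

Partial correlation residualizes both variables on [intercept, covariates]
by least squares and tests the residual Pearson r against t with
df = n−2−k. Education is the default covariate for imaging–cognition
correlations (it differs between groups in the emulated setting, and in
the generator by construction). A residual with norm below 10⁻¹⁰ of its
variable (e.g. y exactly equals a covariate) is reported NaN.

## Classification

Features: per-subject means of each significant cluster, AI and CFH
pooled. Each LOOCV fold standardizes with the training fold's mean and
standard deviation only (sd floored at 10⁻¹², so constant features
standardize to zero rather than explode), fits a linear-kernel soft-margin
SVM at fixed C = 1, and records the held-out decision value. Sensitivity
takes the patient group as positive; AUC ranks the pooled LOOCV decision
values. The permutation test shuffles labels and reruns the complete LOOCV
per permutation, `p = (1 + #{null acc ≥ observed})/(n_perm + 1)`.

The SVM is an in-package SMO solver (maximal-violating-pair working-set
selection on the C-SVC dual, ε = 10⁻⁴, intercept from the free-vector KKT
conditions), numba-compiled and operating on precomputed per-fold Gram
matrices — fold kernels depend only on the features, never the labels, so
permutations reuse them and a 200-permutation LOOCV on 40 subjects takes
well under a second. The test suite pins the solver against an independent
reference SVM implementation (decision values within solver tolerance,
identical off-margin predictions).

## Synthetic cohort

Each mirror pair (v, m(v)) shares a latent source s with weight √ρ:
`x_v = √ρ·s + √(1−ρ)·n_v`, all sources unit-variance AR(1) (φ = 0.3)
mixed with 40% white noise, so corr(x_v, x_m) = ρ exactly in population
and the achieved correlations are testable against targets. Controls
couple at ρ = 0.6 everywhere. Patients: ρ drops by Δρ = 0.3 in the CFH
lesion ROI, and the AI ROI receives a shared ipsilateral source at weight
√gain (gain = 0.5) — raising within-hemisphere correlations — while its
mirror coupling is attenuated by 30% (`contralateral_loss`). Both planted
boxes hold 18 left-hemisphere voxels; the CFH ground-truth effect mask is
derived from the group difference of the coupling maps, so it includes the
lesion pairs *and* the attenuated AI-ROI pairs, on both sides.

A per-subject jitter (sd 0.06) on the lesion-ROI coupling provides the
individual differences that cognitive scores track: MoCA-like scores are
`group mean + 20·(z_subject − group mean z) + 0.3·(education − group mean)
+ N(0, 2.5)`, with education group-shifted (10 ± 3 vs 7 ± 3 years) as in
the emulated cohort; AVLT-immediate uses a 0.3× slope. At these settings
the population CFH–MoCA partial correlation in the patient group is
deliberately modest (~0.3), matching the marginal brain–behaviour
correlations such studies report, so its sample value at n = 20 is noisy —
the recovery *property* is tested at small score noise instead.

Weak global WM/CSF signals (weight 0.15 each) leak into every voxel and
are emitted as confound columns; they inflate raw pairwise correlations by
≈0.015 until the regression removes them. Motion is a small-increment
random walk with Bernoulli spike displacements (rate 0.03, 0.7–1.5 mm)
that exceed the scrubbing threshold. Written cohorts prepend 10 synthetic
unsteady volumes so that loading with the standard initial discard
recovers exactly the generated frames.

**Grid resolution.** The default grid is 16×20×16 at **9 mm** voxels
(≈1.9k in-mask voxels in a symmetric ellipsoid mask). At this voxel size
the fixed 8 mm smoothing kernel is sub-voxel, so planted box boundaries
stay sharp and recovered clusters coincide with the truth; at finer
desk-scale resolutions the kernel's one-voxel halo rivals the ROI volume
and recovery Dice degrades for purely geometric reasons. Calibration
simulations of the cluster test instead use 3 mm voxels on the same grid,
reproducing the kernel-to-voxel ratio (σ ≈ 1.1 voxel) of a typical 3 mm
acquisition, where the extent null is rich enough for the permutation
test's discreteness to be negligible.

What the generator does **not** emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) noise, spatial autocorrelation of the
noise field, registration error, scanner drift beyond a linear trend, or
motion-correlated signal artifacts. Passing tests therefore demonstrate
the estimators' correctness and calibration under exchangeable,
temporally-autocorrelated Gaussian data with planted effects — not
robustness to the full physics of real BOLD.

## Problem sizes and seeds

The test suite and acceptance script run at desk scale, chosen so the full
battery completes in minutes on one core: recovery uses 20 replicate
cohorts of 20+20 subjects × 160 frames; FWER calibration uses 200 null
cohorts of 15+15 maps with 500 permutations; classifier calibration uses
100 replicates of 40 subjects with 200 permutations each. All randomness
descends from explicit integer seeds; the pipeline derives per-stage seeds
(simulation, AI/CFH cluster permutations, label permutations) from one
master seed via a seed sequence, and a config hash (analysis parameters,
output path excluded) stamps every table.

## Known limitations

* The pooled seed definition leaks group structure into seed choice; the
  bias cancels in group contrasts but per-group seed sensitivity analyses
  are the user's responsibility (flags provided).
* Permutation cluster inference assumes exchangeability under the null —
  group differences in map *variance* would violate it.
* The AI p-threshold treats frames as independent; temporal
  autocorrelation surviving the bandpass makes the nominal p optimistic.
  Both hemispheres are affected identically, so AI contrasts are not
  biased, but the effective threshold is data-dependent.
* CFH values are upward-biased by the argmax seed selection; absolute CFH
  levels should not be compared across cohorts analyzed with different
  subject pools, only contrasts within one analysis.
* Sphere extraction at 3.5 mm is meaningful only at acquisition-scale
  voxel sizes; on the coarse synthetic grid it reduces to the peak voxel.
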
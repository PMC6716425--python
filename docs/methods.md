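# Methods

`pdstriatum` implements a fully automatic multi-modality pipeline for
Parkinson's-disease (PD) versus normal-control (NL) classification from
paired structural MR and dopamine-transporter (DAT) PET volumes, exercised
end to end on synthetic 3D phantoms. This note records the models, the
study conditions the phantom generator encodes, the numerical choices, and
the limits of what phantom-scale results demonstrate.

## Pipeline

Three stages per subject:

1. **Segmentation.** A deeply supervised residual 3D encoder-decoder
   segments the six striatal anatomical regions (SARs: caudate nucleus,
   putamen, pallidum; bilateral) on the MR volume.
2. **Registration.** A rigid MR→PET registration propagates the MR-space
   labels (plus the parieto-occipital reference region, which comes from the
   prior label map, not the network) onto the PET grid with
   nearest-neighbour resampling. A single-modality comparison arm instead
   aligns a pre-labeled PET template to the subject PET with an affine
   registration following a pre-rigid stage.
3. **Features and prediction.** The caudate and putamen are each divided
   into three substructures by k-means on voxel physical coordinates; six
   intensity statistics (max, min, median, Q1, Q3, mean) per region are
   normalized to striatal-to-occipital ratios, SOR = (striatum −
   occipital)/occipital, against the occipital statistic of the same kind;
   whole-SAR volumes are measured on the original-resolution MR labels.
   The result is a fixed 90-vector: 14 regions × 6 statistics = 84 SOR
   features + 6 volumes. Welch t-tests at α = 0.01 select features, a
   linear SVM (C = 1, features standardized by training-fold statistics)
   classifies, leave-n-out cross-validation scores the pipeline, and a
   random forest (500 trees, impurity importance) ranks features.

## Segmentation model

The network is a 3-level residual U-Net: residual blocks of k = 2
convolution (3³) + instance-norm + ReLU layers with identity shortcuts
(1³ projection on channel change), 2³ max-pooling in the encoder,
nearest-neighbour ×2 upsampling and skip concatenation in the decoder, and a
1³ convolution + softmax head at every decoder level. Default channel
ladder (8, 16, 32); a 32³ input region of interest is the desk-scale
default (96³ is the intended setting at clinical resolution — the ROI is a
config field, not a constant).

The loss is

```
L = w_D · E_i[(−ln Dice_i)^γ] + w_C · E_x[−ln p_l(x)],
Dice_i = (2 Σ_x δ_il(x) p_i(x)) / (Σ_x δ_il(x) + p_i(x))
```

with w_D = 0.8, w_C = 0.2, γ = 0.3. E_i averages over the six foreground
labels by default (`include_background` is a switch): the exponentiated
−ln-Dice term exists precisely to keep small structures from being swamped,
and a background term would re-introduce the imbalance. Deep supervision
applies the same loss to each auxiliary head against strided-downsampled
truth, with per-level weights 1/2^level, normalized.

Numerical choices that matter:

* Dice smoothing ε = 1e-6 in numerator and denominator (an absent label
  with no predicted mass scores 1, and the ratio never divides by zero).
* Logarithms are guarded only against true floating-point underflow
  (1e-300 in float64, 1e-30 in float32). An earlier draft clamped
  probabilities at 1e-7, which silently zeroed the gradient of any class
  whose predicted mass had collapsed below the clamp — the class could then
  never recover ("dead class"). The guard must sit far below any reachable
  probability so the rescue gradient survives.
* (−ln Dice)^γ with γ < 1 has unbounded slope as Dice → 1; the backward
  pass floors the base at 1e-6 so a perfectly fitted label cannot produce
  an infinite gradient. Forward values are exact.
* Training runs in float32 by default (~4-7× faster than float64 in this
  numpy implementation); parameters are kept in float64 outside training,
  and all gradient checks run in float64.
* Adam, learning rate 1e-3 order; `train_to_convergence` wraps the plain
  trainer with a warmup (2e-3) + refinement (5e-4, then 2e-4) schedule that
  stops once the network fits its training subjects to a minimum per-SAR
  hard Dice target. Argmax ties break to the lowest label index.

The implementation is a self-contained reverse-mode autodiff engine over
numpy arrays (`pdstriatum.nn`): im2col 3D convolution, pooling/upsampling,
broadcasted arithmetic, and Adam. Analytic gradients of every primitive and
of the composite loss are tested against central finite differences.

## Registration

Similarity is Mattes mutual information (32 bins) — both MR/PET and
template/PET pairs are cross-modal — over a 3-level multi-resolution
pyramid (shrink 4/2/1, smoothing σ 2/1/0 voxels), dense (non-stochastic)
metric sampling, optimized by regular-step gradient descent with
physical-shift parameter scaling (SimpleITK). Dense sampling plus a
deterministic optimizer make results reproducible bit-for-bit for fixed
options. A gradient-free simplex/Powell search was tried first and
abandoned: on phantoms it repeatedly walked into far-rotated local optima
whose MI was worse than at the true pose. The rotation centre is the fixed
image's physical centre; intensity interpolation is trilinear, label
propagation strictly nearest-neighbour.

Two option presets exist: the default (200 iterations, full pyramid;
median recovery errors ~0.05 mm and ~0.4° on phantoms) and
`RegistrationOptions.fast()` (two levels, 60 iterations, ~10× faster;
worst observed phantom errors ~0.5 mm / 4°, i.e. a small fraction of a PET
voxel at striatal radii). The cohort pipeline uses the fast preset; the
registration-accuracy analyses use the default.

All world coordinates are RAS millimetres; NIfTI affines must be
axis-aligned (diagonal); voxel indices are 0-based; anterior is +y, which
defines the anterior→posterior ordering of k-means subregions (index 1 =
most anterior, so indices correspond across subjects).

## Phantom generator: what it emulates, and what it does not

Each synthetic subject is a paired MR/PET volume with gold-standard labels:

* **Geometry.** Axis-aligned ellipsoids for the six SARs (caudate elongated
  anterior-posterior, putamen lateral, pallidum medial and small) and a
  posterior box slab as the parieto-occipital reference, inside an
  ellipsoidal brain envelope. The two hemispheres are mildly asymmetric, as
  real striata are; this also anchors the network's left/right assignment —
  with exactly mirror-symmetric phantoms a convolutional segmenter can
  settle into a left/right label-swapped optimum on some initializations.
  Per-subject, group-independent jitter (3% SD) scales region semi-axes so
  volumes vary realistically but carry no diagnostic signal.
* **MR.** Tissue-mean intensities (background 0, brain 100, caudate 150,
  putamen 165, pallidum 180) plus Gaussian noise; optional linear bias
  field, off by default.
* **PET.** A piecewise-constant uptake field on the MR grid (background
  0.05, brain 0.9, occipital 1.0, caudate/putamen 3.0, pallidum 2.5 in
  arbitrary units), resampled onto the coarser PET grid through the
  subject's true rigid transform with nearest-neighbour interpolation, plus
  Gaussian noise. NN resampling keeps noise-free region means exactly equal
  to the configured values, which gives the feature extractor sharp oracles
  (e.g. whole-putamen mean-SOR exactly (3−1)/1 = 2).
* **Disease effect.** PD subjects lose a configured fraction of SAR uptake
  (putamen 0.40, pallidum 0.25, caudate 0.15), modulated inside the putamen
  by a linear anterior→posterior gradient from 0.5 to 1.0 — the reduction
  is strongest posteriorly, which is where DAT loss concentrates in early
  PD. No quantitative uptake values were available to copy for the cohort
  this emulates; the defaults were chosen once so that groups are cleanly
  separable and were not revisited.
* **Misalignment.** A uniform random rigid MR→PET offset within ±6° / ±5 mm
  per subject, stored as ground truth.
* **Grids.** MR 48³ at 2 mm, PET 32³ at 3 mm by default (PET deliberately
  coarser); a compact 32³ MR configuration exists for desk-scale
  segmentation experiments. Identical (config, seed) pairs are bit-identical;
  per-subject streams derive from the config seed and a stable id hash.

The PET template for the single-modality arm is generated at run time: the
noise-free NL uptake field of the cohort's mean geometry, isotropically
scaled (default 1.05, brain envelope included) to mimic atlas-to-subject
anatomical mismatch, lightly smoothed, with matching labels.

Not modelled: attenuation/scatter physics, partial-volume effects, motion,
anatomical shape variation beyond size jitter, and MR/PET intensity
inhomogeneity beyond the optional bias flag. Consequently, passing results
on phantoms demonstrate the *mechanics* of the pipeline — loss analytics,
registration recovery, feature schema, statistical calibration, leakage-free
cross-validation — not clinical performance. Phantom cohorts are far more
separable than clinical ones; perfect leave-one-out accuracy here says the
pipeline preserves an obvious signal, not that it would achieve any
particular accuracy on real data.

## Statistics

* Welch's (unequal-variance) two-sided t-test per feature: the cohort
  design is unbalanced (49 PD vs 18 NL). No multiple-testing correction, by
  design: the selection rule is the raw α = 0.01 threshold, and its per-
  feature type-I rate is verified by simulation (1000 null replicates).
* Leave-n-out: exact leave-one-out for n = 1; 200 random held-out subsets
  per n otherwise (class-empty training splits are resampled, bounded
  retries). Feature selection and standardization are refit inside every
  training split; the no-leakage property is tested by label permutation
  (accuracy must fall to chance). If no feature passes α in a fold, the
  single lowest-p feature is used so every fold emits a prediction.
* Arm comparisons share identical partitions (same seed) and are paired;
  wrong-prediction counts across n are compared with a paired t-test
  (identical arms are reported as identical with p = 1).
* Random-forest importances are normalized to sum 1 and aggregated per
  statistic kind (mean, median, Q3, Q1, max, min, volume) by summation, so
  the aggregate table is itself a partition of 1.

## Problem sizes

Defaults throughout are phantom-scale: 32³ segmentation ROIs, 48³/32³
grids, 49 + 18 subject cohorts, 3 training phantoms for the cohort
segmentation network, 20 pairs for registration-recovery statistics, 1000
replicates for selection calibration, 100-200 random partitions per
leave-n-out point. These sizes keep the full pipeline reproducible on a
single CPU core in minutes while leaving every algorithmic path identical
to the full-scale setting.

## Known limitations

* The autodiff engine processes one volume at a time (no batching) and has
  no GPU path; it is sized for phantom-scale experiments.
* Only diagonal (axis-aligned RAS) NIfTI affines are supported.
* The segmentation network does not delineate the occipital reference; the
  reference comes from the prior label map in every arm.
* k-means subdivision assumes roughly comparable region shape across
  subjects; grossly different anatomies would break subregion
  correspondence.
* The single-modality arm measures volumes on propagated PET-grid labels
  (there is no subject MR in that arm), so its volume features are
  template-driven and near-constant by construction.
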
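# Methods

## Scientific question and overall design

Male and female brains differ most obviously in size: total intracranial
volume (TIV) is on average 10–15% smaller in females. A classifier trained
to predict sex from brain images without TIV correction can therefore
succeed for two very different reasons — genuine regional structure, or
brain size alone. This package reproduces, on synthetic phantom cohorts,
the analysis pipeline that separates those explanations:

1. train a 3D convolutional sex classifier on minimally preprocessed
   volumes (Male is the positive class);
2. compute gradient class-saliency maps for correctly classified subjects,
   min-max normalise each within the brain mask, and average them — per sex
   and over a TIV-balanced subset — into a composite *sex differences map*;
3. score atlas regions on that map (proportion of voxels with saliency
   > 0.1, and that proportion weighted by the across-regions normalised
   regional mean) and rank them;
4. audit TIV reliance post hoc: per-sex recall in TIV tertiles, and the
   density-overlap interval R_tiv where both sexes' Gaussian KDEs exceed
   20% of their own maxima.

Because real multi-site MRI cohorts are access-controlled, the package is
organised as an analysis over a first-class synthetic cohort generator
whose two signal arms (volumetric and regional) can be switched
independently; every headline behaviour is then a parameter-recovery
statement about planted ground truth.

## Synthetic cohort generator

Each phantom is a brain-extracted ellipsoidal "brain" on a configurable
grid (default 48³ voxels at 3 mm): fixed semi-axis ratios 1.00 : 1.25 : 1.05
(longest front-to-back), concentric tissue-like intensity bands
(core 1.0, mid 0.75, rim 0.45) smoothed with a 0.6-voxel Gaussian, additive
Gaussian noise (SD 0.05) inside the mask, and background exactly zero. The
ellipsoid scale is bisected so the voxel-counted mask volume matches the
subject's sampled TIV; across cohorts the voxelisation error stays within
2%.

Cohort metadata emulate a pooled multi-site study: sex assigned by exact
counts at the configured female fraction (default 1115/2110 ≈ 52.8%, the
pooled composition of the four public cohorts the analysis emulates), site
marginals GE/Philips/Siemens = 11/8/81%, field strengths 3 T/1.5 T =
79/21%, ages uniform over 18–90. Site and field are independent of sex —
the published cohort tables give only marginals, not the joint
distribution.

TIV is Normal per sex, truncated at ±3 SD: male mean 500 ml, SD 35 ml at
desk scale, female mean = male mean × (1 − deficit) with deficit 0.125 by
default. The desk-scale values keep the female–male separation at ≈ 1.8 SD,
matching the separation implied by full-scale cohorts (≈ 1,550 vs
≈ 1,356 ml at SD ≈ 110), while letting the largest truncated brain fit a
144 mm grid. The full-scale 193×229×193 grid at 1 mm remains configurable.

Regional effects are additive intensity shifts (+0.15 by default) applied
to whole labelled regions of the toy atlas for one sex only (female by
default). Using an intensity shift rather than a shape change keeps the
planted ground truth exactly recoverable by region scoring. The toy atlas
places disjoint spherical regions (radius ≈ 18% of the smallest envelope
semi-axis) inside the brain envelope of the smallest plausible phantom, so
every region lies inside every subject's mask.

What the phantoms do *not* emulate: MRI physics (bias fields, vendor
intensity profiles, motion), skull/scalp anatomy, cortical folding,
inter-subject shape variability beyond global scaling, and any site- or
field-dependence of intensities. Passing tests therefore demonstrate that
the *pipeline* recovers planted volumetric and regional signals under
realistic sampling noise — not that the classifier architecture would reach
any particular accuracy on real MRI.

## Preprocessing

* **Rigid registration** (6 degrees of freedom: rotations in degrees about
  the grid centre, Rz·Ry·Rx order, then translations in mm) by Powell
  minimisation of the mean squared intensity difference over a 3-level
  multi-resolution pyramid (shrink factors 4, 2, 1), warm-starting each
  level. Rigid alignment preserves individual brain volume, the property
  the TIV audit depends on; the contract tested is transform recovery on
  phantoms (0.5 voxel / 1°). Because phantoms are generated in a common
  space, the pipeline leaves per-subject registration off by default; the
  operation exists (and is tested) for volumes that arrive unaligned. The
  replacement of nonlinear template warping by shared-space rigid alignment
  is the principal fidelity gap relative to analyses of real, individually
  shaped brains.
* **Z-score normalisation** of intensities within the brain mask
  (population SD; background excluded and left at zero). Within-mask mean 0
  and SD 1 to 1e-6; idempotent. Whether background voxels should enter the
  statistics is genuinely open for real data; within-mask statistics were
  chosen because the phantoms' background is exactly zero and would
  otherwise dominate the moments.
* **TIV estimation** is purely mask-based: voxel count × voxel volume
  (mm³) / 1,000 → ml.
* **Stratified splitting** over sex × site × field strata: 80/10/10 by
  largest-remainder rounding per stratum, reconciled so global totals equal
  the largest-remainder rounding of the whole cohort (2,110 → exactly
  1,688/211/211). Age is deliberately not a stratification key; it enters
  only subgroup reporting. Strata smaller than the number of splits get a
  best-effort assignment with a warning.

## Classifier

A seven-block SFCN-style fully convolutional network: five blocks of
3×3×3 convolution → batch norm → 2× max pool → ReLU; a 1×1×1
convolution → batch norm → ReLU; then average pooling over the entire
remaining spatial extent, dropout (p = 0.5, training only), and a final
1×1×1 convolution to a single pre-sigmoid score. The average-pool kernel is
derived from the input shape by five stride-2 floor halvings (193×229×193 →
6×7×6; 48³ → 1³). Channel widths are configurable; the package default is
(8, 16, 16, 32, 32, 16) and the experiments use (4, 8, 8, 16, 16, 8) —
original SFCN widths are impractical on one CPU and the phantom signals do
not need them.

The network, its training loop, and backpropagation are implemented
directly in NumPy (im2col + BLAS matrix multiplies for the convolutions,
hand-derived backward passes, Adam, reduce-on-plateau). Backprop runs
through to the input tensor, which is exactly the quantity the saliency
maps need; every backward pass is verified against float64 central finite
differences in the test suite. The first convolution skips its input
gradient during weight training (nothing upstream consumes it) and
re-enables it for saliency.

Training protocol: Adam on binary cross-entropy, batch 16, initial learning
rate 0.01, ×0.1 after 5 epochs without validation-loss improvement
(min-mode, no cooldown, strict improvement), 50 epochs by default; the
epoch with the lowest validation loss supplies the final weights.
Augmentation rotates each scan with probability 0.5 by an angle uniform in
[−15°, +15°] about one of the three grid axes chosen uniformly, fresh each
epoch ("on-the-fly"); the bounded-magnitude reading was chosen because a
fixed 15° rotation would make augmented samples bimodal for no benefit.
Dropout is active only during training. Seeded runs are bit-reproducible on
a fixed BLAS configuration.

## Saliency and region scoring

The per-subject map is |∂s/∂x| of the pre-sigmoid score s — the absolute
value is the single-channel reduction of channelwise-max saliency, and the
pre-sigmoid score avoids vanishing gradients when the sigmoid saturates.
With one logit, targeting the other class only flips the gradient's sign,
so one backward pass serves both sexes. Maps are min-max normalised within
the subject's brain mask, zero outside.

Averages (per-sex over correctly classified subjects; composite over the
balanced R_tiv subset) are voxelwise means, re-normalised to [0, 1] by
default so the 0.1 scoring threshold keeps a stable meaning; the
re-normalisation is exposed as a flag since a mean of normalised maps is
already interpretable.

Region scores: saliency score = fraction of in-region voxels with saliency
strictly > τ (τ = 0.1); mean saliency includes sub-threshold voxels (the
regional mean is a property of the whole region); norm_mean is the min-max
of the regional means *across regions* — the only normalisation under which
some region attains 1 — and the weighted score is their product. Ranking is
by weighted score with ties broken by saliency score, then region id.

## TIV audit

Tertiles are rank-based with stable tie order; group sizes differ by at
most one, larger groups first (210 → 70/70/70, 211 → 71/70/70). Per-tertile
female/male recall and their unweighted mean (balanced accuracy) make up
the audit table; a tertile missing one sex reports NaN, never 0.

R_tiv: Gaussian KDE per sex with Scott's-rule bandwidth (recorded in the
output), evaluated on a 512-point grid spanning the pooled range padded by
three bandwidths. The 20% threshold is applied relative to *each sex's own
maximum* density — the reading under which "excluding the low-density
tails" is scale-free; an absolute threshold would change meaning with
sample size and units. The interval is the intersection of the convex hulls
of the two thresholded supports (convex hulls avoid fragmenting on
multimodal KDEs; fragments are logged). Raising the threshold can only
shrink the interval. An empty intersection is an explicit empty result.

The balanced subset keeps correctly classified subjects with TIV inside
R_tiv and down-samples the larger sex uniformly at random (seeded) to match
the smaller, so the composite map weights the sexes equally by
construction.

## Evaluation conventions

Thresholding at probability 0.5 with ties classified as Female keeps the
decision rule total (a strict sigmoid never ties, but the contract must
not depend on that). Balanced accuracy is the unweighted mean of per-sex
recalls; per-sex "accuracy" in tertile tables *is* per-sex recall — the
only reading under which the tabulated balanced accuracy is their mean.
Single-class subgroups report NaN for balanced accuracy and AUC. Metrics
are stored at full precision; printed tables use 3 decimals or half-up
1-decimal percentages.

## Experiment designs and problem sizes

The signal-isolation experiments train on one cohort (n = 200; stratified
80/10/10, train and validation splits drive optimisation) and audit a
*freshly generated* cohort of 210 from the same distribution. Auditing
held-out data matters here: with TIV-only signal the overlap region is
genuinely ambiguous, and a model could memorise training-set noise,
flattening the tertile asymmetry on seen subjects. Experiments run 8
epochs with the narrow channel stack — the planted signals saturate well
before the full 50-epoch protocol, and the selected-epoch rule makes extra
epochs harmless but slow. Three seeds per design; the effect-recovery
check asks for the planted regions in the top (planted + 1) ranking in at
least 2 of 3 seeds, and the TIV-asymmetry check must hold in every seed.

## Known limitations

* The phantom's geometry is globally scaled, so TIV is the *only* shape
  signal; real brains confound size with allometric shape change.
* The smooth ellipsoid is nearly rotationally symmetric about its
  anterior–posterior-orthogonal axis pair with ratio 1.00 : 1.05, so
  rotations about that axis are weakly identifiable by any intensity-based
  cost; registration recovery is specified (and tested) for rotations about
  the clearly asymmetric axes.
* Rigid-only alignment and a shared template sidestep the inter-subject
  correspondence problem that nonlinear warping solves for real data.
* Saliency magnitudes are noisy at the single-subject level; all claims are
  made about averaged maps.
* The NumPy network trains small models on small grids; it is not a
  general-purpose deep-learning stack (no GPU, no autograd beyond the
  layers implemented).
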
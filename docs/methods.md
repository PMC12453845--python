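# Methods

## Problem and pipeline

`cxrcad` implements a patch-based computer-aided-diagnosis pipeline for
two-class lung-cancer screening on chest radiographs (CXR). The pipeline
has three stages:

1. **Patch generation.** Each radiograph is resized so its long side
   equals a working resolution, and a dense grid of overlapping square
   patches is enumerated (stride = `round(patch_size * (1 - overlap))`,
   with the final anchor clamped to the image edge). Candidates are
   ranked by *lung fraction* — the share of their pixels inside the
   binary lung-field mask — and the top `n_patches` are kept (default
   11 patches of 256 px at 25% overlap on a 1024-px working image,
   which yields a 5 x 5 candidate grid). Ties break in row-major grid
   order, so extraction is deterministic. Patches inherit the image
   label; there is no nodule localization anywhere in the pipeline.

2. **Patch selection.** A per-patch two-sample t-test compares pixel
   intensities of the lung region (group 1) against the non-lung region
   (group 2). Patches with two-sided p < 0.003 are retained. Patches
   with less than 5% lung pixels are discarded without testing (they
   carry no diagnostic tissue); patches with more than 95% lung pixels
   are retained without testing (they are exactly the diagnostically
   relevant region, and offer no second group to test against). The
   default statistic is Welch's (unequal variances, Welch–Satterthwaite
   degrees of freedom) because lung and soft-tissue intensity variances
   have no reason to agree; the pooled equal-variance statistic is
   available. No multiplicity correction is applied — the threshold is
   a per-patch filter, not an inference. A mask-free baseline selector
   (per-patch Otsu threshold, retain if ≥ 30% of pixels are dark) is
   provided for comparison.

3. **Classification and evaluation.** A compact five-block CNN
   classifies patches; patch probabilities are averaged into one
   diagnosis per radiograph (cancer iff mean ≥ 0.5, ties to cancer —
   the clinically safer call; majority voting is available). Evaluation
   is grouped stratified k-fold cross-validation: folds partition
   *images*, stratified by label, and every patch follows its parent
   image. Per-patch splitting would leak near-duplicate overlapping
   patches of one radiograph across folds and invalidate the CV — the
   grouping is therefore not optional. Metrics are accuracy,
   sensitivity, specificity, precision and F1 from the pooled confusion
   matrix of each fold, reported per fold and as mean ± sample (n−1)
   standard deviation, at both the patch and the full-image level. Any
   0/0 metric ratio yields 0 with a `degenerate` flag rather than an
   exception, so fold aggregation never crashes.

## The custom CNN

Five blocks of [Conv2D(2x2 kernel, stride 2, ReLU) → batch
normalization → dropout(0.5)], then one non-overlapping 2x2 average
pool, flatten, a fully connected *fusion* layer of width 128, the
two-class head, and softmax. Counting the five convolutions, five batch
norms, five dropouts and the fully connected head gives the
architecture's 16-layer tally (pooling, flatten and softmax are
uncounted). The stride-2 convolutions carry the downsampling
(256 → 128 → 64 → 32 → 16 → 8, pooled to 4): a stride-1 reading would
flatten ~10^7 activations into the dense layers, which is implausible;
stride 2 yields a tractable 8x8x160 tensor. 2x2 convolutions use edge
padding so even sizes halve exactly and odd sizes round up. Default
block widths are (32, 64, 96, 128, 160) — monotone widening with a
modest ~0.5 M parameter total; widths are configurable. The "fusion"
layer is interpreted as a fully connected merge layer between flatten
and the class head — the only reading consistent with the listed layer
order. Windowed 2x2 average pooling is the default; global average
pooling is exposed as an option.

Because no deep-learning framework is part of this package's
dependency set, the layers (convolution via im2col, batch
normalization, inverted dropout, average/max/adaptive pooling, linear,
residual and parallel-branch containers) and the Adam optimizer are
implemented directly on numpy in `cxrcad._nn`, with hand-written
backward passes that the test suite verifies against central finite
differences. Baselines (AlexNet: 5 conv + 3 FC; GoogLeNet: 22-layer
inception network; ResNet-34: 34 weighted layers) are built in their
published shapes on the same layer stack, adapted only to 1-channel
input and a 2-class head.

### Training

Cross-entropy, Adam (lr 1e-3, batch 32 by default; all configurable),
deterministic given the seed and data order. Two optional stabilizers,
both off by default and enabled in the synthetic benchmarks:

* **Polyak/EMA weight averaging** (`ema_decay`): inference uses an
  exponential moving average of the weights, which damps the
  step-to-step oscillation of small-batch Adam.
* **Precise batch-norm recalibration** (always applied after the last
  epoch): running statistics are recomputed exactly over the training
  set under the final weights, since the exponential running average
  lags the weights it normalizes for.

Optional decoupled weight decay and a one-step learning-rate decay are
also available.

## Synthetic phantoms

The generator emulates the gross intensity structure of a
posteroanterior CXR on a 512x512 grid: soft-tissue background at 0.65,
two elliptical lung fields at 0.30 (the lung-field mask is their
union; area fraction ~0.31 of the frame), sinusoidal rib shading of
amplitude 0.05 inside the lungs, Gaussian sensor noise of sigma 0.02,
and — for cancer phantoms — one radiopaque disk of contrast +0.30 and
radius 28 px placed uniformly at random wholly inside a lung. The
radius corresponds to a ~2 cm nodule on a ~35 cm field of view and
scales with image size. An optional low-frequency clutter field
(`background_texture`) outside the lungs emulates off-lung structures
(shoulders, abdomen, labels) for the selection-ablation benchmarks.
Noise, clutter and nodule placement draw from independent seed-derived
streams, so toggling the nodule changes pixels only inside the disk —
a property the tests assert exactly.

What the phantoms do **not** model: projective anatomy (mediastinum,
diaphragm, clavicles), heterogeneous parenchymal texture, exposure and
positioning variation, and nodules that are subtle against overlapping
ribs. Passing the synthetic benchmarks therefore demonstrates that the
pipeline's machinery — geometry, selection statistics, optimization,
leakage-free evaluation — behaves correctly on a controlled,
separable task; it says nothing about clinical accuracy on real
radiographs.

## Desk-scale benchmark configuration

The end-to-end benchmarks run the full pipeline on phantom cohorts at
sizes a single CPU handles in minutes:

* cohort: 40 cancer + 40 normal phantoms, nodule contrast 0.30, noise
  sigma 0.02 (the clean cohort); the cluttered cohort raises rib
  amplitude to 0.15 and adds background texture 0.15;
* patching: 9 patches of 128 px at 25% overlap on a 256-px working
  image — the complete 3 x 3 overlapping grid. At this geometry the
  patch interior (128 − nodule diameter = 100 px) exceeds the 96-px
  stride, so every nodule lies wholly inside at least one patch; with
  64-px patches the stride exceeds the containment interior and a
  nodule can straddle every patch boundary, which caps the achievable
  image-level sensitivity regardless of the classifier;
* model: the custom architecture at input 128 with block widths
  (8, 16, 16, 16, 16) and dropout 0.2 — the full-width model's 0.5
  dropout is matched to 32–160-channel blocks and destroys the signal
  at 8–16 channels;
* training: 50 epochs, lr 3e-3, batch 32, EMA 0.99, two-model
  ensembles per fold (probabilities averaged);
* decision calibration: a stratified 20% of each training fold's
  images is held out of model fitting; after training, the final
  layer's class biases are offset so the boundary sits 30% of the way
  from the normal-side mean of the image-mean probabilities toward the
  cancer-side mean on those calibration images, mapped onto the fixed
  0.5 threshold. The cancer side is left-skewed (images differ in how
  many patches their nodule reaches) while the normal side is tight,
  so a screening-oriented boundary sits nearer the normal mode;
* evaluation: grouped stratified 5-fold CV, mean aggregation; the
  selection ablation uses the same pipeline at k = 2 on the cluttered
  cohort.

These choices interlock. Patch labels are inherited from the image,
so most patches of a cancer phantom look exactly like normal-phantom
patches; the posterior of such an *uninformative* patch sits just
below 0.5, and a cancer image whose nodule reaches only one or two of
its nine patches averages to just under the 0.5 decision threshold
even with perfect nodule detection. Worse, where the
uninformative-patch probability lands drifts with the training run
(regularization strength, stopping time, cohort), in either direction
— no fixed loss weighting or stopping rule is robust to it.
Decision-bias calibration measures the drift on held-out
training-fold images and re-centers the boundary; the validation fold
plays no part in it. With the boundary self-centering, training can
run until nodule-patch confidence saturates — which *widens* the gap
between nodule-bearing and uninformative patches — instead of being
stopped early to keep raw probabilities near their nominal scale. The
per-fold two-model ensemble averages out the initialization and
shuffling lottery of small-batch training on ~500 patches, which
otherwise dominates fold-to-fold variance.

## Numerical choices and edge cases

* Intensities normalized to [0, 1]; JSRT raw files decode as unsigned
  16-bit big-endian over a 12-bit range (÷ 4095), with an optional LUT
  inversion flag.
* Boxes are half-open `[r0, r1) x [c0, c1)`, 0-based, row-major,
  top-left origin.
* Zero-variance t-test groups: equal means → (t=0, p=1); unequal means
  → (t=±inf, p=0). Constancy is detected by range, not by the
  floating-point sample variance.
* Otsu on a constant patch is undefined → the patch is discarded with
  a warning.
* An image whose selection removes every patch falls back to its
  pre-selection patches with a warning; no image is silently dropped.
* Labels are case-insensitive on input and canonical lowercase inside.
* All randomness flows from one top-level seed through
  `numpy.random.SeedSequence` children (per image, per fold); derived
  seeds stay below 2^31.

A structural note on the selection ablation: because patch extraction
already ranks candidates by lung fraction, every selected phantom
patch carries at least ~20% lung and shows strong lung/soft-tissue
contrast, so the t-test retains the full ranked set — on these
phantoms, t-test selection and no selection coincide exactly, and
their comparison is a guaranteed tie. The t-test's discarding power
matters for inputs whose ranked grid still contains near-lung-free
patches (small or displaced lung fields, or coarser candidate
ranking). The Otsu-thresholding baseline, by contrast, genuinely
alters the patch set — it can discard boundary patches whose dark
fraction falls under its cutoff, including the patch carrying a
juxtapleural nodule, which is how it falls behind the t-test run.

## Known limitations

* The numpy training loop is single-threaded BLAS-bound; full-scale
  (256-px, 32–160-channel) training is possible but slow — the package
  is built for method study and desk-scale validation, not for GPU
  throughput.
* The t-test selector needs a lung mask; masks are inputs (or come
  from the generator) — automatic lung segmentation is out of scope.
* Image-level aggregation uses a fixed 0.5 threshold on the mean
  probability; with image-level (weak) labels the patch posterior for
  uninformative patches sits just below 0.5, so the margin is thin by
  construction — the benchmark geometry above is chosen so that
  informative patches exist for every nodule.
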
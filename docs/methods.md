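# Methods

`sonosex` implements a tested pipeline for classifying the sex of red abalone
(*Haliotis rufescens*) from B-mode ultrasound frames. Annotated multi-frame
data of individually identified animals are not generally available, so the
package is driven end-to-end by a synthetic phantom generator whose job is not photorealism but *statistical
fidelity*: it reproduces the properties of the data that the pipeline's
correctness arguments depend on. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic results
do and do not show about real data.

## The phantom generator

Each individual abalone is a draw of latent anatomy (`PhantomSpec`): a bright
specimen ellipse on a near-black background, containing a cone-shaped
digestive gland whose boundary is enveloped by a thin, high-echogenicity
gonad band. All of an individual's frames render from the same spec and
differ only by probe-repositioning jitter (Gaussian translation, sd 1.5 px,
and axis-angle rotation, sd 0.04 rad) and fresh speckle. Speckle is the
standard multiplicative idealization: gamma noise with unit mean and shape
`speckle_shape` (default mean 9; variance 1/shape), applied inside the
specimen only. Region echogenicities default to band ≈ 170, gland ≈ 105,
tissue ≈ 55 on the 8-bit scale, with the background fixed at 1 — strictly
below the ROI threshold of 5, as in the real acquisition where the imaging
field is uniformly dark.

Two consequences are deliberate:

* **Within-individual correlation.** Frames of one animal share anatomy and
  are much more correlated than frames of different same-sex animals. This
  is the property that makes image-level random splitting leak, and it is
  asserted as a generator invariant.
* **Sex signal only where configured.** Sexual dimorphism enters solely
  through configurable offsets: females get a thicker gonad band with a
  darker core and stronger internal texture; males a thinner, brighter,
  homogeneous band. A single `effect_size` scales every offset; at 0 the two
  sexes are the same distribution and no classifier can legitimately beat
  chance on unseen individuals.

Quality defects mirror the three visual exclusion criteria of the manual
QC workflow the package automates:
(a) an echo ghost — an attenuated copy of the specimen added at an offset,
as produced by shell reverberation; (b) missing anatomy — band *and* gland
rendered at plain tissue echogenicity (the criterion is absence of
identifiable gonad and digestive-gland anatomy, so the specimen is
featureless); (c) incomplete capture — the specimen shifted diagonally off
two image borders. A device overlay (constant border plus a blocky
pseudo-text band) can be burned into every frame so overlay stripping is
exercised. Default defect rates (0.18/0.08/0.08) flag roughly a third of raw frames,
the attrition a conservative manual filter produces on field acquisitions.

Filenames follow `<ID>_<location>_<sex>_<size>_<YYYYMMDD>_<frame>.png`; an
individual's identity is the composite key (ID, location, sex, size class).

All randomness derives from one integer seed via counter-based child streams
keyed by stable string/integer paths (crc32 for strings), so any frame or
training run is reproducible in isolation.

## Preprocessing

Overlay stripping removes the maximal constant-valued frame plus a
configured text-band height; a constant ring at background level (≤ 5) is
the dark imaging field, not an overlay, and is left alone. ROI extraction
binarizes at a strict threshold (foreground > 5; a pixel at exactly 5 is
background), labels foreground components with 8-connectivity, ranks them by
hole-filled area — the area enclosed by each outermost contour — and crops
to the winner's axis-aligned bounding box. Ties break on the
lexicographically smallest (row, column) origin. Boxes are 0-based with
explicit height/width. An image with no foreground raises an explicit
"empty specimen" error. Crops are zero-padded to common dimensions
(dataset-wide maxima by default, center-anchored with floored offsets).

Visual quality filtering is manual in practice; the package substitutes three
conservative numeric detectors, run on overlay-stripped, *uncropped* frames
(criterion (c) concerns the acquisition field of view, which a crop
destroys): (a) the maximum off-center peak of the normalized autocorrelation
of the high-pass-filtered frame (a ghost duplicates the speckle pattern
exactly; threshold 0.21); (b) the 99th-percentile-to-median ratio of the
speckle-smoothed foreground (threshold 1.22 — anatomy present means a bright
tail); (c) foreground touching at least two image borders. Thresholds sit at
conservative midpoints of the clean/defective score distributions measured
from the generator, so borderline frames are retained. The detectors never
see sex labels, and a test asserts QC output is invariant to flipping every
label.

## Partitioning and augmentation

Splits are drawn over individuals, stratified by sex: a fixed number per sex
to validation and test (full-scale protocol: 4 + 4 from 22 per sex, leaving
14 per sex in training), the rest to training; every frame inherits its
animal's split. `check_leakage` audits any frame-level membership for
individuals straddling splits and is the oracle used to demonstrate that an
80/20 frame-level random split of multi-frame data must leak.

Offline balancing augments only the training split, cycling each
under-represented individual's originals in filename order and appending
rotation (±15°), brightness/contrast jitter (10%), and zoom (up to 20%)
copies until each individual reaches the target count — by default the
per-sex maximum per-individual count; balancing is per-individual, not
class-equalizing, by default. Augmented rows are
flagged `synthetic` and can never cross splits because balancing runs after
assignment.

Train-time augmentation applies horizontal flip (p = 0.5), color jitter
(brightness 0.4, contrast 0.7, saturation 0.7, hue 0.015 — order as
conventionally listed; saturation/hue are a near no-op on replicated
grayscale and are kept for fidelity to the stated parameter set), random
rectangle erasure (p = 0.4, area 2–20% of the image, aspect 0.3–3.3, zero
fill), and translation up to 10% per axis. Geometric operations use bilinear
interpolation with zero fill: the background of a B-mode frame is black, and
reflection padding would invent tissue.

## The linear baseline

Frames are resized to 64×64 grayscale (bilinear) and flattened to 4,096
features. Standardization statistics and the PCA basis are fitted on the
training partition only — a test corrupts the validation features and
asserts the fitted transforms are unchanged. The logistic classifier uses
inverse class-frequency loss weights, tolerance 1e-4, and at most 5,000
iterations; the grid is C ∈ {0.001 … 100} (13 values) × {L1, L2} ×
{liblinear, saga} × components ∈ {5, 10, 20, 30, 50, 75, 100}, 364
candidates. Selection maximizes validation balanced accuracy (mean of
per-class recalls); ties break toward parsimony (fewer components, smaller
C, L2 before L1). Classes are encoded F = 0, M = 1 (alphabetical) with a 0.5
decision threshold on the M probability. Invalid penalty/solver pairs are
skipped and logged rather than raised.

## The CNN families

Both families are VGG-style stacks of blocks: `convs_per_block` (default 2)
3×3/stride-1/pad-1 convolutions with ReLU, then one 2×2 max pool. The
*forward* family widens channels with depth (64→128→256→512); the *reverse*
family starts wide and narrows (512→256→128→64) — "double compression",
since channel depth and spatial resolution shrink together, an information
bottleneck intended to squeeze out speckle-like texture while keeping
anatomy. Size variants S/M/L take 2/3/4 blocks from the start of the
family's schedule. Exactly one dropout stage sits at the end of the
convolutional stack, immediately before flattening, ahead of a small dense
head and a single sigmoid output trained with binary cross-entropy
(numerically stable log-sum-exp form).

The network is implemented directly on numpy: im2col convolutions, explicit
backprop, He initialization, SGD-with-momentum (0.9) and Adam (β = 0.9/0.999,
ε = 1e-8) optimizers. Training records per-epoch train/validation loss and
accuracy; the best checkpoint is the lowest validation loss among epochs
where it is below the checkpoint gate (default 0.70, read as a quality bar —
no checkpoint is written above it); early stopping fires after `patience`
epochs without validation-loss improvement, with monitoring active from
`monitor_start_epoch`. Full-scale defaults (monitor from epoch 100,
patience 500) suit long training runs; `desk_scale_train_config()` is the
small-problem preset (monitor from 0, patience 30, 60 epochs). Warm starting
loads a checkpoint's weights into an architecture that must match exactly.

The full-scale tuning grid (`full_scale_grid`) enumerates 22 structures —
family × size variant crossed with head width and per-block conv depth, a
repo convention since the structure list itself is not published — times 11
learning rates × 2 dropout rates × 2 optimizers = 44 combinations, 968
specifications in total. Enumeration is bookkeeping only; nothing trains 968
models at desk scale.

## Evaluation and diagnostics

Confusion matrices are exact integer counts, rows = truth (F, M), columns =
predicted. Accuracy, per-class precision/recall/F1 follow the usual ratios;
undefined ratios (empty row/column) are reported as NaN with a flag, never
silently zero. The leakage-inflation harness trains twin models per seed on
a frame-level random split and an individual-level split of matched holdout
size and reports the per-strategy means and their gap.

Feature diagnostics extract intermediate activations (default: the flattened
post-dropout output of the conv stack), render channel-mean overlays,
cluster PCA-reduced features with K-means (10 seeded restarts per K), and
embed with seeded t-SNE (PCA initialization). The elbow is formalized as the
maximum second difference of the WCSS curve anchored at K = 1, whose WCSS is
the total sum of squares and needs no clustering — without the anchor the
smallest tested K could never be selected. When elbow and silhouette
disagree, the disagreement is logged and the silhouette argmax wins.

## Named benchmarks and what they show

`sonosex.benchmarks` freezes four experimental conditions (14 individuals per sex,
5 frames each, 96×96 canvas, no defects; 2 validation and 4 test individuals
per sex):

* **zero-effect** — identical sex populations; the null for leakage checks.
* **linear effect** — photometric dimorphism only: global echogenicity
  offsets of ~5 population sd (band +40, gland +25, tissue +18 toward males)
  with identical geometry. This exists because the default dimorphism —
  thick-but-dim female band versus thin-but-bright male band — leaves the
  band's *integrated* brightness nearly sex-invariant: the two effects
  photometrically cancel, and the remaining signal is geometric, which a
  linear pixel-space model cannot represent across individuals. A "large
  linear effect" therefore has to be photometric by construction.
* **strong geometry** — effect size 2.5 on band thickness with photometric
  offsets zeroed, so the thickness signal is not masked; the recovery
  benchmark on which the desk-scale reverse-S model reaches ≥ 0.9 accuracy
  on unseen individuals.
* **speckle contrast** — heavy speckle (shape ≈ 4) with a weak textural
  effect; the regime for the reverse-vs-forward comparison. At desk scale
  both families saturate near 0.95 and the comparison asserts only that
  reverse is not more than two points worse, not the larger advantage
  reported on real data.

Statistical assertions on these benchmarks use effective sample sizes: a
chance band for a mean over held-out *frames* would be too narrow, because
frames of one animal are correlated by construction, so null bands are
computed over held-out individuals (and, for the baseline null, averaged
over three independent split draws).

**What passing does and does not show.** The phantoms have sharp class
boundaries, a single anatomy template, no probe-pressure deformation, no
attenuation/shadowing, and sex effects that are exactly the configured
offsets — no more. Passing therefore validates the *pipeline*: leakage-free
partitioning, train-only fitting, faithful metric arithmetic, and the
capacity of each model family to recover a signal of the configured kind and
size. It does not validate the magnitude of any accuracy on real abalone
ultrasound, and no such magnitude is asserted anywhere in the suite.

## Problem sizes

Desk-scale sizes are used throughout: 96–128 px canvases, 32–48 px model
inputs, channel schedules of (16, 8) against the full (512, 256, 128, 64)
used only for construction/introspection checks, 40–60 training epochs, and
140-frame cohorts. These were chosen so the complete suite runs in a few
minutes on one CPU while every statistical property above remains
detectable; all full-scale values stay reachable through configuration.

## Known limitations

* The acoustic model is a mask-and-noise idealization (no beamforming,
  attenuation profiles, or depth-dependent resolution).
* QC detector thresholds are calibrated to this generator's score
  distributions; real devices would need re-calibration, and the ghost
  detector assumes the ghost preserves the speckle pattern exactly.
* The numpy CNN is single-threaded-BLAS bound and meant for desk-scale
  experiments, not production training.
* Hue/saturation jitter on replicated grayscale is a near no-op; it is kept
  only so the stated augmentation parameter set is applied verbatim.
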
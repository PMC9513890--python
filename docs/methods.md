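# Methods

## Data model

Volumes are 3D arrays in (x, y, z) index order with voxel spacing in mm and
an origin; orientation handling is deliberately minimal (direction cosines
assumed identity) because the phantoms control their own geometry and the
pipeline never resamples between scans. Voxel indices are 0-based, boxes use
half-open bounds [lo, hi), and geometry equality means exact shape match
plus spacing agreement within 1e-6 mm. NIfTI-1 is the only file format;
masks are stored as unsigned 8-bit.

## Phantom generator

Each phantom emulates a vessel-extracted TOF-MRA volume — the input the
segmentation cascade would receive after bias-field correction and artery
extraction, which are therefore out of scope here.

* **Vessels.** `n_vessels` (default 2) cubic splines through 5 jittered
  control points, pinned to opposite faces of a random axis so each tube
  crosses the volume. The tube is all voxels within a radius drawn uniformly
  from 1.0–2.5 mm of the densely sampled centerline (distance transform with
  physical sampling).
* **Aneurysms.** Diameters follow a lognormal whose *untruncated* mean/SD
  are 5.468/3.283 mm — clinical cohort statistics for unruptured cerebral
  aneurysms — with draws outside
  [2, 20] mm rejected. Truncation shifts the realized mean to ≈ 5.64 mm;
  the acceptance script reports the realized statistics. Each bulge is a
  volume-preserving jittered ellipsoid (axes ±15%) whose centre sits at
  `r_vessel + 0.6·R` from a random centerline point along a random normal,
  so the bulge always intersects the parent wall and most of it lies outside
  the lumen. The label is `bulge \ lumen`; with the 0.6·R offset the label's
  equivalent-sphere diameter stays within a few percent of the drawn
  diameter (the voxel-count test bounds it at 15%). 100 placement attempts
  are made before a `PlacementError`.
* **Intensities.** Clinical TOF-MRA intensity statistics are
  scanner-dependent and unpublished for the reference cohort, so these are
  free parameters: foreground 1.0 ± 0.05,
  background 0.05 ± 0.02, additive noise SD 0.03, optional smooth
  multiplicative bias field (amplitude 0.2, off by default). A 0.6-voxel
  Gaussian on the foreground indicator mimics partial-volume edges.
* **Geometry defaults.** 96³ voxels at 0.5 mm isotropic (typical TOF-MRA
  in-plane resolution): a 5.5 mm aneurysm is ~11 voxels across and a 20 mm
  one still fits. The desk preset keeps the 48 mm physical extent at 64³ /
  0.75 mm so whole cohorts generate and train in minutes on one CPU.
* **Reproducibility.** Per-sample seeds derive from
  `SeedSequence((master_seed, index))`; cohorts are deterministic at any
  size and samples pairwise distinct.

What the phantoms do **not** emulate: MR flow physics, intensity
inhomogeneity across centres, touching/kissing vessels, ruptured-aneurysm
morphology, skull/background tissue. Passing tests demonstrate that the
pipeline's machinery works and can learn shape-vs-tube discrimination; they
say nothing about clinical segmentation accuracy.

## Preprocessing

* **Z-score** over the whole volume (not a vessel mask): the pipeline
  receives extracted-vessel volumes with controlled background, and nothing
  prescribes restricting the statistics to a region.
* **Sobel contour**: 3D Sobel per axis on the *intensity* image (after
  normalization — the stated pipeline order; applying it to a binarized
  mask instead is a plausible alternative reading), Euclidean magnitude,
  rescaled to [0, 1] by the maximum. Replicate padding at the border, so a
  constant volume yields an exactly zero contour.
* **Adaptive label dilation** (coarse stage only): per 26-connected
  component, ball dilation of radius `max(1, round(0.25 · d_eq / mean
  spacing))` voxels with `d_eq` the equivalent-sphere diameter. The 0.25
  coefficient is this package's concretization of "dilate according to
  lesion size"; it is a module constant and easy to change.
* **Eightfold augmentation**: cumulative — originals (N) ∪ z-flips → 2N,
  Gaussian-filtered copies of those → 4N, histogram-equalized copies of
  those → 8N. Labels undergo only the flip; contour channels are re-derived
  from each transformed vessel image. Gaussian sigma is specified in mm
  (default 0.5) and converted to voxels per axis; histogram equalization
  uses 256 bins.

## VOI geometry

Training crops are centred on the label centroid (mean index, rounded
half-up). At inference one box is proposed per 26-connected component of
the coarse mask; boxes whose centres are within side/2 voxels (Chebyshev)
merge at their count-weighted mean centroid, so one lesion split across
touching blobs triggers a single fine pass. Crops beyond the border are
zero-padded (background is zero in extracted-vessel images) and the padding
is recorded; paste-back discards it and combines overlapping VOIs by union.

## Networks

Context blocks contain two stride-1 3×3×3 convolutions with dropout 0.3
between them; downsampling lives only in the stage-entry stride-2
convolution. A stride-2 convolution inside the block would make the
residual addition around it ill-shaped, so this follows the variant 3D
U-Net family the architecture extends. Choices that were genuinely open:

* upsampling = nearest-neighbour ×2 followed by a 3×3×3 convolution;
* SE reduction ratio 8 (config knob);
* deep supervision at the two coarsest decoder levels, upsampled and summed
  into the final head before the softmax;
* instance normalization inside convolution blocks (disable with
  `norm=False`);
* He-initialised weights from the config seed, so parameter counts and
  initial states are pure functions of the config.

The coarse localizer is a compact single-channel encoder–decoder whose
only contract is the stage-one one: single-channel full volume in,
two-class softmax out, trained on dilated labels with the stage-one
schedule. It makes no claim to reproduce any particular detection
architecture.

Both networks run on `aneuseg.nn`, a reverse-mode autodiff engine on numpy
arrays. Feature maps are channels-last internally so the im2col gather is
one sequential copy and each convolution is a single batched BLAS matmul —
the difference between hours and minutes of CPU training. Every layer's
gradient is validated against central finite differences in the test suite.

## Training schedules

Full-scale plans carry the reference two-stage schedule: coarse — 700
epochs, batch 10, RMSProp at 1e-3 with L1 1e-6 / L2 1e-4 and stepwise decay
(×0.5 every ⌈epochs/3⌉, a concretization of "dropped gradually"); fine —
500 epochs, batch 1, Adam at 5e-4, halved on a 10-epoch validation plateau,
early stop after 50 epochs without improvement. All schedules count
epochs.

Desk presets shrink the problem so everything runs on one CPU: 64³ phantoms
at 0.75 mm, 32³ VOI crops, depth-3 networks with 4 base filters, batch 4,
30 epochs. The desk fine preset raises the Adam step to 2e-3 — the 4-filter
network is far smaller than the full-scale model and converges an order of
magnitude faster at the larger step, while 5e-4 remains the full-scale
default. The plateau/early-stop machinery is active in both presets and
unit-tested against scripted loss sequences.

The weighted-loss focal factor is gradient-detached by default — the
weight then rescales the dice gradient without adding a term of its own;
`detach_weight=False` differentiates
through it, at the cost of an unbounded factor derivative near D = 1.

Predictions binarize by per-voxel argmax of the two-class softmax
(equivalent to thresholding the foreground probability at 0.5). VOIs at
inference are normalized globally (once per volume, not per crop), keeping
training crops and inference crops on the same intensity scale.

A constant (e.g. all-zero) input volume short-circuits the cascade to an
empty prediction with an empty VOI manifest: there is no signal to
normalize or segment.

## Evaluation

DSC and VS are pure voxel-count formulas; both-empty cases define to 1.
HD is the full symmetric maximum (no percentile variant) between foreground
voxel-centre point sets in mm; it is undefined when either mask is empty —
those cases return NaN, are counted, and are excluded from cohort HD means.
Cohort summaries report mean ± SD per metric plus a component-level
detection tally (a ground-truth component counts as detected when any
predicted voxel overlaps it).

## Problem sizes

The self-check run trains the desk fine network on 30 phantoms (25
train/validation, 5 held out) and reports held-out mean DSC/HD/VS; it
finishes in about 4 minutes on one CPU and reaches mean DSC well above the
0.5 sanity bar (≈ 0.76 at seed 0). The metric oracles check 200 random mask
pairs up to 12³; diameter statistics use 2000 sampler draws. These sizes
are the package's desk-scale defaults; clinical-scale numbers require
clinical data and GPU-scale training, which are explicitly out of scope.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-scale 128³ training
  is possible but impractically slow — the full-scale presets document the
  reference schedule rather than promise desk-scale runtimes.
* Phantom realism bounds what the learning tests can show (see above).
* The coarse localizer is a generic compact detector, not a reproduction
  of any specific detection network.
* Sub-voxel surface positions are ignored by the HD (voxel centres only),
  matching the point-set definition used for evaluation.
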
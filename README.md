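# aneuseg

Coarse-to-fine cascaded 3D CNN segmentation of saccular aneurysms in
angiographic volumes, exercisable end to end on synthetic vascular phantoms.

## The problem

Unruptured cerebral aneurysms are small saccular bulges on intracranial
arteries. On vessel-extracted TOF-MRA volumes they occupy a few hundred
voxels inside a large, mostly empty field of view, which makes single-pass
segmentation fragile: lesion features vanish as network depth grows and the
foreground/background imbalance starves the loss. The cascade here attacks
both problems:

1. a **coarse localizer** (small single-channel 3D CNN) detects candidate
   lesions on the full volume, trained against labels dilated adaptively with
   lesion size;
2. candidate **volumes of interest (VOIs)** — 64³ cubes at clinical scale —
   are cropped around each coarse component;
3. a **dual-channel fine network** segments each VOI from two aligned
   channels: the z-scored vessel image and its Sobel gradient-magnitude
   contour, which re-injects the morphological boundary information small
   lesions lose in deep layers;
4. fine predictions are pasted back at their original position, combining
   overlapping VOIs by union.

The fine network is a four-level 3D U-Net variant: strided 3×3×3 encoder
convolutions each followed by a residual *context block* (two stride-1
convolutions with dropout 0.3), squeeze-and-excitation channel attention
after the penultimate context block and after the first upsampling block,
and deep supervision — auxiliary segmentation heads at the coarsest decoder
levels summed into the final head before the softmax.

Training minimizes a **weighted dice loss**

    L = -(1 - D)^β · D,   D = (2 Σ g·p + S) / (Σ g + Σ p + S),  S = 1e-4

with β ∈ [0, 1]: the `(1 - D)^β` factor up-weights poorly overlapping
predictions (focal-loss style), and β = 0 recovers the plain soft-dice loss.
Evaluation uses the dice similarity coefficient (DSC), the symmetric
Hausdorff distance (HD, in mm), and volumetric similarity (VS), each
validated against brute-force oracles in the test suite.

Because clinical TOF-MRA cohorts are private, the package ships a **phantom
generator**: smooth tubular vessels along random spline centerlines with
attached ellipsoidal bulges whose diameters follow a truncated lognormal law
(mean 5.468 mm, SD 3.283 mm, bounds [2, 20] mm) matching a published
clinical cohort. Labels mark bulge voxels only, never the parent lumen.
All networks run on a small numpy autodiff engine (`aneuseg.nn`) — no GPU
or deep-learning framework required.

## Worked example

```bash
python examples/04_desk_training_run.py
```

trains the 4-filter dual-channel fine network on 12 phantoms (32³ VOI crops,
weighted dice loss at β = 0.1) and prints, on one CPU in a few minutes:

```
epochs run: 30
training loss: -0.012 -> -0.312
final learning rate: 2.00e-03

held-out per-case scores:
  case 0: DSC 0.720  HD 1.50 mm  VS 0.954
  case 1: DSC 0.054  HD 6.45 mm  VS 0.403
  case 2: DSC 0.691  HD 2.37 mm  VS 0.751

mean DSC 0.489, VS 0.703 — the loss fell and the network segments unseen
phantom aneurysms.
```

The loss trajectory shows the optimizer converging; the per-case scores are
the three phantoms the network never saw. The weak case is a small lesion a
few voxels across at this resolution — exactly the failure mode that
motivates the cascade at clinical scale; the 30-phantom self-check run
(`desk_learning_run`, also driven by `scripts/acceptance.py`) reaches mean
held-out DSC ≈ 0.76. The other examples cover phantom generation,
preprocessing/augmentation, VOI geometry + metrics, and the full two-stage
cascade.

A thin CLI mirrors the pipeline stages
(`aneuseg generate | preprocess | train-coarse | train-fine | infer |
evaluate | ablate-beta`); see `aneuseg --help`.

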
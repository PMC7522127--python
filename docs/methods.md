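# Methods

## Problem and model

`petseg` delineates FDG-avid tumors in co-registered whole-body PET/CT and
derives metabolic burden (TMTV, SUVmax). The design answers three
constraints of eyes-to-thighs data: volumes too large for a single 3D
network, extreme class imbalance (tumor voxels are typically < 0.5% of a
volume), and strong anatomical heterogeneity of both modalities. The
pipeline therefore (i) segments 2D slices with a multi-scale network,
(ii) normalises anatomy with deterministic organ landmarks, and (iii)
refines candidate components with region-specific 3D networks on patches,
fusing 2D and 3D probabilities into the final mask.

### Geometry and units

All volumes are `(z, y, x)` arrays: z index 0 most superior, y index 0
most anterior, x index 0 patient-right. "Patient-right" is low x; the
liver is therefore expected at low x. Spacing is millimetres; PET is
body-weight SUV (dimensionless), CT is Hounsfield units. Preprocessing
resamples to isotropic 2 mm (linear for intensities, nearest for masks);
physical extent is preserved to within one voxel per axis.

### SUV

Body-weight SUV with a single decay correction to acquisition start:
`SUV = A · w / (D · 2^(−Δt/T½))`, with F-18 half-life 6586.2 s by default.
Lean-body-mass variants are out of scope; which flavour the clinical
protocols used is not derivable from the header fields we consume, and
SUVbw is the common denominator. Conversion refuses incomplete
calibration (missing dose/weight/times) and negative uptake times.

### Landmarks

All three detectors are morphology only, hence bit-deterministic:

* **Brain**: threshold PET at 2.5 SUV, 26-connected labeling, most
  superior component with volume ≥ 500 mL. The threshold is a config
  value; 2.5 separates brain (SUV ≈ 6) from blood pool (≈ 0.7) with wide
  margin.
* **Liver**: search window from 100 mm to 500 mm below the brain bounding
  box on the patient-right half; threshold 1.0 SUV (normal hepatic
  uptake); 3D hole fill; erosion with a radius-8 mm ball (4 voxels at
  2 mm); among surviving components whose COM lies in the patient-right
  third of the x axis, the largest wins (ties: more superior). The
  "largest" reading (rather than "most superior") is a deliberate choice:
  it is robust to small hot nodules in the window.
* **Lungs**: CT < −300 HU; keep the 8 largest 3D components; per axial
  slice, drop 8-connected regions touching the slice border (removes the
  surrounding air, which always touches borders); erode 3×3×3; keep the
  2 largest components; return the COM of their union. A single combined
  COM (not two per-lung COMs) is used downstream.

Regions are z-slabs: head-neck above the lungs' bounding-box top, chest
from there to the liver COM slice, abdomen-pelvis below. The two planes
are exposed in config; slabs make region assignment trivially
deterministic and match how the landmarks are actually used (as reference
heights, not organ masks).

### Networks

The 2D network is a U-Net whose per-level block is two residual
sub-blocks. Each sub-block runs depthwise 3×3 convolutions at dilation
rates (1, 2, 4, 8) in parallel, concatenates the four branches, fuses
with a pointwise convolution, batch-normalises, adds the block input and
applies ReLU. Concatenation+1×1 was chosen for the branch merge
(addition is available via config); rates 1/2/4/8 give a one-block
receptive field of 31 pixels against 9 for undilated stacking, which is
what lets a shallow network distinguish a 5 cm brain from a 1 cm lesion.
Filters double per level from `base_filters` (default 8, depth 6;
448×512 native input, fully convolutional for any size divisible by
`2^(depth−1)`). Downsampling is max-pooling, upsampling
nearest-neighbour + pointwise reduction, output 1×1 conv + sigmoid.

The 3D refiner is V-Net-style with encoder stages of (16, 32, 64, 128)
filters and three upsampling blocks. The first stage runs at full
resolution and the following three each open with a stride-2 convolution:
three downsamplings, mirrored by the three upsamplings, so output shape
equals input shape and patch edges need only be divisible by 8 (32, 64
and 96 all qualify; a literal four-downsampling stack could not restore
the input shape with three upsamplings, and 96 is not divisible by 16).
Decoder stages use nearest upsampling, skip concatenation, pointwise
fusion and one residual 3×3×3 conv+BN+ReLU stage.

Both networks run on `petseg.nn`, a small reverse-mode autodiff engine on
numpy arrays (convolutions with stride/dilation, depthwise convolution,
max-pool, nearest upsampling, batch norm, the usual pointwise ops;
RMSProp and Adam). Gradients are verified against central differences in
the test suite; the depthwise convolutions optionally use numba kernels
(numpy fallback produces identical results). float32 is used for network
graphs and float64 for metric evaluation; dtype is preserved through the
graph.

### Losses

2D: soft Dice plus weighted BCE, `w = |V|/max(Σy, 1)` on the positive
term, mean-reduced so magnitude is image-size invariant. The published
algebraic form of the weighted cross-entropy is internally inconsistent
as typeset (its `(1 − |V|/Σy)` factor makes the negative term change sign
whenever positives are a minority, and the leading sign inverts the
bracket); the standard class-frequency-weighted BCE is what that text
describes in words, and the literal printed variant is available behind
`weighted_bce_term(..., literal=True)` for comparison. 3D: Dice +
sensitivity + voxel-mean absolute error; each term lies in [0, 1], the
total in [0, 3]. All ratio terms carry ε = 1e-6 (so two empty masks give
Dice term 0 and an empty target gives sensitivity term 0), probabilities
are clipped at 1e-7 before logs. Evaluation conventions: hard Dice of two
empty masks is 1.0; sensitivity with empty truth is reported as 1.0 with
an explicit flag.

### Cascade

The orientation-averaged 2D probability volume is thresholded at 0.5
(ties positive, everywhere in the pipeline), 26-connected components are
assigned to the region of their centroid voxel, and each component
produces one centred cube of the region's patch edge — or a 50%-overlap
tiling of its bounding box when it is larger. Cubes are gathered with
zero padding and exact inverse geometry; overlapping patch predictions
are averaged; voxels outside every patch get 3D probability 0. Fusion
averages the 2D and 3D probability volumes (not hard masks — the soft
reading lets a confident 3D veto actually remove a 2D false positive)
and thresholds at 0.5. Landmark failure degrades to a single whole-volume
CHEST region with a warning rather than aborting.

## Synthetic phantom

The generator renders hard-edged ellipsoids on a (220, 112, 128) grid at
2 mm (a ~44 cm eyes-to-thighs torso): body envelope (soft tissue 40 HU,
blood-pool SUV 0.7) in −1000 HU air; brain sphere r = 50 mm (≈ 524 mL,
SUV 6); two lung ellipsoids (−700 HU, SUV 0.3); heart sphere (SUV 5);
liver ellipsoid ≈ 1.4 L (SUV 2) centred patient-right; bladder sphere
(SUV 8); then n tumors (default 3) with radii 6–15 mm and SUV uniform in
3–10, placed by rejection sampling inside the body, disjoint from each
other and from the brain/heart/bladder so per-lesion ground truth stays
exact. Additive Gaussian noise: σ = 0.1 SUV and 20 HU. Ground truth
(mask, organ COM/volume/bbox, region planes) is measured from the
rendered grids, so it is consistent by construction.

What the phantom does *not* emulate: partial-volume effects, scanner
point-spread, respiratory motion, anatomical shape variation, uptake
texture. Passing tests therefore demonstrate that the pipeline machinery
is correct and learnable-on, not clinical-grade accuracy; the published
clinical Dice/sensitivity figures are not reproducible from synthetic
data and are not claimed.

## Desk-scale study conditions

Full-scale training (98k slices, 25/100 epochs) is far beyond one CPU;
the package fixes one scaled-down configuration in `petseg.presets` and
uses it everywhere (tests and the reproduction script):

* 2D: depth 3, base 8 filters (≈ 21k parameters), trained on 200 slices
  drawn from 16 phantoms over axial+coronal+sagittal reformations
  (all tumor slices kept, tumor-free slices rebalanced to 10%, windows of
  112×128), 10 epochs, RMSProp with a desk-scaled hold-then-halve
  schedule (2e-3 for 6 epochs, halved every 2 thereafter) — the shape of
  the published schedule at learning rates suited to ~130 steps of
  training. Window placement matters at this scale: half of the
  tumor-slice windows are positioned uniformly at random (a window that
  always tracks the tumor never shows the network distant physiological
  uptake), and tumor-free-slice windows centre on a high-uptake voxel
  when one exists. Drawing the 200 slices from many phantoms buys tumor
  diversity at a fixed slice budget. A depth-4 variant (larger receptive
  field) was evaluated and overfits 200 slices without held-out gain.
* 3D: one V-Net with filters (4, 8, 16, 32) on 32³ patches shared by all
  three regions (~50 patches: one per truth lesion plus equal negatives),
  12 epochs, Adam 2e-3 with the analogous 6/3/3 piecewise schedule.
  Half of the negative patches are centred on high-uptake (≥ 2.5 SUV)
  tumor-free voxels: at inference the refiner only ever sees cubes around
  *detected* components, which include physiological hotspots the 2D
  stage flags, so purely uniform negatives would be a train/test
  mismatch. This is the one place the sampling deviates from uniform.
* Evaluation: Dice of the orientation-averaged 2D-stage output (the
  "2D masks only" quality measure), pooled over 3 held-out phantoms;
  V-Net patch Dice on held-out patches; and a 20-phantom held-out cohort
  with tumor counts cycling 1–5 (a correlation analysis needs burden
  dynamic range, as a patient cohort would have) processed by the full
  cascade with axial-only 2D inference — the problem size chosen so the
  whole analysis runs in minutes on one CPU. The physiological
  false-positive volume is nearly constant across phantoms, so it shifts
  TMTV estimates without scrambling their ranks.

## Numerical and degenerate-input choices

Threshold comparisons are `>=` throughout (binarisation, fusion ties).
Component connectivity: 26 in 3D, 8 in 2D. Empty probability maps yield
empty component sets, empty masks yield TMTV 0 and SUVmax `None`.
Resampling short-circuits when input spacing already equals the target
(bitwise idempotence). Training aborts on non-finite loss with the epoch
in the message. All randomness flows through explicit
`numpy.random.Generator` seeds: phantom rendering, dataset subsampling,
weight initialisation and batch shuffling are reproducible; inference is
deterministic given fixed checkpoints.

## Known limitations

* The tiny trained models mis-segment part of the phantom's physiological
  uptake (typically the bladder, whose size and intensity overlap the
  tumor distribution) — the desk-scale analogue of the false-positive
  modes discussed for the full-scale system; held-out Dice and the TMTV
  correlation should be read with that offset in mind.
* PET–CT registration is assumed (inputs co-localized); no motion or
  scatter handling.
* The DICOM reader consumes the common single-frame series layout with
  `RadiopharmaceuticalInformationSequence`; exotic vendor layouts are not
  handled.
* `petseg.nn` is a CPU engine built for this package's scale; it is not a
  general training framework.
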
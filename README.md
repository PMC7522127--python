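# petseg

Automated tumor segmentation and metabolic burden quantification for
whole-body (eyes-to-thighs) FDG-PET/CT.

Metabolically active tumors take up ^18^F-fluorodeoxyglucose and appear as
hotspots in PET; radiologists delineate them to measure **total metabolic
tumor volume (TMTV)** and **SUVmax**, but manual whole-body delineation is
slow and reader-dependent. The difficulty for automation is that normal
tissue also lights up (brain, heart, liver, bladder), tumor voxels are a
tiny fraction of the volume, and full 3D networks do not fit whole-body
grids. `petseg` implements a cascaded 2D→3D convolutional pipeline for
this problem, aimed at researchers working on PET/CT quantification:

1. **Preprocessing** — load DICOM series or NIfTI, derive body-weight SUV
   from the calibration header,
   `SUV(v) = A(v) · w / (D · 2^(−Δt/T½))`
   (activity concentration `A` in Bq/mL, weight `w` in g, injected dose `D`
   in Bq decay-corrected over the uptake time `Δt`), and resample both
   modalities to an isotropic 2 mm lattice.
2. **2D segmentation** — a modified U-Net segments axial and sagittal
   slices (2-channel PET+CT input, native size 448×512×2); each level uses
   two residual blocks with batch-normalised, depthwise-separable
   convolutions evaluated at four dilation rates (1, 2, 4, 8). The two
   orientations' probability volumes are averaged.
3. **Anatomical normalisation** — deterministic morphology finds the brain
   (most superior PET component ≥ 500 mL above SUV 2.5), the liver
   (threshold 1.0 SUV in a window inferior to the brain, hole filling,
   8 mm spherical erosion, largest patient-right component) and the lungs
   (CT < −300 HU, 8 largest components, axial border removal, erosion, 2
   largest), and splits the body into head-neck / chest / abdomen-pelvis.
4. **3D refinement** — connected components of the 2D mask are re-examined
   by region-specific V-Nets (encoder stages of 16/32/64/128 filters,
   3×3×3 kernels, ReLU) on patches of 32³ (head-neck), 64³ (chest) and
   96³ (abdomen) voxels.
5. **Fusion and metrics** — the 2D and 3D probability volumes are averaged
   and thresholded at 0.5; TMTV, SUVmax and per-lesion statistics are
   computed from the final mask.

Training uses two compound losses built for extreme class imbalance:

* 2D: `L = [1 − 2|P∩T|/(|P|+|T|)] + BCE_w`, a soft-Dice term plus
  binary cross-entropy with the positive class weighted by `|V|/Σy`;
* 3D: `L = [1 − 2|P∩T|/(|P|+|T|)] + [1 − |P∩T|/|T|] + (1/|V|)Σ|y−ŷ|`,
  Dice + sensitivity + mean absolute error, penalising false negatives.

The published schedules are implemented exactly (2D: RMSProp, batch 16,
25 epochs, lr 1e-5 for 13 epochs then halved every 3; 3D: Adam, batch 4,
100 epochs, lr 1e-4/5e-5/2.5e-5 for 50/25/25), along with the slice
rebalancing that keeps ~10% tumor-free slices.

Everything is testable without clinical data through a seeded synthetic
phantom: a soft-tissue body with air background, two −700 HU lungs, a hot
brain (SUV 6, ≥ 500 mL), moderate liver (SUV 2), heart/bladder hotspots
(SUV 5/8), blood-pool background (SUV 0.7) and ellipsoidal tumors of
configurable count, size and uptake (default SUV 3–10), plus per-modality
Gaussian noise. Networks run on a small numpy autodiff core
(`petseg.nn`), so the package needs no GPU framework.

## Worked example

```python
from petseg.phantom import PhantomSpec, generate_phantom
from petseg.presets import train_tiny_models, desk_cascade_config
from petseg.cascade import run_pipeline

models = train_tiny_models(seed=0)          # ~6-8 min on one CPU
study, truth = generate_phantom(PhantomSpec(seed=1000))
result = run_pipeline(study, models.model_2d, models.models_3d,
                      desk_cascade_config(orientations=("axial",)))
m = result.metrics
print(f"TMTV {m.tmtv_ml:.1f} mL (truth {truth.tmtv_ml:.1f}), "
      f"SUVmax {m.suv_max:.1f}, {m.n_lesions} lesion(s)")
```

Output (seed 0 training, phantom seed 1000):

```
TMTV 45.8 mL (truth 25.9), SUVmax 8.4, 7 lesion(s)
```

The desk-scale cascade finds all three true tumors but, like its
full-scale counterpart, also picks up part of the physiological uptake
(chiefly the bladder, whose size and intensity overlap the tumor
distribution) — a roughly constant ~20 mL addition plus small speckle
components. Because that offset is nearly constant across subjects, the
*ranking* of tumor burden is preserved: over a 20-phantom held-out cohort
the Spearman correlation between estimated and true TMTV is 0.99 (seed 0;
recomputed by the reproduction script below). Landmarks and regions are
available on the result (`result.landmarks`, `result.regions`), and
`petseg run / landmarks / metrics / phantom / train-2d / train-3d` expose
the same steps on the command line.

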
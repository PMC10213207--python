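# octva

Foveal morphometry from macular OCT B-scans, and multimodal
transformer-fusion models that predict postoperative best-corrected
visual acuity (BCVA) after cataract surgery.

## Who this is for

Cataract surgery usually restores vision, but macular disease can limit
the outcome. Predicting the postoperative BCVA from the preoperative
work-up helps set expectations and triage surgical decisions. `octva`
implements such a pipeline end to end for researchers working with
macular OCT:

- **Morphometry.** From a horizontal B-scan through the fovea, the
  package segments the internal limiting membrane (ILM) and the retinal
  pigment epithelium (RPE), builds the calibrated retinal-thickness
  profile, locates the five foveal landmarks (temporal rim, temporal
  wall, center, nasal wall, nasal rim) and computes seven macular
  indices: foveal thickness, pit depth, pit diameter, temporal/nasal
  max thickness, and temporal/nasal foveal slope.
- **Prediction.** Five fusion models (I–V) combine the horizontal and
  vertical B-scans, the preoperative BCVA and the seven indices. Images
  pass through a CNN backbone into 512-dim features; each modality
  becomes a token (128-dim from images, 32-dim from scalars, projected
  to a common width); a transformer encoder with a learnable prediction
  token fuses them:

      MSA(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V

  Training minimizes the RMSE loss with SGD (lr 0.01, x0.1 every 40
  epochs, <= 100 epochs).
- **Evaluation.** MAE/RMSE for the regression; for the "improved by at
  least two chart lines" endpoint (preop − postop >= 0.2 logMAR):
  precision, sensitivity, accuracy, F1, ROC/AUC, and DeLong's paired
  AUC comparison.
- **Synthetic data.** No clinical images ship with the package. A
  phantom generator renders B-scans whose pit morphology is known in
  closed form, and simulates cohorts with a known morphology-to-outcome
  mapping, so every stage is testable against ground truth.

The neural network runs on a small numpy autodiff engine included in
the package (`octva.nn`); there is no GPU or deep-learning-framework
dependency.

## Worked example

```python
import numpy as np
from octva import PhantomSpec, generate_phantom, extract_indices_pipeline

spec = PhantomSpec(rim_thickness_t=350, rim_thickness_n=350,
                   center_thickness=220, noise_sd=6, seed=1)
img, truth = generate_phantom(spec)
idx = extract_indices_pipeline(img)
for name, got, want in zip(
    ("foveal_thickness_um", "pit_depth_um", "pit_diameter_um"),
    idx.as_array(), truth.indices_true.as_array(),
):
    print(f"{name:20s} measured {got:8.1f}   truth {want:8.1f}")
```

prints

```
foveal_thickness_um  measured    218.0   truth    220.0
pit_depth_um         measured    129.3   truth    130.0
pit_diameter_um      measured   3170.8   truth   3125.0
```

i.e. the pipeline recovers the phantom's closed-form morphology to a
few microns despite the added noise. The same flow from the shell, with
training and evaluation included:

```sh
octva end2end --n-eyes 200 --variant V --seed 0 --outdir run/
```

which writes the cohort (`cohort.csv`, phantom PNGs), the extracted
indices (`indices.csv`), a trained variant-V checkpoint, per-eye
predictions, and `metrics.json` with mae/rmse/precision/sensitivity/
accuracy/f1/auc.

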
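# Methods

This note documents the models, algorithms and design choices behind
`octva`: what each stage assumes, which knobs matter, and what the
synthetic phantoms do and do not establish about behaviour on clinical
scans.

## Problem setting

Cataract surgery restores vision unless macular disease limits it.
`octva` implements a pipeline that predicts postoperative best-corrected
visual acuity (BCVA, logMAR) from preoperative macular OCT: foveal
morphometry extracted from B-scans, plus multimodal fusion models that
combine the B-scans, the morphometric indices and preoperative BCVA.
Because no clinical images ship with the package, a synthetic phantom
generator with closed-form ground truth stands in for patient data in
every test.

## Device calibration

Three scanners are supported, each with a fixed scan geometry
(width x depth in tissue over a native pixel grid): 10,000 x 2,000 um
over 768 x 496 px (spectralis), 6,000 x 2,000 um over 938 x 625 px
(cirrus), 10,000 x 2,000 um over 1020 x 960 px (rtvue). Lateral and
axial um/px are the ratios of these constants. Exported frames are often
resampled, so calibration accepts an actual image size and rescales the
factors while preserving the physical extents exactly.

## Layer segmentation

Total retinal thickness needs two boundaries: the internal limiting
membrane (ILM), the first bright interface from the vitreous side, and
the retinal pigment epithelium (RPE), the dominant bright band at the
outer retina. The stages:

1. **Denoise** — 3x3 median filter (impulse-robust, edge-preserving),
   optional Gaussian follow-up. OCT speckle statistics are not modelled;
   the median's rank nature makes the exact noise law unimportant here.
2. **Connect + edge** — bright pixels (above the 0.90 intensity
   quantile) are dilated with a 3x3 structuring element so broken
   boundary fragments merge, then a depth-direction Sobel gives the edge
   map. Both boundaries of interest are near-horizontal, so only the
   vertical gradient is used.
3. **ILM probe** — per column, the first downward dark-to-bright
   transition whose gradient exceeds 0.3x that column's maximum
   (adaptive, so absolute scanner intensity scales cancel), refined to
   the membrane line's intensity peak with a 3-point parabola on a
   lightly Gaussian-smoothed column. Columns without a transition are
   interpolated; fewer than 50% valid columns raises a segmentation
   failure (the analogue of excluding ungradable scans).
4. **Flatten** — integer per-column shifts put the ILM on a common
   reference row. Shifts are recorded so curves can be mapped back;
   because shifts are per-column and rigid, ILM-to-RPE distances are
   exactly preserved.
5. **RPE probe** — on the flattened frame, each column is searched from
   ILM+50 um to ILM+600 um (below the inner retina, above the choroid;
   the deep limit covers edematous retinas). Band centers are peaks of
   the axially smoothed intensity; near-ties (within 5%) resolve to the
   deeper candidate because the RPE is the outermost bright band.
   Positions are mapped back through the recorded shifts **before** gap
   interpolation and curve smoothing — smoothing in flattened
   coordinates would smear the integer-shift staircase into a sawtooth
   on the thickness profile (about 0.5 px, enough to disturb rim
   localization on tilted scans).
6. **Thickness** — (RPE row − ILM row) x axial um/px; negative values
   are clipped to zero and counted in QC.

Boundary curves are smoothed with a moving average spanning ~150 um.
All detection is deterministic; the same frame always yields the same
curves.

## Foveal marks and the seven indices

The foveal pit is parameterized by five marks on the thickness profile
of the horizontal meridian: temporal rim, temporal wall, center, nasal
wall, nasal rim. Definitions:

- **center** — zero-slope local minimum nearest the frame center,
  searched in the central half of the scan;
- **rims** — the first zero-slope peak outward of each wall;
- **walls** — the steepest point (maximum |slope| of the expected sign)
  between center and periphery on each side.

"Zero slope" uses a tolerance of 0.02 um/um, since exact zeros do not
occur on sampled data. Mark location runs on a cubic Savitzky–Golay
smooth spanning ~500 um (residual boundary noise otherwise creates
spurious extrema on the walls), with two refinements that remove the
biases heavy smoothing introduces:

- the center snaps back to the minimum of the lightly smoothed profile
  within +-4 px;
- each rim is re-localized as the zero crossing of the slope on a
  lighter (~180 um) smooth, then refined by fitting a line to the inner
  slope branch 2–10 px inside the rim and extrapolating it to zero.
  The inner branch is steep in slope while the outer side is nearly
  flat, so the crossing is well-conditioned where a plain argmax of a
  flat-topped peak is not. A crossing is accepted only where the heavy
  smooth's slope has dropped below 30% of the wall slope, which rejects
  crossings caused by localized boundary glitches.

The seven indices follow from the marks: foveal thickness (at the
center), temporal/nasal max thickness (at the rims), pit depth (mean rim
thickness minus foveal thickness — the mean-rim convention; a per-side
reference would differ only for markedly asymmetric pits), pit diameter
(rim-to-rim lateral distance in um), and the two wall slopes, reported
as atan of the um-per-um thickness gradient at the walls, in degrees.
Slopes are measured on the thickness profile rather than the inner
surface; on phantoms with a flat RPE the two coincide.

Profiles without a central depression (flat, monotone, or dome-shaped as
in macular edema) raise a no-pit error carrying fallback marks: center =
minimum-thickness column of the central window, rims = thickness maxima
on each side. Indices computed from fallback marks carry a QC flag and
pit depth may legitimately be near zero or negative; it is reported
unclamped.

## Synthetic phantoms

A phantom B-scan renders, per column: dark vitreous, a thin bright ILM
line (Gaussian profile, sigma 0.9 px), a moderately bright retinal
interior, and a bright RPE band (erf-edged box, default 5 px wide). The
thickness profile is a raised-cosine pit: on each side of the center,
over halfwidth `w`, thickness rises from the center value to the rim
value along `(1 - cos(pi d / w))/2`. This shape was chosen because every
landmark is closed-form: the center and rims are genuine zero-slope
extrema and the maximum wall slope `pi (T_rim - T_center) / (2 w)` falls
exactly at `d = w/2`. Beyond the rims the retina thins along a log-cosh
curve whose slope starts at zero (the rim remains a zero-slope peak) and
saturates at 35% of that side's wall slope — emulating normal
parafoveal-to-peripheral thinning and keeping the wall the steepest
point. The interior band starts 2.5 px below the ILM line so the line's
local neighbourhood is symmetric and its intensity peak unbiased.

Noise is additive Gaussian (default sd 6 grayscale units on ~200-unit
boundary contrast) with an optional multiplicative log-normal speckle
toggle. The scanners' true noise textures are not modelled; phantom
realism is calibrated to geometry, not texture, so segmentation results
on phantoms bound algorithmic error, not clinical error.

Simulated cohorts draw preoperative BCVA from a truncated normal
(0.66 +/- 0.52 logMAR on [-0.3, 2.0] — the truncation keeps the left
tail physical), pit geometry from truncated normals chosen to give
foveal thickness, pit depth, diameter and slopes on the scales observed
in surgical cataract cohorts (center thickness 277 +/- 150 um truncated
to [120, 700]; rim excess 92 +/- 40 um; halfwidth 1100 +/- 350 um), and
generate the postoperative outcome from a linear model:

    postop = -0.16 + 0.50 * preop + 0.30 * (foveal_thickness - 277.4) / 310.32 + e,

with residual sd 0.10 logMAR, clamped to [-0.3, 2.0]. These coefficients
make the marginal postoperative distribution land near 0.17 +/- 0.32
logMAR while giving both acuity and morphology genuine predictive value,
so modality-ablation experiments have a known answer. Cohort phantoms
default to 256 x 192 px frames (calibration rescaled accordingly) to
keep full-cohort experiments fast.

## Fusion models

Five variants share one architecture and differ in inputs: I horizontal
B-scan; II vertical B-scan; III both; IV both + preoperative BCVA; V
both + BCVA + the seven indices.

- **Image branch** — both B-scans share one convolutional backbone (a
  strided stem plus three residual conv blocks, global average pooling,
  and a linear layer) that flattens each frame into a 512-dim feature
  vector. The backbone is intentionally compact: it trains from random
  initialization on a single CPU at the cohort sizes used here. Inputs
  are resized to `image_size` (default 224; experiments here use 64) and
  scaled to [-0.5, 0.5].
- **Encoding** — each image feature becomes a 128-dim token; the
  preoperative VA (1-dim) and the index vector (7-dim) become 32-dim
  tokens. Because attention needs a common width, every token is then
  linearly projected to d_model = 128 and concatenated with a learnable
  prediction token of the same size. Scalar inputs are z-scored with
  train-set statistics first, so um-scale indices cannot dominate.
- **Fusion** — a stack of transformer encoder layers (default 2 layers,
  4 heads, FFN width 256), each MSA + residual + LayerNorm then FFN +
  residual + LayerNorm, with MSA(Q,K,V) = softmax(Q K^T / sqrt(d_k)) V.
  No positional encoding is used: modality identity lives in the
  per-modality projections, making the token set unordered (verified by
  a permutation-invariance test). The prediction token's output passes
  through a linear head to a single logMAR scalar.
- **Training** — SGD minimizing the RMSE loss sqrt(mean((y_hat - y)^2)),
  initial learning rate 0.01 decayed x0.1 every 40 epochs, at most 100
  epochs; the best-on-validation checkpoint is returned. Default SGD
  momentum is 0.5: the RMSE loss has a scale-free gradient (its
  magnitude does not shrink as the fit improves), and heavier momentum
  produces sustained oscillation that inflates run-to-run variance at
  small epoch budgets. For runs much shorter than 100 epochs the decay
  step is scaled proportionally (e.g. every 8 of 20 epochs), a faithful
  miniature of the 40-of-100 schedule. Everything (init, shuffling) is
  driven by one seed; training is bit-reproducible.

All tensor operations run on a small reverse-mode automatic
differentiation engine written on numpy (`octva.nn`), validated against
central finite differences; convolution uses im2col.

## Evaluation

MAE and RMSE score the regression. The clinical endpoint is improvement
by at least two chart lines: preop − postop >= 0.2 logMAR. Predicted
labels come from the same rule applied to the predicted postop;
the continuous predicted improvement (preop − y_hat) is the ROC score —
the regressor itself is the classifier, no separate head is trained.
Precision, sensitivity, accuracy and F1 use the standard formulas, with
zero-denominator ratios reported as flagged nulls rather than zeros.
AUC is trapezoidal (equal to Mann–Whitney concordance with average-rank
tie handling); paired AUCs are compared with DeLong's test (midrank
formulation), two-sided.

## Problem sizes used in the shipped experiments

The acceptance suite and `scripts/acceptance.py` run scaled-down
versions of the full protocol, chosen as the smallest sizes at which the
qualitative conclusions are stable: morphometry recovery on 50 phantoms
(384 x 320 px); the modality ablation on a 500-eye cohort at 64 x 64
input and 20 epochs with 3 seeds; degenerate-identity recovery on 200
eyes at 40 epochs. Expected behaviour at these sizes: thickness-type
index MAE of a few um, pit-diameter MAE well under two lateral pixels,
slope MAE well under one degree; ablation medians ordered V < IV < I.

## Known limitations

- The phantom retina has exactly two boundaries; multi-layer anatomy,
  intraretinal fluid and pathology other than pit-shape deformation are
  out of scope, so the segmenter's behaviour on such scans is untested.
- Phantom texture is not scanner-realistic; results bound algorithmic,
  not clinical, error.
- The backbone is far smaller than a standard ImageNet-scale CNN;
  with clinical data and GPUs one would swap in a deeper backbone
  (the module boundary supports this) and enable pretrained weights.
- Pit depth uses the mean-rim reference and slopes are measured on the
  thickness profile; other conventions exist and differ slightly on
  asymmetric pits.
- The DeLong comparison assumes paired scores on identical eyes and
  two-class outcomes; single-class samples are rejected, not imputed.
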
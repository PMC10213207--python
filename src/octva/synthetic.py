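"""Synthetic OCT phantoms and simulated surgical cohorts.

Every downstream stage of the package — segmentation, foveal
morphometry, fusion-model training, evaluation — is testable against
these phantoms because their morphology is known in closed form.

A phantom B-scan contains, per column, a dark vitreous background, a
thin bright ILM line, a moderately bright retinal interior, and a bright
RPE band. The retinal thickness profile follows a raised-cosine foveal
pit: on each side of the pit center, over a halfwidth ``w``,

    T(d) = T_center + (T_rim - T_center) * (1 - cos(pi * d / w)) / 2,

where ``d`` is the lateral distance (px) from the center. The
raised-cosine wall has zero slope at the center and at the rim (so rims
and center are genuine zero-slope extrema) and its maximum slope,
``pi * (T_rim - T_center) / (2 w)`` um per lateral px, occurs exactly at
``d = w/2`` — all five foveal marks and all seven indices therefore have
closed-form ground truth. Beyond each rim the retina thins toward the
periphery along a log-cosh curve whose slope rises from zero at the rim
(so the rim stays a genuine zero-slope peak) and saturates at a fixed
fraction of that side's wall slope (so the wall stays the steepest
point), emulating normal parafoveal-to-peripheral thinning.

Simulated cohorts pair each eye's preoperative acuity (truncated-normal
logMAR) with two phantoms (horizontal/vertical meridians) whose geometry
is drawn from configurable index distributions, and generate the
postoperative acuity from a known linear model of preoperative acuity
and central foveal thickness plus residual noise — so fusion models can
be trained and scored against a recoverable ground-truth mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf
from scipy.stats import truncnorm

from .boundary import BoundaryCurve
from .devices import calibration_for_device
from .errors import ValidationError
from .fovea import FoveaMarks, MacularIndices
from .io import BScanImage, CohortRecord

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "analytic_thickness_um",
    "analytic_truth",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
    "BCVA_RANGE",
]

#: plausible logMAR range; acuity draws and generated outcomes are clamped to it
BCVA_RANGE = (-0.3, 2.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise parameters of one phantom B-scan.

    Thicknesses are in um; column quantities in px. ``tilt`` is the
    px-per-column drift of the ILM baseline about the frame's middle
    column. ``noise_sd`` is additive Gaussian noise in grayscale units;
    ``speckle`` toggles an extra multiplicative log-normal factor.
    """

    rows: int = 320
    cols: int = 384
    device_id: str = "spectralis"
    ilm_baseline_row: float = 80.0
    tilt: float = 0.0
    rim_thickness_t: float = 350.0
    rim_thickness_n: float = 350.0
    center_thickness: float = 220.0
    pit_center_col: float = 192.0
    pit_halfwidth_t: float = 60.0
    pit_halfwidth_n: float = 60.0
    rpe_band_width: float = 5.0
    noise_sd: float = 6.0
    seed: int = 0
    speckle: bool = False
    speckle_sigma: float = 0.15
    inner_band_amplitude: float = 0.0  # faint intermediate layer, for robustness tests
    outer_slope_frac: float = 0.35  # peripheral thinning slope / wall slope
    outer_scale_px: float = 12.0  # lateral scale of the log-cosh decline

    def __post_init__(self):
        for name in ("rows", "cols"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in (
            "pit_halfwidth_t",
            "pit_halfwidth_n",
            "rpe_band_width",
            "center_thickness",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not (
            self.rim_thickness_t >= self.center_thickness
            and self.rim_thickness_n >= self.center_thickness
        ):
            raise ValidationError(
                "rim_thickness_t/rim_thickness_n must be >= center_thickness"
            )
        t_rim = self.pit_center_col - self.pit_halfwidth_t
        n_rim = self.pit_center_col + self.pit_halfwidth_n
        if not (2 <= t_rim and n_rim <= self.cols - 3):
            raise ValidationError(
                "pit_center_col/pit_halfwidth place a rim outside the frame"
            )


@dataclass
class PhantomTruth:
    """Closed-form ground truth for one phantom (never produced by segmentation)."""

    ilm_true: BoundaryCurve
    rpe_true: BoundaryCurve
    marks_true: FoveaMarks
    indices_true: MacularIndices


def analytic_thickness_um(spec: PhantomSpec, cols: np.ndarray | None = None) -> np.ndarray:
    """Closed-form retinal thickness (um) at the given columns."""
    if cols is None:
        cols = np.arange(spec.cols, dtype=float)
    x = np.asarray(cols, dtype=float)
    d = x - spec.pit_center_col
    out = np.empty_like(x)
    for side, (w, t_rim) in {
        -1: (spec.pit_halfwidth_t, spec.rim_thickness_t),
        +1: (spec.pit_halfwidth_n, spec.rim_thickness_n),
    }.items():
        sel = (d * side) >= 0
        a = np.abs(d[sel])
        inside = a <= w
        t = np.empty_like(a)
        t[inside] = spec.center_thickness + (t_rim - spec.center_thickness) * (
            1.0 - np.cos(np.pi * a[inside] / max(w, 1e-9))
        ) / 2.0
        # peripheral thinning: slope 0 at the rim, saturating at a fraction
        # of this side's wall slope so the wall remains the steepest point
        wall_slope = np.pi * (t_rim - spec.center_thickness) / (2.0 * max(w, 1e-9))
        s_max = spec.outer_slope_frac * wall_slope
        L = max(spec.outer_scale_px, 1e-9)
        t[~inside] = t_rim - s_max * L * np.log(np.cosh((a[~inside] - w) / L))
        out[sel] = t
    return np.clip(out, 0.0, None)


def _ilm_rows(spec: PhantomSpec) -> np.ndarray:
    x = np.arange(spec.cols, dtype=float)
    return spec.ilm_baseline_row + spec.tilt * (x - (spec.cols - 1) / 2.0)


def analytic_truth(spec: PhantomSpec) -> PhantomTruth:
    """Ground-truth boundaries, marks and indices, all in closed form."""
    cal = calibration_for_device(spec.device_id, cols=spec.cols, rows=spec.rows)
    thickness = analytic_thickness_um(spec)
    ilm = _ilm_rows(spec)
    rpe = ilm + thickness / cal.axial_um_per_px
    all_valid = np.ones(spec.cols, dtype=bool)

    c = spec.pit_center_col
    wt, wn = spec.pit_halfwidth_t, spec.pit_halfwidth_n
    marks = FoveaMarks(
        temporal_rim_col=c - wt,
        temporal_wall_col=c - wt / 2.0,
        center_col=c,
        nasal_wall_col=c + wn / 2.0,
        nasal_rim_col=c + wn,
    )
    # max raised-cosine slope: pi * (T_rim - T_center) / (2 w)  [um per px]
    ts = np.pi * (spec.rim_thickness_t - spec.center_thickness) / (2.0 * wt)
    ns = np.pi * (spec.rim_thickness_n - spec.center_thickness) / (2.0 * wn)
    indices = MacularIndices(
        foveal_thickness_um=spec.center_thickness,
        pit_depth_um=(spec.rim_thickness_t + spec.rim_thickness_n) / 2.0
        - spec.center_thickness,
        pit_diameter_um=(wt + wn) * cal.lateral_um_per_px,
        temporal_max_thickness_um=spec.rim_thickness_t,
        nasal_max_thickness_um=spec.rim_thickness_n,
        temporal_slope_deg=float(np.degrees(np.arctan(ts / cal.lateral_um_per_px))),
        nasal_slope_deg=float(np.degrees(np.arctan(ns / cal.lateral_um_per_px))),
    )
    return PhantomTruth(
        ilm_true=BoundaryCurve(ilm, all_valid),
        rpe_true=BoundaryCurve(rpe, all_valid),
        marks_true=marks,
        indices_true=indices,
    )


# rendering contrasts (grayscale units)
_BG = 12.0
_INTERIOR = 55.0
_ILM_AMP = 170.0
_RPE_AMP = 205.0
_EDGE_SIGMA = 0.9


def _soft_box(r: np.ndarray, top: np.ndarray, bottom: np.ndarray, sigma: float) -> np.ndarray:
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((r - top) / s) - erf((r - bottom) / s))


def generate_phantom(
    spec: PhantomSpec, orientation: str = "horizontal"
) -> tuple[BScanImage, PhantomTruth]:
    """Render a phantom B-scan and return it with its closed-form truth.

    Rendering is fully analytic (erf-profiled bands, Gaussian membrane
    line), and with the same seed the image is bit-identical across
    calls; the additive/speckle noise is the only stochastic element.
    """
    truth = analytic_truth(spec)
    rows = np.arange(spec.rows, dtype=float)[:, None]
    ilm = truth.ilm_true.row_at_col[None, :]
    rpe = truth.rpe_true.row_at_col[None, :]
    if np.any(rpe >= spec.rows - 2):
        raise ValidationError(
            "rpe rows exceed frame: increase rows or reduce ilm_baseline_row/thickness"
        )

    img = np.full((spec.rows, spec.cols), _BG)
    # interior starts a little below the membrane line so the line's local
    # neighbourhood is symmetric (keeps its intensity peak at the true row)
    img += _INTERIOR * _soft_box(rows, ilm + 2.5, rpe - spec.rpe_band_width / 2.0, 1.2)
    img += _ILM_AMP * np.exp(-((rows - ilm) ** 2) / (2.0 * _EDGE_SIGMA**2))
    img += _RPE_AMP * _soft_box(
        rows, rpe - spec.rpe_band_width / 2.0, rpe + spec.rpe_band_width / 2.0, _EDGE_SIGMA
    )
    if spec.inner_band_amplitude > 0:
        mid = (ilm + rpe) / 2.0
        img += spec.inner_band_amplitude * np.exp(
            -((rows - mid) ** 2) / (2.0 * _EDGE_SIGMA**2)
        )

    rng = np.random.default_rng(spec.seed)
    if spec.speckle:
        img = img * rng.lognormal(mean=0.0, sigma=spec.speckle_sigma, size=img.shape)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return (
        BScanImage(pixels=img, device_id=spec.device_id, orientation=orientation),
        truth,
    )


def _truncnorm_rvs(rng, mean, sd, lo, hi, size=None):
    if sd <= 0:
        return np.full(size, float(np.clip(mean, lo, hi))) if size else float(
            np.clip(mean, lo, hi)
        )
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated surgical cohort.

    The generating outcome model is

        postop = intercept + coeff_preop * preop
                 + coeff_thickness * (foveal_thickness - reference) / scale
                 + N(0, residual_sd),

    clamped to the plausible logMAR range. Defaults reproduce a cohort
    whose preoperative acuity is 0.66 +/- 0.52 logMAR and postoperative
    acuity is about 0.17 +/- 0.32 logMAR, with foveal-thickness spread on
    the scale observed in macular morphometry of surgical cataract
    populations.

    ``index_distributions`` maps each sampled geometric quantity to
    (mean, sd, lo, hi) of a truncated normal: ``center_thickness`` (um),
    ``rim_excess`` (um above the center, drawn per side), and
    ``pit_halfwidth_um`` (drawn per side).
    """

    n_eyes: int = 200
    preop_mean: float = 0.66
    preop_sd: float = 0.52
    residual_sd: float = 0.10
    coeff_preop: float = 0.50
    coeff_thickness: float = 0.30
    intercept: float = -0.16
    thickness_reference: float = 277.4
    thickness_scale: float = 310.32
    index_distributions: dict = field(
        default_factory=lambda: {
            "center_thickness": (277.4, 150.0, 120.0, 700.0),
            "rim_excess": (92.0, 40.0, 25.0, 250.0),
            "pit_halfwidth_um": (1100.0, 350.0, 450.0, 2000.0),
        }
    )
    device_id: str = "spectralis"
    phantom_rows: int = 192
    phantom_cols: int = 256
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_eyes <= 0:
            raise ValidationError("n_eyes must be positive")
        for name in ("preop_sd", "residual_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Simulate a cohort of eyes with paired phantoms and known outcomes.

    Each returned record carries the preoperative/true postoperative
    acuity; its ``extras`` dict holds the in-memory horizontal and
    vertical phantoms (``himg``/``vimg``), the horizontal phantom's
    closed-form truth (``truth``), and the generator's linear predictor
    before noise (``postop_linear``). ``indices`` is left unset — filling
    it is the morphometry pipeline's job.
    """
    rng = np.random.default_rng(spec.seed)
    cal = calibration_for_device(
        spec.device_id, cols=spec.phantom_cols, rows=spec.phantom_rows
    )
    dist = spec.index_distributions
    lo, hi = BCVA_RANGE

    records = []
    for i in range(spec.n_eyes):
        preop = float(_truncnorm_rvs(rng, spec.preop_mean, spec.preop_sd, lo, hi))
        center = float(_truncnorm_rvs(rng, *dist["center_thickness"]))
        geom = {}
        for key in ("h", "v"):
            rims = _truncnorm_rvs(rng, *dist["rim_excess"], size=2)
            widths_um = _truncnorm_rvs(rng, *dist["pit_halfwidth_um"], size=2)
            geom[key] = (rims, widths_um / cal.lateral_um_per_px)
        max_thick_px = (center + max(geom["h"][0].max(), geom["v"][0].max())) / (
            cal.axial_um_per_px
        )
        baseline = float(
            rng.uniform(30.0, max(31.0, spec.phantom_rows - max_thick_px - 18.0))
        )
        jitter = float(rng.uniform(-8.0, 8.0))
        tilt = float(rng.normal(0.0, 0.05))

        def _spec(key, seed):
            rims, widths = geom[key]
            half = spec.phantom_cols / 2.0
            return PhantomSpec(
                rows=spec.phantom_rows,
                cols=spec.phantom_cols,
                device_id=spec.device_id,
                ilm_baseline_row=baseline,
                tilt=tilt,
                rim_thickness_t=center + rims[0],
                rim_thickness_n=center + rims[1],
                center_thickness=center,
                pit_center_col=float(
                    np.clip(half + jitter, widths[0] + 3, spec.phantom_cols - widths[1] - 4)
                ),
                pit_halfwidth_t=float(widths[0]),
                pit_halfwidth_n=float(widths[1]),
                noise_sd=spec.noise_sd,
                seed=seed,
            )

        seed_h, seed_v = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
        himg, truth = generate_phantom(_spec("h", seed_h), orientation="horizontal")
        vimg, _ = generate_phantom(_spec("v", seed_v), orientation="vertical")

        linear = (
            spec.intercept
            + spec.coeff_preop * preop
            + spec.coeff_thickness
            * (center - spec.thickness_reference)
            / spec.thickness_scale
        )
        postop = linear + (rng.normal(0.0, spec.residual_sd) if spec.residual_sd else 0.0)
        postop = float(np.clip(postop, lo, hi))

        records.append(
            CohortRecord(
                eye_id=f"eye{i:05d}",
                device_id=spec.device_id,
                preop_bcva=preop,
                postop_bcva=postop,
                extras={
                    "himg": himg,
                    "vimg": vimg,
                    "truth": truth,
                    "postop_linear": float(linear),
                },
            )
        )
    return records


def write_cohort(records: list[CohortRecord], outdir: str) -> str:
    """Write phantom PNGs and the cohort CSV; returns the CSV path."""
    import os

    from .io import save_cohort_table, save_image

    imgdir = os.path.join(outdir, "images")
    os.makedirs(imgdir, exist_ok=True)
    out = []
    for r in records:
        rec = CohortRecord(
            eye_id=r.eye_id,
            device_id=r.device_id,
            preop_bcva=r.preop_bcva,
            postop_bcva=r.postop_bcva,
            himg_path=os.path.join(imgdir, f"{r.eye_id}_h.png"),
            vimg_path=os.path.join(imgdir, f"{r.eye_id}_v.png"),
            indices=r.indices,
        )
        save_image(r.extras["himg"], rec.himg_path)
        save_image(r.extras["vimg"], rec.vimg_path)
        out.append(rec)
    csv_path = os.path.join(outdir, "cohort.csv")
    save_cohort_table(out, csv_path)
    return csv_path
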
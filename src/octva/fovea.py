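"""Foveal landmark detection and the seven macular morphological indices.

The foveal pit is parameterized by five marks on the retinal thickness
profile along the horizontal meridian: the temporal rim peak, the point
of maximum slope on the temporal wall, the pit center, the maximum-slope
point on the nasal wall, and the nasal rim peak. Rims and center are
zero-slope extrema; walls are the steepest points between them.

From the five marks, seven indices are computed:

- foveal thickness (um): thickness at the pit center
- pit depth (um): mean of the two rim thicknesses minus foveal thickness
- pit diameter (um): lateral rim-to-rim distance
- temporal / nasal max thickness (um): thickness at each rim peak
- temporal / nasal foveal slope (deg): arctangent of the maximum
  um-per-um thickness gradient on each wall

Pit depth uses the mean-rim reference and slopes are measured on the
thickness profile (not the inner surface); both conventions follow the
common foveal-morphometry literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary import ThicknessProfile
from .devices import DeviceCalibration
from .errors import NoPitDetected, SegmentationError, ValidationError
from .io import BScanImage

__all__ = [
    "FoveaMarks",
    "MacularIndices",
    "INDEX_NAMES",
    "locate_marks",
    "compute_indices",
    "extract_indices_pipeline",
]

#: Column names used in index CSVs, in canonical order.
INDEX_NAMES = (
    "foveal_thickness_um",
    "pit_depth_um",
    "pit_diameter_um",
    "temporal_max_thickness_um",
    "nasal_max_thickness_um",
    "temporal_slope_deg",
    "nasal_slope_deg",
)

#: |dT/dx| below this (um thickness per um lateral) counts as "zero slope".
ZERO_SLOPE_TOL = 0.02


@dataclass
class FoveaMarks:
    """Subpixel column positions of the five foveal landmarks."""

    temporal_rim_col: float
    temporal_wall_col: float
    center_col: float
    nasal_wall_col: float
    nasal_rim_col: float
    fallback: bool = False  # True when set by the no-pit fallback rule

    def __post_init__(self):
        cols = self.as_tuple()
        if not self.fallback and not all(a < b for a, b in zip(cols, cols[1:])):
            raise ValidationError(f"fovea marks must be strictly ordered, got {cols}")

    def as_tuple(self):
        return (
            self.temporal_rim_col,
            self.temporal_wall_col,
            self.center_col,
            self.nasal_wall_col,
            self.nasal_rim_col,
        )


@dataclass
class MacularIndices:
    """The seven macular morphological indices."""

    foveal_thickness_um: float
    pit_depth_um: float
    pit_diameter_um: float
    temporal_max_thickness_um: float
    nasal_max_thickness_um: float
    temporal_slope_deg: float
    nasal_slope_deg: float
    qc: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in INDEX_NAMES], dtype=float)

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValidationError("all indices must be finite")
        if self.pit_diameter_um < 0:
            raise ValidationError("pit diameter must be non-negative")
        for s in (self.temporal_slope_deg, self.nasal_slope_deg):
            if not (-90.0 < s < 90.0):
                raise ValidationError("slopes must lie in (-90, 90) degrees")


def _snap_extremum(y: np.ndarray, i0: int, radius: int, find_max: bool) -> float:
    """Re-localize an extremum found on a heavily smoothed curve.

    Heavy smoothing can drag a peak toward its flatter flank; snapping to
    the extremum of the lightly smoothed curve within ``radius`` removes
    that systematic shift while keeping the heavy smooth's robustness.
    """
    lo = max(1, i0 - radius)
    hi = min(y.size - 1, i0 + radius + 1)
    seg = y[lo:hi]
    j = lo + int(np.argmax(seg) if find_max else np.argmin(seg))
    return _parabolic_refine(y, j)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Subpixel extremum position via a 3-point parabola around index i."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-12:
        return float(i)
    return float(i + np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -1.0, 1.0))


#: lateral extent (um) of the heavy Savitzky-Golay window used for mark location
MARK_SMOOTH_UM = 500.0
#: lighter window (um) used to localize the rim's zero-slope crossing
RIM_SMOOTH_UM = 180.0


def _savgol(t: np.ndarray, window: int) -> np.ndarray:
    from scipy.signal import savgol_filter

    window = max(5, min(window, max(5, t.size // 4)))
    if window % 2 == 0:
        window += 1
    return savgol_filter(t, window_length=window, polyorder=3, mode="interp")


def _smoothed_profile(profile: ThicknessProfile) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay-smoothed thickness and its um/um slope.

    Mark location needs a heavier smooth than boundary tracing: rims and
    center are broad zero-slope extrema, so residual boundary noise
    creates spurious local extrema on the walls. A cubic Savitzky-Golay
    fit over ~500 um suppresses those while preserving the positions (and
    most of the amplitude) of the genuine extrema and wall slopes.
    """
    t = profile.thickness_um
    dx = float(np.median(np.diff(profile.lateral_pos_um)))
    t_s = _savgol(t, int(round(MARK_SMOOTH_UM / dx)))
    slope = np.gradient(t_s, profile.lateral_pos_um)
    return t_s, slope


def _fallback_marks(profile: ThicknessProfile, central_frac: float) -> FoveaMarks:
    """Marks for pitless (flat/dome-shaped, e.g. edematous) profiles.

    Center is the minimum-thickness column in the central window; rims are
    the thickness maxima outside it on each side. Pit depth downstream may
    then be near zero or negative and is reported unclamped with a QC flag.
    """
    t = profile.thickness_um
    n = t.size
    lo, hi = int(n * (0.5 - central_frac / 2)), int(n * (0.5 + central_frac / 2))
    center = lo + int(np.argmin(t[lo:hi]))
    center = max(2, min(n - 3, center))
    left = t[:center]
    right = t[center + 1 :]
    t_rim = int(np.argmax(left)) if left.size else 0
    n_rim = center + 1 + (int(np.argmax(right)) if right.size else 0)
    t_rim = min(t_rim, center - 2) if center >= 2 else 0
    n_rim = max(n_rim, center + 2)
    n_rim = min(n_rim, n - 1)
    return FoveaMarks(
        temporal_rim_col=float(t_rim),
        temporal_wall_col=(t_rim + center) / 2.0,
        center_col=float(center),
        nasal_wall_col=(center + n_rim) / 2.0,
        nasal_rim_col=float(n_rim),
        fallback=True,
    )


def locate_marks(profile: ThicknessProfile, central_frac: float = 0.5) -> FoveaMarks:
    """Find the five foveal marks on a smoothed thickness profile.

    The pit center is the zero-slope local thickness minimum nearest the
    frame center (searched within the central ``central_frac`` of columns);
    the rims are the first zero-slope peaks walking outward from the
    center; the walls are the maximum-|slope| columns strictly between
    center and each rim.

    Raises
    ------
    NoPitDetected
        If no local minimum exists in the central window. The exception
        carries fallback marks (minimum-thickness column rule) so callers
        may still index edematous maculae, flagged in QC.
    """
    n = profile.cols
    if n < 15:
        raise ValidationError("profile too short to locate foveal marks")
    t, slope = _smoothed_profile(profile)

    lo = int(n * (0.5 - central_frac / 2))
    hi = int(n * (0.5 + central_frac / 2))
    interior = np.arange(1, n - 1)
    is_min = (t[interior] <= t[interior - 1]) & (t[interior] <= t[interior + 1])
    near_zero = np.abs(slope[interior]) < ZERO_SLOPE_TOL * 5  # sampled minima rarely hit 0
    cand = interior[is_min & near_zero]
    cand = cand[(cand >= lo) & (cand < hi)]
    # require a genuine depression: strictly lower than both flanks
    cand = np.array(
        [c for c in cand if t[c] < t[max(0, c - 5)] and t[c] < t[min(n - 1, c + 5)]],
        dtype=int,
    )
    if cand.size == 0:
        raise NoPitDetected(
            "no zero-slope thickness minimum in the central window",
            fallback=_fallback_marks(profile, central_frac),
        )
    center_i = int(cand[np.argmin(np.abs(cand - (n - 1) / 2))])

    # walls: steepest point of the correct sign on each side of the center
    # (thickness falls toward the center, so slope is negative temporally
    # and positive nasally)
    t_side = slope[3 : center_i - 1]
    n_side = slope[center_i + 2 : n - 3]
    if t_side.size == 0 or n_side.size == 0 or t_side.min() >= 0 or n_side.max() <= 0:
        raise NoPitDetected(
            "no wall of the expected slope sign on one or both sides",
            fallback=_fallback_marks(profile, central_frac),
        )
    t_wall_i = 3 + int(np.argmin(t_side))
    n_wall_i = center_i + 2 + int(np.argmax(n_side))

    # rims: walking outward from each wall, the first zero crossing of the
    # (lightly smoothed) slope — the first zero-slope peak outside the wall.
    # The crossing is then refined by extrapolating a straight-line fit of
    # the inner slope branch to zero, which is well-conditioned because the
    # slope changes steeply inside the pit and barely at all outside it.
    dx = float(np.median(np.diff(profile.lateral_pos_um)))
    t_m = _savgol(profile.thickness_um, int(round(RIM_SMOOTH_UM / dx)))
    slope_m = np.gradient(t_m, profile.lateral_pos_um)

    def _rim(wall_i: int, outward: int) -> float | None:
        wall_slope = abs(slope[wall_i])
        i = wall_i
        while 1 <= i + outward <= n - 2:
            j = i + outward
            if (
                slope_m[i] * slope_m[j] <= 0
                and slope_m[i] != slope_m[j]
                # localized boundary glitches can dip the light slope through
                # zero mid-wall; a genuine rim is flat on the heavy smooth too
                and abs(slope[j]) < 0.3 * wall_slope
            ):
                cross = i + outward * abs(slope_m[i]) / abs(slope_m[i] - slope_m[j])
                r0 = int(round(cross))
                # inner-branch columns, 2..10 px toward the wall from the rim
                xs = r0 - outward * np.arange(2, 11)
                xs = xs[(xs >= 0) & (xs <= n - 1)]
                if outward > 0:
                    xs = xs[xs > wall_i]
                else:
                    xs = xs[xs < wall_i]
                if xs.size >= 4:
                    coef = np.polyfit(xs.astype(float), slope_m[xs], 1)
                    if abs(coef[0]) > 1e-9:
                        root = -coef[1] / coef[0]
                        if abs(root - cross) <= 6.0:
                            return float(np.clip(root, 1.0, n - 2.0))
                return float(cross)
            i = j
        return None

    t_rim = _rim(t_wall_i, -1)
    n_rim = _rim(n_wall_i, +1)
    if t_rim is None or n_rim is None:
        raise NoPitDetected(
            "no zero-slope rim peak on one or both sides of the pit center",
            fallback=_fallback_marks(profile, central_frac),
        )

    abs_slope = np.abs(slope)
    t_raw = profile.thickness_um  # already lightly smoothed by boundary tracing
    return FoveaMarks(
        temporal_rim_col=t_rim,
        temporal_wall_col=_parabolic_refine(abs_slope, t_wall_i),
        center_col=_snap_extremum(t_raw, center_i, 4, find_max=False),
        nasal_wall_col=_parabolic_refine(abs_slope, n_wall_i),
        nasal_rim_col=n_rim,
    )


def _interp_at(profile: ThicknessProfile, col: float) -> float:
    cols = np.arange(profile.cols, dtype=float)
    return float(np.interp(col, cols, profile.thickness_um))


def compute_indices(
    marks: FoveaMarks, profile: ThicknessProfile, cal: DeviceCalibration
) -> MacularIndices:
    """Compute the seven indices from the five marks and the profile."""
    n = profile.cols
    for c in marks.as_tuple():
        if not (0 <= c <= n - 1):
            raise ValidationError(f"mark column {c} outside profile range [0, {n - 1}]")
    ft = _interp_at(profile, marks.center_col)
    tmax = _interp_at(profile, marks.temporal_rim_col)
    nmax = _interp_at(profile, marks.nasal_rim_col)
    # wall slopes are read on the smoothed profile: |slope| of a noisy
    # gradient is biased upward, and the wall maximum amplifies that
    _, slope = _smoothed_profile(profile)
    cols = np.arange(n, dtype=float)
    ts = float(np.interp(marks.temporal_wall_col, cols, np.abs(slope)))
    ns = float(np.interp(marks.nasal_wall_col, cols, np.abs(slope)))
    return MacularIndices(
        foveal_thickness_um=ft,
        pit_depth_um=(tmax + nmax) / 2.0 - ft,
        pit_diameter_um=(marks.nasal_rim_col - marks.temporal_rim_col)
        * cal.lateral_um_per_px,
        temporal_max_thickness_um=tmax,
        nasal_max_thickness_um=nmax,
        temporal_slope_deg=float(np.degrees(np.arctan(ts))),
        nasal_slope_deg=float(np.degrees(np.arctan(ns))),
        qc={"fallback_marks": marks.fallback},
    )


def extract_indices_pipeline(
    img_h: BScanImage,
    cal: DeviceCalibration | None = None,
    allow_fallback: bool = True,
) -> MacularIndices:
    """Full morphometry pipeline on a horizontal B-scan.

    Runs denoise -> connect/edge -> ILM probe -> flatten -> RPE probe ->
    thickness profile -> mark location -> index computation, and attaches
    QC metadata (noise estimate, valid-column fractions, fallback flag).
    Stage failures are re-raised with the stage name attached.
    """
    from . import segmentation as seg

    if cal is None:
        cal = img_h.calibration

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except SegmentationError as exc:
            raise SegmentationError(f"stage {name!r}: {exc}", stage=name) from exc

    den = _stage("denoise", seg.denoise_bscan, img_h)
    noise_est = float(np.median(np.abs(img_h.pixels - den.pixels)))
    edges = _stage("edge", seg.connect_and_edge, den)
    ilm = _stage("ilm", seg.detect_ilm, edges, den)
    flat, shifts = _stage("flatten", seg.flatten_to_ilm, den, ilm)
    flat_ilm_row = float(np.median(ilm.row_at_col + shifts))
    # shifts passed so the curve comes back in original (unflattened) frame
    rpe = _stage("rpe", seg.detect_rpe, flat, flat_ilm_row, cal, shifts=shifts)
    profile = _stage("thickness", seg.thickness_profile, ilm, rpe, cal)
    try:
        marks = locate_marks(profile)
    except NoPitDetected as exc:
        if not allow_fallback or exc.fallback is None:
            raise
        marks = exc.fallback
    indices = compute_indices(marks, profile, cal)
    indices.qc.update(
        noise_estimate=noise_est,
        ilm_valid_fraction=ilm.valid_fraction,
        rpe_valid_fraction=rpe.valid_fraction,
        n_negative_thickness=profile.n_clipped_negative,
    )
    return indices
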
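"""Foveal mark location and the seven indices."""

import numpy as np
import pytest

from octva import PhantomSpec, generate_phantom
from octva.boundary import ThicknessProfile
from octva.devices import calibration_for_device
from octva.errors import NoPitDetected, SegmentationError, ValidationError
from octva.fovea import (
    FoveaMarks,
    compute_indices,
    extract_indices_pipeline,
    locate_marks,
)
from octva.io import BScanImage
from octva.synthetic import analytic_thickness_um


def _profile_from_spec(spec: PhantomSpec) -> ThicknessProfile:
    cal = calibration_for_device(spec.device_id, cols=spec.cols, rows=spec.rows)
    t = analytic_thickness_um(spec)
    return ThicknessProfile(
        thickness_um=t, lateral_pos_um=np.arange(spec.cols) * cal.lateral_um_per_px,
        calibration=cal,
    )


def test_marks_ordering_enforced():
    with pytest.raises(ValidationError):
        FoveaMarks(10, 5, 20, 30, 40)


def test_symmetric_pit_marks_within_two_px():
    spec = PhantomSpec(noise_sd=0.0)
    prof = _profile_from_spec(spec)
    marks = locate_marks(prof)
    truth = (132.0, 162.0, 192.0, 222.0, 252.0)
    for got, want in zip(marks.as_tuple(), truth):
        assert got == pytest.approx(want, abs=2.0)


def test_symmetric_profile_center_equidistant_from_rims():
    marks = locate_marks(_profile_from_spec(PhantomSpec(noise_sd=0.0)))
    d_t = marks.center_col - marks.temporal_rim_col
    d_n = marks.nasal_rim_col - marks.center_col
    assert d_t == pytest.approx(d_n, abs=2.0)


def test_flat_profile_raises_no_pit():
    cal = calibration_for_device("spectralis", cols=200, rows=200)
    prof = ThicknessProfile(
        thickness_um=np.full(200, 300.0),
        lateral_pos_um=np.arange(200) * cal.lateral_um_per_px,
        calibration=cal,
    )
    with pytest.raises(NoPitDetected):
        locate_marks(prof)


def test_monotone_profile_raises_no_pit():
    cal = calibration_for_device("spectralis", cols=200, rows=200)
    prof = ThicknessProfile(
        thickness_um=np.linspace(250, 400, 200),
        lateral_pos_um=np.arange(200) * cal.lateral_um_per_px,
        calibration=cal,
    )
    with pytest.raises(NoPitDetected):
        locate_marks(prof)


def test_dome_profile_fallback_marks_center_at_minimum():
    """Edematous (dome) maculae still get fallback marks with a QC flag."""
    cal = calibration_for_device("spectralis", cols=300, rows=200)
    x = np.arange(300)
    dome = 350.0 + 150.0 * np.exp(-((x - 150) ** 2) / (2 * 60.0**2))
    prof = ThicknessProfile(
        thickness_um=dome, lateral_pos_um=x * cal.lateral_um_per_px, calibration=cal
    )
    with pytest.raises(NoPitDetected) as exc:
        locate_marks(prof)
    fb = exc.value.fallback
    assert fb is not None and fb.fallback
    # fallback center = minimum-thickness column of the central window
    lo, hi = 75, 225
    assert fb.center_col == pytest.approx(lo + np.argmin(dome[lo:hi]), abs=1.0)
    idx = compute_indices(fb, prof, cal)
    assert idx.qc["fallback_marks"]
    # no pit: the "depth" is far below a genuine pit's scale, unclamped
    assert idx.pit_depth_um < 60.0


def test_indices_from_marks_printed_calibration():
    """Diameter uses the lateral scale: 300 cols on a native spectralis
    frame span 300 * 10000/768 = 3906 um."""
    cal = calibration_for_device("spectralis")
    n = 768
    x = np.arange(n, dtype=float)
    t = np.full(n, 350.0)
    c, w = 350.0, 150.0
    d = np.abs(x - c)
    inside = d <= w
    t[inside] = 220.0 + 130.0 * (1 - np.cos(np.pi * d[inside] / w)) / 2
    prof = ThicknessProfile(
        thickness_um=t, lateral_pos_um=x * cal.lateral_um_per_px, calibration=cal
    )
    marks = FoveaMarks(200.0, 275.0, 350.0, 425.0, 500.0)
    idx = compute_indices(marks, prof, cal)
    assert idx.foveal_thickness_um == pytest.approx(220.0, abs=1.0)
    assert idx.pit_depth_um == pytest.approx(130.0, abs=1.0)
    assert idx.pit_diameter_um == pytest.approx(300 * 10000 / 768, abs=1.0)


def test_slope_matches_brute_force_gradient_maximum():
    """Reported wall slope equals atan(max um/um gradient) of the profile."""
    spec = PhantomSpec(noise_sd=0.0, pit_halfwidth_t=50.0, pit_halfwidth_n=80.0)
    prof = _profile_from_spec(spec)
    marks = locate_marks(prof)
    idx = compute_indices(marks, prof, prof.calibration)
    grad = np.gradient(prof.thickness_um, prof.lateral_pos_um)
    c = int(round(marks.center_col))
    g_t = np.abs(grad[:c]).max()
    g_n = np.abs(grad[c:]).max()
    assert idx.temporal_slope_deg == pytest.approx(np.degrees(np.arctan(g_t)), abs=0.5)
    assert idx.nasal_slope_deg == pytest.approx(np.degrees(np.arctan(g_n)), abs=0.5)


def test_marks_out_of_range_rejected():
    spec = PhantomSpec(noise_sd=0.0)
    prof = _profile_from_spec(spec)
    with pytest.raises(ValidationError):
        compute_indices(FoveaMarks(100, 200, 300, 350, 1000), prof, prof.calibration)


def test_scale_equivariance_of_diameter_and_slopes():
    """Halving the column count doubles um/px: diameter is unchanged in um,
    slopes follow the arctan relation, thicknesses are untouched."""
    spec_hi = PhantomSpec(noise_sd=0.0, cols=384, pit_center_col=192.0)
    spec_lo = PhantomSpec(
        noise_sd=0.0, cols=192, pit_center_col=96.0,
        pit_halfwidth_t=30.0, pit_halfwidth_n=30.0,
    )
    from octva.synthetic import analytic_truth

    hi = analytic_truth(spec_hi).indices_true
    lo = analytic_truth(spec_lo).indices_true
    assert lo.pit_diameter_um == pytest.approx(hi.pit_diameter_um, rel=1e-6)
    assert lo.foveal_thickness_um == hi.foveal_thickness_um
    # halfwidth halves in px but um/px doubles: same physical wall slope
    assert lo.temporal_slope_deg == pytest.approx(hi.temporal_slope_deg, rel=1e-6)


# ---- full pipeline -----------------------------------------------------


def test_pipeline_deterministic(noisy_phantom):
    _, img, _ = noisy_phantom
    a = extract_indices_pipeline(img).as_array()
    b = extract_indices_pipeline(img).as_array()
    np.testing.assert_array_equal(a, b)


def test_pipeline_blank_image_reports_stage():
    img = BScanImage(pixels=np.zeros((64, 64)), device_id="spectralis")
    with pytest.raises(SegmentationError) as exc, pytest.warns(UserWarning):
        extract_indices_pipeline(img)
    assert exc.value.stage == "ilm"


def test_pipeline_recovers_indices_on_phantom(noisy_phantom):
    _, img, truth = noisy_phantom
    idx = extract_indices_pipeline(img)
    err = idx.as_array() - truth.indices_true.as_array()
    assert np.all(np.abs(err[[0, 1, 3, 4]]) <= 10.0)  # thickness-type, um
    assert abs(err[2]) <= 2.1 * img.calibration.lateral_um_per_px  # diameter
    assert np.all(np.abs(err[[5, 6]]) <= 2.0)  # slopes, deg


def test_flattening_invariance_of_indices():
    """Indices agree whether the scan arrives tilted or pre-flattened."""
    tilted_spec = PhantomSpec(noise_sd=3.0, tilt=0.06, seed=21)
    flat_spec = PhantomSpec(noise_sd=3.0, tilt=0.0, seed=21)
    idx_t = extract_indices_pipeline(generate_phantom(tilted_spec)[0]).as_array()
    idx_f = extract_indices_pipeline(generate_phantom(flat_spec)[0]).as_array()
    diff = np.abs(idx_t - idx_f)
    assert np.all(diff[[0, 1, 3, 4]] <= 2.0)  # um
    assert diff[2] <= 2.0 * 10000 / 384  # lateral px worth of um
    assert np.all(diff[[5, 6]] <= 0.5)  # deg


def test_pipeline_ordering_invariant_holds(tiny_cohort):
    for rec in tiny_cohort[:6]:
        idx = extract_indices_pipeline(rec.extras["himg"])
        assert np.all(np.isfinite(idx.as_array()))
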
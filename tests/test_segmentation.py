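"""Layer segmentation against phantom ground truth."""

import numpy as np
import pytest

from octva import PhantomSpec, generate_phantom
from octva import segmentation as seg
from octva.boundary import BoundaryCurve
from octva.errors import SegmentationError
from octva.io import BScanImage


def _img(arr):
    return BScanImage(pixels=np.asarray(arr, dtype=float), device_id="spectralis")


def run_segmentation(img):
    """denoise -> edge -> ILM -> flatten -> RPE, returning both curves
    (RPE mapped back to original coordinates)."""
    den = seg.denoise_bscan(img)
    edges = seg.connect_and_edge(den)
    ilm = seg.detect_ilm(edges, den)
    flat, shifts = seg.flatten_to_ilm(den, ilm)
    rpe = seg.detect_rpe(
        flat, float(np.median(ilm.row_at_col + shifts)), shifts=shifts
    )
    return ilm, rpe, shifts


# ---- denoise -----------------------------------------------------------


def test_denoise_constant_image_is_identity():
    img = _img(np.full((20, 30), 37.0))
    out = seg.denoise_bscan(img)
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_denoise_preserves_clean_phantom(clean_phantom):
    _, img, truth = clean_phantom
    out = seg.denoise_bscan(img)
    # away from the boundary bands the filter must change almost nothing
    mask = np.ones_like(img.pixels, dtype=bool)
    rows = np.arange(img.rows)[:, None]
    for curve in (truth.ilm_true, truth.rpe_true):
        mask &= np.abs(rows - curve.row_at_col[None, :]) > 6
    assert np.abs(out.pixels - img.pixels)[mask].mean() < 1.0


def test_denoise_restores_salt_and_pepper(clean_phantom):
    _, img, _ = clean_phantom
    rng = np.random.default_rng(0)
    corrupted = img.pixels.copy()
    hits = rng.random(corrupted.shape) < 0.01
    corrupted[hits] = rng.choice([0.0, 255.0], size=int(hits.sum()))
    out = seg.denoise_bscan(_img(corrupted))
    restored = np.abs(out.pixels - img.pixels)[hits] < 5.0
    assert restored.mean() >= 0.95


# ---- connect + edge ----------------------------------------------------


def test_edge_map_peaks_at_line_transitions():
    arr = np.full((30, 20), 5.0)
    arr[14:16, :] = 200.0
    emap = seg.connect_and_edge(_img(arr))
    peak_rows = np.argsort(emap[:, 10])[-4:]
    assert set(peak_rows) <= {12, 13, 14, 15, 16, 17}


def test_dilation_bridges_small_gap():
    arr = np.full((30, 40), 5.0)
    arr[15, :] = 200.0
    arr[15, 18:21] = 5.0  # 3-px gap
    emap = seg.connect_and_edge(_img(arr))
    band = emap[12:19, :]
    assert np.all(band.max(axis=0) > 0)  # no zero-response column across the gap


def test_edge_map_equivariant_under_180_rotation(noisy_phantom):
    _, img, _ = noisy_phantom
    emap = seg.connect_and_edge(img)
    emap_rot = seg.connect_and_edge(_img(img.pixels[::-1, ::-1]))
    np.testing.assert_allclose(emap_rot, emap[::-1, ::-1], atol=1e-9)


def test_all_zero_image_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        emap = seg.connect_and_edge(_img(np.zeros((10, 10))))
    assert not emap.any()


# ---- ILM ---------------------------------------------------------------


def test_ilm_on_flat_phantom_within_one_px():
    spec = PhantomSpec(noise_sd=4.0, tilt=0.0, ilm_baseline_row=100.0, seed=4)
    img, truth = generate_phantom(spec)
    den = seg.denoise_bscan(img)
    ilm = seg.detect_ilm(seg.connect_and_edge(den), den)
    assert np.all(np.abs(ilm.row_at_col - truth.ilm_true.row_at_col) <= 1.0)


def test_ilm_recovers_tilt_slope():
    spec = PhantomSpec(noise_sd=4.0, tilt=0.05, seed=5)
    img, truth = generate_phantom(spec)
    den = seg.denoise_bscan(img)
    ilm = seg.detect_ilm(seg.connect_and_edge(den), den)
    fit = np.polyfit(np.arange(ilm.cols), ilm.row_at_col, 1)
    assert fit[0] == pytest.approx(0.05, rel=0.10)


def test_blank_image_is_segmentation_failure():
    img = _img(np.zeros((40, 40)))
    with pytest.raises(SegmentationError), pytest.warns(UserWarning):
        seg.detect_ilm(seg.connect_and_edge(img), img)


# ---- flatten -----------------------------------------------------------


def test_flatten_already_flat_is_identity(clean_phantom):
    _, img, truth = clean_phantom
    flat, shifts = seg.flatten_to_ilm(img, truth.ilm_true)
    np.testing.assert_array_equal(shifts, 0)
    np.testing.assert_array_equal(flat.pixels, img.pixels)


def test_flatten_levels_tilted_ilm():
    spec = PhantomSpec(noise_sd=4.0, tilt=0.08, seed=6)
    img, _ = generate_phantom(spec)
    den = seg.denoise_bscan(img)
    ilm = seg.detect_ilm(seg.connect_and_edge(den), den)
    flat, shifts = seg.flatten_to_ilm(den, ilm)
    ilm2 = seg.detect_ilm(seg.connect_and_edge(flat), flat)
    assert np.var(ilm2.row_at_col) < 1.0


def test_flatten_preserves_boundary_distance(noisy_phantom):
    """Thickness must be identical computed before or after flattening."""
    _, img, _ = noisy_phantom
    cal = img.calibration
    ilm, rpe, shifts = run_segmentation(img)
    thick_after = (rpe.row_at_col + shifts) - (ilm.row_at_col + shifts)
    thick_before = rpe.row_at_col - ilm.row_at_col
    np.testing.assert_allclose(
        thick_before * cal.axial_um_per_px, thick_after * cal.axial_um_per_px, atol=1.0
    )


# ---- RPE ---------------------------------------------------------------


def test_rpe_recovered_within_two_px(noisy_phantom):
    _, img, truth = noisy_phantom
    ilm, rpe, _ = run_segmentation(img)
    err = np.abs(rpe.row_at_col - truth.rpe_true.row_at_col)
    assert np.all(err <= 2.0)


def test_rpe_prefers_bright_band_over_faint_inner_layer():
    spec = PhantomSpec(noise_sd=4.0, inner_band_amplitude=60.0, seed=7)
    img, truth = generate_phantom(spec)
    ilm, rpe, _ = run_segmentation(img)
    err = np.abs(rpe.row_at_col - truth.rpe_true.row_at_col)
    assert np.all(err <= 2.0)


def test_no_band_below_ilm_is_segmentation_failure():
    arr = np.full((60, 40), 5.0)
    arr[10, :] = 220.0  # ILM line only, nothing deeper
    with pytest.raises(SegmentationError):
        seg.detect_rpe(_img(arr), 10.0)


# ---- thickness ---------------------------------------------------------


def test_thickness_arithmetic_from_printed_calibration():
    from octva.devices import calibration_for_device

    cal = calibration_for_device("spectralis")
    n = 32
    ilm = BoundaryCurve(np.full(n, 100.0), np.ones(n, bool))
    rpe = BoundaryCurve(np.full(n, 150.0), np.ones(n, bool))
    prof = seg.thickness_profile(ilm, rpe, cal)
    # 50 px * (2000/496) um/px = 201.61 um
    np.testing.assert_allclose(prof.thickness_um, 201.61, atol=0.01)


def test_identical_curves_zero_thickness():
    from octva.devices import calibration_for_device

    cal = calibration_for_device("spectralis")
    n = 16
    c = BoundaryCurve(np.full(n, 80.0), np.ones(n, bool))
    prof = seg.thickness_profile(c, c, cal)
    np.testing.assert_array_equal(prof.thickness_um, 0.0)


def test_profile_minimum_at_pit_center(noisy_phantom):
    spec, img, _ = noisy_phantom
    cal = img.calibration
    ilm, rpe, _ = run_segmentation(img)
    prof = seg.thickness_profile(ilm, rpe, cal)
    # restrict to the central half: the periphery also thins
    n = prof.cols
    central = slice(n // 4, 3 * n // 4)
    min_col = n // 4 + int(np.argmin(prof.thickness_um[central]))
    assert abs(min_col - spec.pit_center_col) <= 2.0


def test_end_to_end_parameter_recovery_with_noise():
    """ILM/RPE MAE <= 2 px and thickness MAE <= 10 um on random phantoms."""
    from tests.conftest import random_phantom_spec

    rng = np.random.default_rng(11)
    ilm_err, rpe_err, th_err = [], [], []
    for k in range(8):
        spec = random_phantom_spec(rng, seed=100 + k)
        img, truth = generate_phantom(spec)
        ilm, rpe, _ = run_segmentation(img)
        cal = img.calibration
        ilm_err.append(np.abs(ilm.row_at_col - truth.ilm_true.row_at_col).mean())
        rpe_err.append(np.abs(rpe.row_at_col - truth.rpe_true.row_at_col).mean())
        prof = seg.thickness_profile(ilm, rpe, cal)
        from octva.synthetic import analytic_thickness_um

        th_err.append(np.abs(prof.thickness_um - analytic_thickness_um(spec)).mean())
    assert np.mean(ilm_err) <= 2.0
    assert np.mean(rpe_err) <= 2.0
    assert np.mean(th_err) <= 10.0


def test_error_monotone_in_noise():
    """Median boundary error does not decrease as phantom noise grows."""
    from octva.synthetic import analytic_thickness_um

    errs = []
    for noise in (0.0, 10.0, 30.0):
        level = []
        for s in range(3):
            spec = PhantomSpec(noise_sd=noise, seed=50 + s)
            img, truth = generate_phantom(spec)
            ilm, rpe, _ = run_segmentation(img)
            prof = seg.thickness_profile(ilm, rpe, img.calibration)
            level.append(np.abs(prof.thickness_um - analytic_thickness_um(spec)).mean())
        errs.append(np.median(level))
    assert errs[0] <= errs[1] + 0.5 and errs[1] <= errs[2] + 0.5


def test_boundary_csv_export_roundtrip(tmp_path, noisy_phantom):
    import pandas as pd

    _, img, _ = noisy_phantom
    ilm, rpe, _ = run_segmentation(img)
    prof = seg.thickness_profile(ilm, rpe, img.calibration)
    path = str(tmp_path / "curves.csv")
    seg.export_boundaries_csv(ilm, rpe, prof, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["col", "row_ilm", "row_rpe", "thickness_um"]
    np.testing.assert_allclose(df["thickness_um"], prof.thickness_um)
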
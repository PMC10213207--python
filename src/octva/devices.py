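"""Per-device scan geometry and pixel-to-micron calibration.

Three spectral-domain OCT scanners are supported. Each line scan covers a
fixed lateral width and axial depth in tissue, imaged at a fixed native
pixel grid, which gives the micron-per-pixel factors used to convert
boundary positions into retinal thickness:

========== ============== ================= ================
device     native (c x r) scan width (um)   scan depth (um)
========== ============== ================= ================
spectralis 768 x 496      10,000            2,000
cirrus     938 x 625       6,000            2,000
rtvue      1020 x 960     10,000            2,000
========== ============== ================= ================

Exported B-scans are often resampled; :func:`calibration_for_device`
accepts an actual image size and rescales the factors proportionally so a
downsampled frame keeps the same physical extent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = ["DeviceCalibration", "calibration_for_device", "SUPPORTED_DEVICES"]


@dataclass(frozen=True)
class DeviceCalibration:
    """Micron/pixel scale factors derived from a scanner's printed geometry."""

    device_id: str
    scan_width_um: float
    scan_depth_um: float
    native_cols: int
    native_rows: int
    lateral_um_per_px: float
    axial_um_per_px: float

    def __post_init__(self):
        if self.lateral_um_per_px <= 0 or self.axial_um_per_px <= 0:
            raise ConfigurationError("calibration scale factors must be positive")


# (scan_width_um, scan_depth_um, native_cols, native_rows)
_DEVICE_GEOMETRY = {
    "spectralis": (10_000.0, 2_000.0, 768, 496),
    "cirrus": (6_000.0, 2_000.0, 938, 625),
    "rtvue": (10_000.0, 2_000.0, 1020, 960),
}

SUPPORTED_DEVICES = tuple(_DEVICE_GEOMETRY)


def calibration_for_device(
    device_id: str,
    cols: int | None = None,
    rows: int | None = None,
) -> DeviceCalibration:
    """Return the calibration for ``device_id``.

    Parameters
    ----------
    device_id:
        One of ``spectralis``, ``cirrus``, ``rtvue``.
    cols, rows:
        Actual image size, if the frame was resampled from the native grid.
        The physical scan extent is unchanged, so the um/px factors scale
        inversely with the pixel counts.
    """
    try:
        width_um, depth_um, native_cols, native_rows = _DEVICE_GEOMETRY[device_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown device {device_id!r}; supported: {', '.join(SUPPORTED_DEVICES)}"
        ) from None
    eff_cols = native_cols if cols is None else int(cols)
    eff_rows = native_rows if rows is None else int(rows)
    if eff_cols <= 0 or eff_rows <= 0:
        raise ConfigurationError("image dimensions must be positive")
    return DeviceCalibration(
        device_id=device_id,
        scan_width_um=width_um,
        scan_depth_um=depth_um,
        native_cols=eff_cols,
        native_rows=eff_rows,
        lateral_um_per_px=width_um / eff_cols,
        axial_um_per_px=depth_um / eff_rows,
    )
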
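"""Image and cohort-table I/O.

A B-scan is stored as a 2-D float array with row 0 on the vitreous side,
so the ILM is the first bright boundary encountered scanning down a
column. Columns run temporal-to-nasal for right eyes; left-eye scans
should be mirrored upstream so "temporal" is always the left half of the
frame.

Cohort tables are plain CSV with one row per eye:

    eye_id, device_id, preop_bcva_logmar, postop_bcva_logmar, himg_path, vimg_path

``postop_bcva_logmar`` may be absent entirely (prediction mode) but must
be numeric when present.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .devices import DeviceCalibration, calibration_for_device
from .errors import SchemaError, ValidationError

__all__ = [
    "BScanImage",
    "CohortRecord",
    "load_image",
    "save_image",
    "load_cohort_table",
    "save_cohort_table",
]


@dataclass
class BScanImage:
    """A calibrated grayscale OCT frame (row 0 = vitreous side)."""

    pixels: np.ndarray
    device_id: str
    orientation: str = "horizontal"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValidationError("pixel intensities must be finite and non-negative")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def calibration(self) -> DeviceCalibration:
        """um/px factors for this frame, rescaled to its actual size."""
        return calibration_for_device(self.device_id, cols=self.cols, rows=self.rows)


@dataclass
class CohortRecord:
    """One eye of a cohort: BCVA measurements plus its two B-scans."""

    eye_id: str
    device_id: str
    preop_bcva: float
    postop_bcva: float | None = None
    himg_path: str | None = None
    vimg_path: str | None = None
    indices: "np.ndarray | None" = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.preop_bcva):
            raise ValidationError(f"eye {self.eye_id}: preop BCVA must be finite")
        if self.postop_bcva is not None and not np.isfinite(self.postop_bcva):
            raise ValidationError(f"eye {self.eye_id}: postop BCVA must be finite")


def load_image(path: str, device_id: str, orientation: str = "horizontal") -> BScanImage:
    """Load a grayscale PNG/TIFF B-scan; RGB inputs are collapsed to luminance."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot decode image {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-size image: {path!r}")
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float)
        # ITU-R 601 luma; identical channels collapse to themselves
        arr = arr @ np.array([0.299, 0.587, 0.114])
    return BScanImage(pixels=arr.astype(float), device_id=device_id, orientation=orientation)


def save_image(img: "BScanImage | np.ndarray", path: str, bit_depth: int = 8) -> None:
    """Write a grayscale image as 8-bit (or 16-bit) PNG, clipping to range."""
    arr = img.pixels if isinstance(img, BScanImage) else np.asarray(img, dtype=float)
    if bit_depth == 8:
        out = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        Image.fromarray(out, mode="L").save(path)
    elif bit_depth == 16:
        out = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
        Image.fromarray(out, mode="I;16").save(path)
    else:
        raise ValidationError("bit_depth must be 8 or 16")


_REQUIRED_COLUMNS = ("eye_id", "device_id", "preop_bcva_logmar", "himg_path", "vimg_path")
_INDEX_COLUMNS = (
    "foveal_thickness_um",
    "pit_depth_um",
    "pit_diameter_um",
    "temporal_max_thickness_um",
    "nasal_max_thickness_um",
    "temporal_slope_deg",
    "nasal_slope_deg",
)


def load_cohort_table(path: str) -> list[CohortRecord]:
    """Read a cohort CSV into typed records.

    The postop column may be missing (prediction mode). Duplicate eye ids
    and non-numeric BCVA values are rejected with the offending row named.
    """
    df = pd.read_csv(path, dtype={"eye_id": str, "device_id": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort table {path!r} is missing column {col!r}")
    dupes = df["eye_id"][df["eye_id"].duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"duplicate eye_id values: {', '.join(map(str, dupes[:5]))}")
    has_postop = "postop_bcva_logmar" in df.columns
    has_indices = all(c in df.columns for c in _INDEX_COLUMNS)

    records = []
    for i, row in df.iterrows():
        try:
            preop = float(row["preop_bcva_logmar"])
        except (TypeError, ValueError):
            raise SchemaError(f"row {i}: non-numeric preop BCVA {row['preop_bcva_logmar']!r}")
        postop = None
        if has_postop and not pd.isna(row["postop_bcva_logmar"]):
            try:
                postop = float(row["postop_bcva_logmar"])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"row {i}: non-numeric postop BCVA {row['postop_bcva_logmar']!r}"
                )
        indices = None
        if has_indices and not any(pd.isna(row[c]) for c in _INDEX_COLUMNS):
            indices = np.array([float(row[c]) for c in _INDEX_COLUMNS])
        records.append(
            CohortRecord(
                eye_id=str(row["eye_id"]),
                device_id=str(row["device_id"]),
                preop_bcva=preop,
                postop_bcva=postop,
                himg_path=None if pd.isna(row["himg_path"]) else str(row["himg_path"]),
                vimg_path=None if pd.isna(row["vimg_path"]) else str(row["vimg_path"]),
                indices=indices,
            )
        )
    return records


def save_cohort_table(records: list[CohortRecord], path: str) -> None:
    """Write records back to the cohort CSV schema (with index columns if present)."""
    rows = []
    for r in records:
        row = {
            "eye_id": r.eye_id,
            "device_id": r.device_id,
            "preop_bcva_logmar": r.preop_bcva,
            "postop_bcva_logmar": r.postop_bcva,
            "himg_path": r.himg_path,
            "vimg_path": r.vimg_path,
        }
        if r.indices is not None:
            row.update(dict(zip(_INDEX_COLUMNS, np.asarray(r.indices, dtype=float))))
        rows.append(row)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def prediction_mode(records: list[CohortRecord]) -> bool:
    """True when any record lacks a postoperative BCVA."""
    return any(r.postop_bcva is None for r in records)
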
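"""Containers for layer boundaries and thickness profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .devices import DeviceCalibration
from .errors import ValidationError

__all__ = ["BoundaryCurve", "ThicknessProfile"]


@dataclass
class BoundaryCurve:
    """Per-column subpixel row position of one retinal boundary.

    ``row_at_col[i]`` is the boundary's (possibly interpolated) row at
    column ``i``; ``valid_mask[i]`` marks columns where the boundary was
    actually detected rather than filled in.
    """

    row_at_col: np.ndarray
    valid_mask: np.ndarray
    orientation: str = "horizontal"

    def __post_init__(self):
        self.row_at_col = np.asarray(self.row_at_col, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.row_at_col.shape != self.valid_mask.shape or self.row_at_col.ndim != 1:
            raise ValidationError("row_at_col and valid_mask must be matching 1-D arrays")

    @property
    def cols(self) -> int:
        return self.row_at_col.size

    @property
    def valid_fraction(self) -> float:
        return float(self.valid_mask.mean()) if self.valid_mask.size else 0.0


@dataclass
class ThicknessProfile:
    """Calibrated total retinal thickness (ILM to RPE) along the scan line."""

    thickness_um: np.ndarray
    lateral_pos_um: np.ndarray
    calibration: DeviceCalibration
    valid_mask: np.ndarray | None = None
    n_clipped_negative: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        self.lateral_pos_um = np.asarray(self.lateral_pos_um, dtype=float)
        if self.thickness_um.shape != self.lateral_pos_um.shape:
            raise ValidationError("thickness and lateral position must align")
        if self.valid_mask is None:
            self.valid_mask = np.ones_like(self.thickness_um, dtype=bool)
        if np.any(self.thickness_um[self.valid_mask] < 0):
            raise ValidationError("thickness must be non-negative on valid columns")

    @property
    def cols(self) -> int:
        return self.thickness_um.size
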
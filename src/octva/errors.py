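"""Exception hierarchy.

Errors are split by where they arise so a pipeline driver can report the
failing stage: configuration (bad device id, missing modality), validation
(malformed inputs), segmentation failure (unusable scan, the analogue of a
poor-quality-image exclusion), and absence of a detectable foveal pit.
"""


class OctvaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OctvaError):
    """Unknown device, missing modality, or otherwise invalid configuration."""


class ValidationError(OctvaError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A tabular input is missing columns or violates table-level invariants."""


class SegmentationError(OctvaError):
    """A layer boundary could not be traced on enough of the scan."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class NoPitDetected(OctvaError):
    """No foveal depression found on the thickness profile.

    Carries a ``fallback`` FoveaMarks computed from the minimum-thickness
    column so edematous/dome-shaped maculae can still be indexed (with a QC
    flag) instead of being dropped.
    """

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class TrainingError(OctvaError):
    """Model training failed (empty data, numerical blow-up)."""
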
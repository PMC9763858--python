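"""Exception hierarchy.

All package-specific failures derive from :class:`PatchStoichError` so callers
can distinguish pipeline problems from programming errors.
"""


class PatchStoichError(Exception):
    """Base class for all package errors."""


class FormatError(PatchStoichError):
    """A file could not be read as the expected format."""


class ConfigurationError(PatchStoichError):
    """Missing or inconsistent run configuration (e.g. no pixel size)."""


class ParameterError(PatchStoichError):
    """A numeric parameter is out of its valid range."""


class GeometryError(PatchStoichError):
    """An image or window is too small for the requested operation."""


class CalibrationError(PatchStoichError):
    """Single-fluorophore brightness could not be calibrated."""


class SegmentationError(PatchStoichError):
    """Binarization failed (e.g. constant image)."""


class OrchestrationError(PatchStoichError):
    """A pipeline stage is missing one of its input artifacts."""


class DegenerateSamplesError(PatchStoichError):
    """A statistical test cannot be computed (zero rank variance)."""
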
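"""Exception hierarchy shared across the pipeline.

Every error a caller can act on derives from :class:`NeckQuantError`;
stage failures inside a composed run are wrapped in :class:`StageError`
so no partial result ever escapes silently.
"""


class NeckQuantError(Exception):
    """Base class for all package errors."""


class InputError(NeckQuantError):
    """Missing, unreadable, or out-of-domain input."""


class FormatError(NeckQuantError):
    """File exists but does not conform to the expected format."""


class CalibrationError(FormatError):
    """HU calibration metadata (rescale slope/intercept) is absent."""


class SpecError(NeckQuantError):
    """Invalid phantom specification (geometry/HU constraints violated)."""


class LandmarkError(NeckQuantError):
    """Anatomic landmarks are inconsistent with the volume geometry."""


class SeedError(NeckQuantError):
    """The airway seed point does not sit in air-dense tissue."""


class EmptySlabError(NeckQuantError):
    """An axial slab does not intersect any voxel slice."""


class EmptyBodyError(NeckQuantError):
    """No body contour found above the tissue threshold."""


class AlignmentError(NeckQuantError):
    """Two grids expected to share shape/spacing do not."""


class SchemaError(NeckQuantError):
    """A tabular input is missing required columns or keys."""

    def __init__(self, missing, message=None):
        self.missing = sorted(missing)
        super().__init__(message or f"missing required fields: {', '.join(self.missing)}")


class SampleError(NeckQuantError):
    """Too few subjects/observations for the requested statistic."""


class DegenerateDataError(NeckQuantError):
    """Zero-variance or otherwise degenerate data for the statistic."""


class ConvergenceError(NeckQuantError):
    """Iterative fit failed to converge (e.g. monotone Cox likelihood)."""


class StageError(NeckQuantError):
    """Failure inside a named stage of a composed pipeline run."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
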
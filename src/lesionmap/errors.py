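"""Exception hierarchy shared across the pipeline."""


class LesionmapError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(LesionmapError):
    """Volumes expected on one shared grid disagree in shape or affine."""


class AtlasSizingError(LesionmapError):
    """The requested grid is too small to place a required region."""


class ConfigurationError(LesionmapError):
    """A configuration value is missing or inconsistent."""


class InvalidImageError(LesionmapError):
    """An image violates a basic assumption (e.g. non-positive brain median)."""


class EmptyROIError(LesionmapError):
    """Percent-resected is undefined for an empty region of interest."""


class CohortValidationError(LesionmapError):
    """A cohort table failed validation; message lists offending rows."""


class CohortCompositionError(LesionmapError):
    """A group comparison requires both outcome groups to be populated."""
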
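"""Exception types shared across the pipeline."""


class MetsperfError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetsperfError):
    """Invalid acquisition geometry or preset configuration."""


class PlacementError(MetsperfError):
    """A phantom object (lesion, vessel) could not be placed without overlap."""


class BaselineError(MetsperfError):
    """Baseline correction is undefined for this curve (e.g. too few post-bolus frames)."""


class ROIError(MetsperfError):
    """An ROI operation failed (mirror out of bounds, no valid reference, ...)."""


class RegionError(MetsperfError):
    """A lesion could not be assigned to an anatomical region."""


class FieldExcludedError(MetsperfError):
    """A histology field must be excluded from analysis (e.g. empty tumor mask)."""
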
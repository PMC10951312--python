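"""Exception hierarchy for octcycle.

All package-specific failures derive from :class:`OctCycleError` so callers can
catch one base class at pipeline boundaries.
"""


class OctCycleError(Exception):
    """Base class for all octcycle errors."""


class ConfigError(OctCycleError):
    """Invalid configuration value."""


class SizingError(ConfigError):
    """Frame too small to hold the configured layer stack."""


class InsufficientCyclesError(OctCycleError):
    """Fewer cardiac cycles than the operation requires."""


class DegenerateInputError(OctCycleError):
    """Input image is constant or otherwise carries no registrable signal."""


class FitError(OctCycleError):
    """Too few usable samples for a model fit."""


class UndefinedMetricError(OctCycleError):
    """A metric's denominator (e.g. background SD) is zero."""


class MaskError(OctCycleError):
    """A required ROI mask is missing or empty."""


class VideoFormatError(OctCycleError):
    """Malformed video file or missing sidecar."""


class NoOutsideRegionError(OctCycleError):
    """Resolution ellipse covers the whole spectrum; no noise region exists."""
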
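"""Exception hierarchy for octaquant.

Every error raised by the package derives from :class:`OctaQuantError`, so
callers can catch one base class at pipeline boundaries while tests can
assert on the precise failure mode.
"""


class OctaQuantError(Exception):
    """Base class for all octaquant errors."""


class FormatError(OctaQuantError):
    """Raster file is not a single-channel 8- or 16-bit image."""


class DimensionError(OctaQuantError):
    """Image grid is not square or shapes of paired inputs disagree."""


class SchemaError(OctaQuantError):
    """A tabular input is missing required columns."""


class RecordError(OctaQuantError):
    """A per-eye record violates its invariants (e.g. stage outside 0-4)."""


class GeometryError(OctaQuantError):
    """Analysis region does not fit inside the image."""


class ParameterError(OctaQuantError):
    """A numeric argument is outside its admissible range."""


class MaskError(OctaQuantError):
    """A mask argument is empty or unusable."""


class FitError(OctaQuantError):
    """Base class for two-segment regression failures."""


class FitDegenerateError(FitError):
    """Fitted segments are (near-)parallel; no usable intersection."""


class FitInvalidError(FitError):
    """Segment intersection falls outside the fitted threshold range."""


class NoThresholdError(OctaQuantError):
    """Histogram-based thresholding is undefined (e.g. constant image)."""


class UndefinedMetricError(OctaQuantError):
    """A perfusion metric is undefined on the given input."""


class FazError(OctaQuantError):
    """Base class for avascular-zone measurement failures."""


class FillEscapeError(FazError):
    """Assisted flood fill leaked to the image border."""


class ImplausibleFazError(FazError):
    """Measured avascular area exceeds the sanity bound."""


class InputError(OctaQuantError):
    """A required pipeline input (e.g. a plexus slab) is missing."""


class ModelError(OctaQuantError):
    """Statistical model could not be fit (singular design, etc.)."""


class LabelError(OctaQuantError):
    """Classification labels are degenerate (one class empty)."""


class UndefinedStatisticError(OctaQuantError):
    """A statistic is undefined (zero variance, zero pooled SD, ...)."""


class ConfigError(OctaQuantError):
    """Run configuration is inconsistent with the data."""
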
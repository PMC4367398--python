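"""Exception hierarchy shared across the toolkit."""


class TomastemError(Exception):
    """Base class for all toolkit errors."""


class DimensionError(TomastemError):
    """Depth and color rasters do not share a pixel grid."""


class EmptyPlantError(TomastemError):
    """No foreground pixels survive the depth window."""


class DegenerateHistogramError(TomastemError):
    """Breadth histogram has mass at fewer than two positions."""


class DegenerateWindowError(TomastemError):
    """Smoothing window too large for the histogram."""


class EmptyPatchError(TomastemError):
    """A texture crop contains no foreground pixels."""


class NoLeafError(TomastemError):
    """Color segmentation found no leaf pixels."""


class EmptyDBError(TomastemError):
    """A texture-database category holds no patches."""


class GrammarError(TomastemError):
    """An L-system grammar file is malformed or ambiguous."""


class InvalidChoiceError(TomastemError):
    """A branch-form choice string violates the closed form set."""


class StructureError(TomastemError):
    """An L-string is not bracket balanced or otherwise ill-formed."""


class ProjectionError(TomastemError):
    """Scene geometry lies behind the synthetic camera."""


class UndefinedRateError(TomastemError):
    """Batch rate requested with a zero denominator."""


class ConfigError(TomastemError):
    """Unknown or out-of-range configuration value."""
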
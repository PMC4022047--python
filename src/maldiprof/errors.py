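"""Exception hierarchy for the profiling pipeline."""


class MaldiprofError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(MaldiprofError):
    """A spectrum or table file could not be parsed."""


class CalibrationError(MaldiprofError):
    """Internal recalibration could not match enough reference masses."""


class RangeError(MaldiprofError):
    """m/z ranges of spectra are incompatible (e.g. no overlap)."""


class NormalizationError(MaldiprofError):
    """A spectrum cannot be normalized (non-positive total intensity)."""


class ValidationError(MaldiprofError):
    """A domain object violates its invariants."""


class ConfigError(MaldiprofError):
    """A pipeline configuration file is malformed or has unknown keys."""
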
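"""Exception hierarchy for the otolith-origin pipeline."""


class OtolithOriginError(Exception):
    """Base class for all package errors."""


class ConfigError(OtolithOriginError):
    """Invalid scenario or run configuration."""


class GenerationError(OtolithOriginError):
    """Synthetic data could not be generated under the given settings."""


class ReductionError(OtolithOriginError):
    """Raw transect counts could not be reduced to concentrations/ratios."""


class SummaryError(ReductionError):
    """A core/edge summary window was empty or out of range."""


class CalibrationError(OtolithOriginError):
    """Water-otolith calibration could not be fit."""


class ClassificationError(OtolithOriginError):
    """Origin classification contract violation."""


class ComparisonError(OtolithOriginError):
    """Assemblage comparison could not be built."""
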
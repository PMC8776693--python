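"""Exception hierarchy for the ofrad pipeline."""


class OfradError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OfradError):
    """Invalid configuration value (probability out of range, bad threshold, ...)."""


class GenerationError(OfradError):
    """Phantom generation failed (e.g. tumour does not fit in the image extent)."""


class FormatError(OfradError):
    """File could not be interpreted as a 3D single-channel volume."""


class DegenerateROIError(OfradError):
    """ROI became empty or constant where a non-degenerate ROI is required."""


class DataError(OfradError):
    """Input table/matrix violates a precondition (non-finite values, id mismatch, collinearity)."""


class NotFittedError(OfradError):
    """Results were requested from a model that has not been fitted."""
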
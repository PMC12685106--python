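"""Exception hierarchy shared across the pipeline stages."""


class DesilipidError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DesilipidError):
    """An invalid configuration field; the message names the field."""


class FormatError(DesilipidError):
    """Malformed input data (imzML, mask, table)."""


class ValidationError(DesilipidError):
    """Inputs are well-formed but mutually inconsistent."""


class EmptyROIError(DesilipidError):
    """A requested tissue label has no pixels for a patient."""


class NormalizationError(DesilipidError):
    """A sample cannot be normalized (e.g. all-zero spectrum)."""


class FittingError(DesilipidError):
    """A model cannot be fitted (degenerate class, bad shapes)."""


class FoldError(DesilipidError):
    """A cross-validation fold lost one of the classes."""


class DimensionError(DesilipidError):
    """Feature-vector length does not match a fitted model."""
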
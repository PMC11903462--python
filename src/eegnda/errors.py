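"""Exception types shared across the package."""


class EegndaError(Exception):
    """Base class for package errors."""


class ConfigurationError(EegndaError, ValueError):
    """Invalid configuration value or combination."""


class SizingError(EegndaError, ValueError):
    """An input is too short / too small for the requested operation."""


class AlignmentError(EegndaError, ValueError):
    """Paired inputs (data/events, recording/timeline) do not line up."""


class SchemaError(EegndaError, ValueError):
    """A file does not match the expected column schema."""


class UndefinedAUCError(EegndaError, ValueError):
    """ROC-AUC is undefined because the labels contain a single class."""


class FitError(EegndaError, ValueError):
    """Too few usable points for a regression fit."""


class NumericError(EegndaError, RuntimeError):
    """A numeric failure (non-finite loss, divergence) during training."""
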
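"""Exception hierarchy.

Every error raised by this package derives from :class:`LawTimeError`, so
callers can catch one base class. Subclasses mirror the pipeline stages:
schedule validation, windowing, eigendecomposition, dataset handling,
pooling and transformation, and experiment configuration.
"""


class LawTimeError(Exception):
    """Base class for all lawtime errors."""


class ScheduleError(LawTimeError, ValueError):
    """Invalid (r, l, k) triplet or schedule."""


class WindowError(LawTimeError, ValueError):
    """A window or row-embedding span does not fit in the series."""


class NumericError(LawTimeError, ValueError):
    """Non-finite or non-symmetric input to the eigensolver."""


class DatasetError(LawTimeError, ValueError):
    """Malformed or inconsistent dataset."""


class ParseError(DatasetError):
    """Malformed dataset file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PoolingError(LawTimeError, ValueError):
    """Pooling over an empty selection."""


class TransformError(LawTimeError, ValueError):
    """Instance incompatible with the trained model."""


class ConfigurationError(LawTimeError, ValueError):
    """Invalid experiment or model configuration."""


class SpecError(LawTimeError, ValueError):
    """Invalid synthetic-data specification."""
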
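"""Exception types shared across the package."""


class GtnormError(Exception):
    """Base class for all package errors."""


class EmptyProfileError(GtnormError):
    """A cell with zero total counts cannot be normalized."""


class NeedsFallback(GtnormError):
    """Raised internally when the log-log regression is undefined
    (< 2 distinct positive count values); callers fall back to ML."""


class InvalidMatrixError(GtnormError):
    """Count matrix contains negative or non-integer entries."""


class FormatError(GtnormError):
    """A file on disk does not match the expected format."""


class InvalidGroupError(GtnormError):
    """A UMI group mixes sequence lengths or is empty."""


class ParseError(GtnormError):
    """A record file line could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class ProjectionError(GtnormError):
    """Fixed PCA projection asked to scale genes with zero variance."""
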
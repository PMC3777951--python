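"""Exception hierarchy for the cardiofp pipeline.

All library errors derive from :class:`CardioFPError` so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class CardioFPError(Exception):
    """Base class for all cardiofp errors."""


class FormatError(CardioFPError):
    """A file does not follow the expected dialect (e.g. missing header)."""


class ParseError(CardioFPError):
    """A file row or cell could not be parsed; message names the row."""


class LookupError_(CardioFPError, KeyError):
    """A requested identifier (electrode, complex index) does not exist."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ParameterError(CardioFPError, ValueError):
    """A parameter is outside its admissible range."""


class InsufficientDataError(CardioFPError):
    """Not enough data to carry out the operation (too few peaks/complexes)."""


class DetectionError(CardioFPError):
    """An automatic landmark detector failed; manual mode is the fallback."""


class UndefinedCorrelationError(CardioFPError):
    """Correlation is undefined because an operand has zero variance."""
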
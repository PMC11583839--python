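"""Typed exceptions raised across the pipeline.

Every reader and pipeline stage fails with one of these instead of a bare
ValueError so callers (and the CLI) can distinguish user-input problems from
bugs.
"""


class MetaboPipeError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(MetaboPipeError):
    """An input file is missing a mandatory column or field."""


class ReconciliationError(MetaboPipeError):
    """Two inputs that must agree (e.g. peak table vs. sample sheet) do not."""


class ParseError(MetaboPipeError):
    """A text format (MGF/MSP/delimited) is malformed.

    Carries ``line`` when the offending location is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ParameterError(MetaboPipeError):
    """A user-supplied parameter is outside its documented range."""


class CheckpointError(MetaboPipeError):
    """A checkpoint file is corrupt, truncated, or of an unknown schema."""


class ReferentialError(MetaboPipeError):
    """A record refers to a feature/compound that does not exist."""
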
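"""Exception hierarchy for the effect-directed-analysis toolkit."""


class EDAScreenError(Exception):
    """Base class for all package errors."""


class UnitError(EDAScreenError):
    """Raised when quantities with incompatible unit tags are combined."""


class FitDomainError(EDAScreenError):
    """Raised when a concentration-response fit has no usable points."""


class UndefinedPotencyError(EDAScreenError):
    """Raised when a potency ratio is requested but the denominator potency is missing."""


class MSPParseError(EDAScreenError):
    """Raised on a malformed MSP block; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SchemaError(EDAScreenError):
    """Raised when a table does not match the expected column schema."""


class ConfigError(EDAScreenError):
    """Raised on inconsistent configuration (e.g. an RT not covered by the IS map)."""
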
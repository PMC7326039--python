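"""Exception hierarchy shared across the package."""


class CircGradeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CircGradeError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class ValidationError(CircGradeError):
    """Input data violates an invariant (bad interval, bad p-value, ...)."""


class ConfigurationError(CircGradeError):
    """A parameter combination is infeasible or out of range."""
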
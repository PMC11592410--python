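"""Exception hierarchy shared across the package."""


class FibroTriageError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FibroTriageError, ValueError):
    """An input is outside the mathematical or physiological domain of an operation."""


class ConfigError(FibroTriageError, ValueError):
    """An algorithm or analysis configuration is internally inconsistent."""


class DataError(FibroTriageError, ValueError):
    """A cohort record is missing or malformed at the point it is consumed."""


class CohortParseError(DataError):
    """A cohort file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
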
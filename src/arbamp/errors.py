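"""Exception hierarchy for arbamp."""


class ArbampError(Exception):
    """Base class for all arbamp errors."""


class InvalidParameterError(ArbampError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidSequenceError(ArbampError, ValueError):
    """A sequence contains characters outside the expected alphabet."""


class CatalogParseError(ArbampError, ValueError):
    """A motif catalog or cocktail file could not be parsed."""


class ConfigurationError(ArbampError, ValueError):
    """A pipeline configuration is missing a required input."""


class DepthParseError(ArbampError, ValueError):
    """A depth table row is malformed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class InvalidSpecError(ArbampError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
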
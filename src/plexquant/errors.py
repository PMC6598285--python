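"""Exception hierarchy shared by all pipeline stages."""


class PlexquantError(Exception):
    """Base class for all errors raised by plexquant."""


class FormatError(PlexquantError):
    """A table could not be parsed (bad header, wrong column count, bad literal).

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PlexquantError):
    """Parsed values violate a domain invariant (negative intensity, duplicate id, ...)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(PlexquantError):
    """A configuration value is out of range or internally inconsistent."""


class DegenerateInputError(PlexquantError):
    """Input is structurally valid but the requested quantity is undefined on it."""
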
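"""Exception hierarchy used across the package."""


class PanstrepError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PanstrepError):
    """A configuration value or file dialect is invalid or incomplete."""


class InputFormatError(PanstrepError):
    """An input file violates its declared dialect.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
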
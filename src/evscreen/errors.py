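"""Exception hierarchy for evscreen."""


class EvscreenError(Exception):
    """Base class for all evscreen errors."""


class DesignError(EvscreenError):
    """Invalid input to a sequence-design operation."""


class FeasibilityError(DesignError):
    """A design request cannot be satisfied within the configured budget."""


class ConfigError(EvscreenError):
    """Missing or inconsistent configuration."""


class ParseError(EvscreenError):
    """Malformed on-disk input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(EvscreenError):
    """An assembled construct violates a structural constraint."""
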
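"""Exception hierarchy."""


class GoosevoxError(Exception):
    """Base class for all goosevox errors."""


class FormatError(GoosevoxError):
    """Unreadable or unsupported file content."""


class ValidationError(GoosevoxError):
    """Input data violates a documented precondition."""


class ConfigError(GoosevoxError):
    """Invalid configuration value or combination."""
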
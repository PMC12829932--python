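"""Exception hierarchy for the lucis package."""


class LucisError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LucisError, ValueError):
    """An input violates a documented precondition or invariant."""


class ConfigError(LucisError):
    """A run configuration is malformed or references missing resources."""
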
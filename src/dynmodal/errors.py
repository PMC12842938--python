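"""Package exception hierarchy."""


class DynmodalError(Exception):
    """Base class for package errors."""


class ValidationError(DynmodalError, ValueError):
    """Data violates a documented invariant (shape, finiteness, labels)."""


class ConfigError(DynmodalError, ValueError):
    """A configuration value is inconsistent or out of range."""
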
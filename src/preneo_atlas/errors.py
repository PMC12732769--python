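"""Package-specific exception and warning types."""


class ConfigurationError(ValueError):
    """An internally inconsistent or impossible configuration."""


class InputDataError(ValueError):
    """Malformed or contradictory input data (matrices, metadata, tables)."""


class EmptyResultWarning(UserWarning):
    """An operation completed but produced an empty result set."""
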
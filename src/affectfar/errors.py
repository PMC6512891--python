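"""Shared exception types."""


class ConfigurationError(ValueError):
    """An invalid configuration value (grid, layout, confusion matrix, ...)."""
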
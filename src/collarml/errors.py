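"""Shared error types."""


class ConfigError(ValueError):
    """A configuration value is outside its supported range."""
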
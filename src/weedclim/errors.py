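class WeedclimError(Exception):
    """Base class for package errors."""


class ConfigError(WeedclimError):
    """Invalid configuration (bad field value, missing path, unknown name)."""


class DataError(WeedclimError):
    """Invalid or insufficient data for a requested analysis."""
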
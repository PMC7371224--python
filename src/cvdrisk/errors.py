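"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input value is outside its scientifically plausible domain."""


class ChartValidationError(ValueError):
    """A risk-chart table is incomplete, duplicated or out of range."""


class ConfigError(ValueError):
    """A configuration value is invalid or inconsistent."""
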
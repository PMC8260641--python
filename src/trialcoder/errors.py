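"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A run configuration is invalid (unknown field, missing table, bad dialect)."""


class UndefinedDenominatorError(ZeroDivisionError):
    """A percentage was requested with a zero denominator."""


class EmptySelectionError(ValueError):
    """A statistic was requested over a selection with no usable records."""
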
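"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A generator or model parameter is outside its valid range."""


class DataValidationError(ValueError):
    """An input table violates its schema or invariants."""


class YearRangeError(ValueError):
    """An admission year falls outside the configured study period."""
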
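"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid model or run configuration (unknown group label, bad schema key)."""


class DataError(ValueError):
    """Observed data violate a precondition (non-positive index, bad CV)."""


class InvalidParameterError(ValueError):
    """A parameter value violates its mathematical domain (e.g. beta <= 0)."""


class InvalidStateError(ValueError):
    """A derived model state is outside its domain (e.g. B0 <= 0)."""


class NumericFailure(RuntimeError):
    """Non-finite or negative population state encountered during projection.

    Carries the year and age at which the failure was detected.
    """

    def __init__(self, message: str, year: int | None = None, age: int | None = None):
        super().__init__(message)
        self.year = year
        self.age = age
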
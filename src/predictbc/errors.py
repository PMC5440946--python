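"""Exception hierarchy shared across the package."""


class PredictError(Exception):
    """Base class for all predictbc errors."""


class InvalidInputError(PredictError):
    """A patient field or numeric argument violates its documented range.

    The ``field`` attribute names the offending variable so callers (and the
    CLI) can point at the exact column.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class HorizonError(PredictError):
    """Prediction time outside the supported horizon (no silent extrapolation)."""


class ConfigurationError(PredictError):
    """Bad model file, unknown treatment, or invalid simulator configuration."""


class SchemaError(PredictError):
    """Cohort CSV or model JSON does not match the declared schema."""


class FittingError(PredictError):
    """Estimation cannot proceed (no events, empty risk set, log of zero...)."""
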
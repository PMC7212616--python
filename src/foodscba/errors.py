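"""Exception hierarchy for the SCBA pipeline."""


class FoodSCBAError(Exception):
    """Base class for all package errors."""


class ConfigError(FoodSCBAError):
    """A generation or analysis configuration value is invalid."""


class GridMismatchError(FoodSCBAError):
    """Two inputs do not share the same age x sex (or year) grid."""


class ModelInputError(FoodSCBAError):
    """A model input violates its contract (negative rate, missing stream, ...)."""
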
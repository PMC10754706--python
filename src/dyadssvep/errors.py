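"""Exception types shared across the package."""


class DyadSSVEPError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DyadSSVEPError):
    """Invalid configuration value (unknown layout, bad band edges, ...)."""


class ScheduleError(DyadSSVEPError):
    """Stimulus schedule cannot be generated or is inconsistent with the data."""


class PreprocessingError(DyadSSVEPError):
    """Epoching/re-referencing contract violated (boundary, state, window)."""


class DegenerateInputError(DyadSSVEPError):
    """Statistic undefined on this input (zero variance, zero noise floor)."""


class DataIOError(DyadSSVEPError):
    """Reading or writing a dataset container failed."""
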
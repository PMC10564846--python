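"""Exception hierarchy for the virocycle pipeline."""


class VirocycleError(Exception):
    """Base class for all package errors."""


class ConfigError(VirocycleError):
    """Invalid or incomplete run configuration (missing columns, bad paths)."""


class ValidationError(VirocycleError):
    """Input data violates a documented contract (enum, range, schema)."""


class ParameterError(VirocycleError):
    """A parameter is outside its admissible range."""


class UndefinedStatisticError(VirocycleError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
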
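"""Exception hierarchy shared across the pipeline."""


class DroughtAdaptError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DroughtAdaptError):
    """A run/config problem: missing column, bad label map, infeasible parameters."""


class ValidationError(DroughtAdaptError):
    """Input data violates a structural invariant (negative value, missing condition...)."""


class DegenerateDataError(DroughtAdaptError):
    """A computation is undefined on this population (zero variance, zero mean...)."""
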
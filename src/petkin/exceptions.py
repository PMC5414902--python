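"""Exception hierarchy for petkin.

Model-fit failures are *not* exceptions: they are recorded as flags on the
results object so that cohort runs always complete.  Exceptions are reserved
for invalid inputs and configuration errors.
"""


class PetkinError(Exception):
    """Base class for all petkin errors."""


class ValidationError(PetkinError, ValueError):
    """An input violates a structural invariant (bad grid, negative dose, ...)."""


class InsufficientDataError(PetkinError, ValueError):
    """Too few data points for the requested fit."""


class DegenerateInputError(PetkinError, ValueError):
    """Input is structurally valid but carries no usable signal (flat curve, zero mean)."""


class SchemaError(PetkinError, ValueError):
    """A table is missing required columns or has malformed rows."""


class ConfigError(PetkinError, ValueError):
    """Invalid study configuration."""
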
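"""Exception hierarchy.

All package-specific failures derive from :class:`BystanderError` so the
CLI can map them onto a single data-error exit code.
"""


class BystanderError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BystanderError):
    """A table is missing a required column or carries an unknown one."""


class EmptyInputError(BystanderError):
    """An input table contained no rows."""


class DataError(BystanderError):
    """Values violate the data contract (e.g. punishment fraction outside [0, 1])."""


class DegenerateInputError(BystanderError):
    """Input has no usable variation (constant response, zero spread)."""


class DegenerateDesignError(BystanderError):
    """A design matrix is rank deficient."""


class InsufficientDataError(BystanderError):
    """Too few observations or participants for the requested computation."""
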
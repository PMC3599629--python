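"""Exception hierarchy for scalestep.

All package errors derive from :class:`ScaleStepError` so callers can catch
one base class; subclasses mirror the failure modes of the individual
operations (schema problems on load, degenerate items in scalability
computations, resampling collapse, optimisation failures).
"""


class ScaleStepError(Exception):
    """Base class for all scalestep errors."""


class SchemaError(ScaleStepError):
    """Input file does not match the instrument specification."""


class RangeError(ScaleStepError):
    """A response code lies outside the item's admissible range."""


class MappingError(ScaleStepError):
    """A category-merging map is non-monotone or leaves gaps."""


class EmptyDataError(ScaleStepError):
    """No usable rows remain (empty file, or listwise deletion removed all)."""


class DegenerateItemError(ScaleStepError):
    """An item has zero variance (or too few distinct codes) where variation is required."""


class DegeneratePairError(ScaleStepError):
    """An item pair has zero maximum covariance; its scalability is undefined."""


class ResampleError(ScaleStepError):
    """All resampling replicates were degenerate."""


class OptimizationError(ScaleStepError):
    """A likelihood optimisation failed in a way that invalidates the result."""


class PreconditionError(ScaleStepError):
    """An operation's structural precondition is violated (e.g. unequal category counts)."""
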
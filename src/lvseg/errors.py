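"""Exception hierarchy shared by all stages.

Every stage raises a subclass of :class:`LVSegError` so that pipeline
callers can tag failures with the stage that produced them.
"""


class LVSegError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(LVSegError):
    """An input object violates one of its documented invariants."""


class GeometryError(LVSegError):
    """A geometric precondition failed (crossing curves, empty crop, ...)."""


class MissingConstraintError(LVSegError):
    """A required constraint class is absent from the detection list."""


class DegenerateInputError(LVSegError):
    """The input carries no exploitable structure (e.g. a constant image)."""


class InsufficientSupportError(LVSegError):
    """Too few sample points to determine a curve of the requested degree."""


class ConstraintConflictError(LVSegError):
    """Equality constraints are mutually incompatible."""


class ExtractionFailureError(LVSegError):
    """Edge approach failed on too large a fraction of the contour."""


class UndefinedMetricError(LVSegError):
    """A metric was requested on inputs for which it is not defined."""


class FormatError(LVSegError):
    """A file could not be read or written in the expected format."""
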
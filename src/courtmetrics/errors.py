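"""Exception hierarchy for courtmetrics.

All package-specific failures derive from :class:`CourtMetricsError` so callers
can catch one base class at pipeline boundaries.
"""


class CourtMetricsError(Exception):
    """Base class for all courtmetrics errors."""


class SchemaError(CourtMetricsError):
    """A required column or category is missing or malformed."""


class IntegrityError(CourtMetricsError):
    """Rows violate a dataset invariant (duplicates, non-consecutive frames)."""


class AlignmentError(CourtMetricsError):
    """Two datasets or series do not share the expected keys/frames."""


class CalibrationError(CourtMetricsError):
    """Projective-transform estimation is impossible (too few or degenerate points)."""


class StructureError(CourtMetricsError):
    """A dataset lacks the session/trial/role structure an operation requires."""


class DegenerateInputError(CourtMetricsError):
    """Input is formally valid but statistically degenerate (e.g. zero mean distance)."""


class ContractError(CourtMetricsError):
    """An operation was called on an object that does not satisfy its contract."""
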
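"""Exception hierarchy.

Everything raised deliberately by ncakit derives from :class:`NcaKitError`
so callers can catch package errors without masking programming bugs.
"""


class NcaKitError(Exception):
    """Base class for all ncakit errors."""


class SchemaError(NcaKitError):
    """Input table is missing required columns or has an invalid layout."""


class ValidationError(NcaKitError):
    """A value violates a domain invariant (negative time, bad unit, ...)."""


class DuplicateRecordError(ValidationError):
    """Two rows share the same (arm, matrix, time) key."""


class DegenerateProfileError(NcaKitError):
    """A profile has no usable records left (e.g. everything was BLQ)."""


class InsufficientDataError(NcaKitError):
    """Too few data points for the requested estimate."""


class ExtrapolationError(NcaKitError):
    """A partial AUC interval extends beyond the sampled time range."""


class RouteError(NcaKitError):
    """An operation was requested for a dosing route it does not apply to."""


class ConventionError(NcaKitError):
    """Fold changes are not in the signed convention (values inside (-1, 1))."""
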
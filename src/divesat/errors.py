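"""Exception hierarchy for the divesat pipeline.

Every error raised by the package derives from :class:`DivesatError`, so
callers can catch pipeline failures without masking programming errors.
"""


class DivesatError(Exception):
    """Base class for all divesat errors."""


class InputDomainError(DivesatError, ValueError):
    """A value lies outside the physical/mathematical domain of an operation
    (negative partial pressure, saturation above capacity, time outside a
    dive, ...)."""


class FormatError(DivesatError, ValueError):
    """Malformed input record (non-monotone time axis, missing columns, ...)."""


class DegenerateDiveError(DivesatError):
    """A detected dive is too short to segment into phases."""


class EmptyProfileError(DivesatError):
    """No blood-gas samples overlap the dive being analysed."""


class InsufficientDataError(DivesatError):
    """Too few samples to compute per-dive metrics."""


class SiteMismatchError(DivesatError):
    """An operation restricted to one sampling site (arterial/venous) was
    given a profile from the other."""


class ZeroDivesError(DivesatError):
    """No dive survived the inclusion filter; downstream summaries would be
    empty."""


class GeneratorError(DivesatError):
    """The synthetic-data generator could not draw a feasible parameter set
    within the bounded retry budget."""
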
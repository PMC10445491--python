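"""Exception hierarchy for assay analysis failures.

Every error raised by the package derives from :class:`BnaKineticsError`
so callers (in particular the pipeline driver, which must keep going when
one compound's stage fails) can catch a single base class.
"""


class BnaKineticsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BnaKineticsError, ValueError):
    """A kinetic or binding parameter is outside its physical domain."""


class DesignError(BnaKineticsError, ValueError):
    """The experimental design is missing a required element (e.g. a control)."""


class UnreliableFitError(BnaKineticsError, RuntimeError):
    """The data cannot constrain the fit (e.g. no bracketing of the 50% point)."""


class NotSlowBindingError(BnaKineticsError, RuntimeError):
    """Kobs does not increase with inhibitor concentration."""


class NoIntersectionError(BnaKineticsError, RuntimeError):
    """Dixon lines are parallel; no intersection defines Ki."""


class DegenerateDesignError(BnaKineticsError, RuntimeError):
    """The rate grid cannot identify the model parameters."""


class ParseError(BnaKineticsError, ValueError):
    """A CSV input is malformed; the message lists offending rows."""
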
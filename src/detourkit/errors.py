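"""Named exceptions raised across the package."""


class DetourkitError(Exception):
    """Base class for all package errors."""


class ValidationError(DetourkitError, ValueError):
    """Input violates a documented precondition (range, sign, shape)."""


class UnknownQualityError(ValidationError):
    """A fix carries a location-quality code outside the known set."""


class AntipodalRouteError(DetourkitError):
    """Great-circle route between antipodal endpoints is undefined."""


class DegenerateTrackError(DetourkitError):
    """A track has too little structure for the requested operation
    (e.g. every fix falls inside a stopover)."""


class DegenerateGeometryError(DetourkitError):
    """Fewer than three non-collinear points; no polygon exists."""


class NumericalError(DetourkitError):
    """A numerical solve failed (no bracket, no interior optimum)."""


class OutOfBoundsError(DetourkitError):
    """Query point outside a grid's spatial or temporal extent; the
    package never extrapolates silently."""
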
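"""Exception hierarchy shared across the package."""


class FemurDispError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FemurDispError, ValueError):
    """An input object violates one of its structural invariants."""


class DegenerateGeometryError(FemurDispError, ValueError):
    """Geometry too degenerate for the requested fit (e.g. coplanar points)."""


class FoveaNotFoundError(FemurDispError, RuntimeError):
    """No head vertex shows an inward deficit above the detection threshold."""


class UndefinedKappaError(FemurDispError, ZeroDivisionError):
    """Chance agreement equals 1; the kappa statistic is undefined."""
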
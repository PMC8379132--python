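"""Exception types shared across the package."""


class UldctError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(UldctError, ValueError):
    """A spatial precondition is violated (point outside volume, source inside
    the reconstruction volume, overlapping structures, ...)."""


class FormatError(UldctError, ValueError):
    """A file could not be interpreted as a consistent CT volume."""


class ArgumentError(UldctError, ValueError):
    """A scalar argument is out of its documented domain."""


class DivisionError(UldctError, ZeroDivisionError):
    """A quantity that must be strictly positive (an SD, an effective dose)
    is zero, so a ratio-based index is undefined."""


class UndefinedStatisticError(UldctError, ValueError):
    """A statistic has no defined value for the given data (e.g. ICC with
    zero total variance)."""
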
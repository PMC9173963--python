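"""Exception hierarchy shared across the package.

All domain failures derive from :class:`RetinexMedError` so callers (and the
CLI) can catch one base class; each subclass also derives from the closest
builtin so idiomatic ``except ValueError`` handling keeps working.
"""


class RetinexMedError(Exception):
    """Base class for all errors raised by retinexmed."""


class FormatError(RetinexMedError, ValueError):
    """Unreadable file, unsupported raster format, or zero-area image."""


class RangeError(RetinexMedError, ValueError):
    """Intensities outside the range representable at the declared bit depth."""


class DomainError(RetinexMedError, ValueError):
    """Scalar argument outside its mathematical domain (e.g. sigma <= 0)."""


class ShapeError(RetinexMedError, ValueError):
    """Mismatched or invalid array shapes."""


class SizeError(RetinexMedError, ValueError):
    """Image too small for the requested operation."""


class ConfigError(RetinexMedError, ValueError):
    """Inconsistent algorithm configuration."""


class DegenerateRangeError(RetinexMedError, ValueError):
    """Constant-valued input where a non-degenerate range is required."""


class DegenerateTableError(RetinexMedError, ValueError):
    """Contingency table with a zero expected count."""


class UndefinedRateError(RetinexMedError, ValueError):
    """Confusion matrix with an empty positive or negative margin."""


class AmbiguityError(RetinexMedError, ValueError):
    """No unique integer count vector reproduces the printed percentages."""
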
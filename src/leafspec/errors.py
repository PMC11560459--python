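"""Exception hierarchy for leafspec.

All package errors derive from :class:`LeafspecError` so callers can catch
broadly; subclasses also derive from the closest builtin (ValueError /
RuntimeError) to stay friendly to generic handling.
"""


class LeafspecError(Exception):
    """Base class for all leafspec errors."""


class InvalidGridError(LeafspecError, ValueError):
    """Wavelength grid is empty, non-ascending, or out of range."""


class ConfigError(LeafspecError, ValueError):
    """Inconsistent or invalid configuration."""


class DataError(LeafspecError, ValueError):
    """Malformed or inconsistent input data (parsing, IDs, bounds)."""


class AlignmentError(LeafspecError, ValueError):
    """Objects that must share a grid or sample set do not."""


class DomainError(LeafspecError, ValueError):
    """Numeric argument outside the mathematical domain of an operation."""


class StateError(LeafspecError, RuntimeError):
    """Operation requires state (e.g. retained residuals) that is missing."""
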
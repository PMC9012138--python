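"""Exception hierarchy shared across the package.

Each family maps to a distinct process exit code in the command-line
interface (usage/domain -> 2, schema -> 3, numerical -> 4).
"""


class OxycapError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OxycapError, ValueError):
    """A physical or mathematical precondition was violated."""


class CalibrationError(DomainError):
    """Baseline calibration impossible (e.g. non-positive PO2 gradient)."""


class NumericalError(OxycapError, RuntimeError):
    """A numerical routine failed to converge or produced a degenerate fit."""


class SchemaError(OxycapError, ValueError):
    """An input table does not match its declared schema."""


class UsageError(OxycapError, ValueError):
    """The caller asked for something the API does not support."""
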
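"""Exception hierarchy.

All user-facing errors derive from :class:`GestnetError` (a ``ValueError``)
so callers can catch one type at pipeline/CLI boundaries.
"""


class GestnetError(ValueError):
    """Base class for all gestnet data and input errors."""


class InputError(GestnetError):
    """Malformed or inconsistent input (bad enum value, unknown individual, ...)."""


class LabelMismatchError(InputError):
    """Matrices or tables that should share an individual label set do not."""


class SizeError(InputError):
    """Problem size too small (or too large) for the requested operation."""


class DegenerateInputError(GestnetError):
    """Statistically degenerate input: constant column, zero-variance matrix, ..."""
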
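"""Exception hierarchy for plbin.

Errors are split by contract: bad user input (:class:`InputError`), unknown
or mismatched identifiers (:class:`IdentifierError`), models that cannot be
applied (:class:`DegenerateModelError`), and malformed files
(:class:`FormatError`).
"""


class PlbinError(Exception):
    """Base class for all plbin errors."""


class InputError(PlbinError, ValueError):
    """Raised when an argument violates an operation's precondition."""


class IdentifierError(PlbinError, KeyError):
    """Raised when a gene/sample identifier is unknown or duplicated."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return str(self.args[0]) if self.args else ""


class DegenerateModelError(PlbinError, ValueError):
    """Raised when a fitted model is unusable (e.g. zero-width normal range)."""


class FormatError(PlbinError, ValueError):
    """Raised on malformed input files (matrices, GMT, edge lists)."""
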
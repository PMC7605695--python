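"""Exception hierarchy for triadscope.

All validation and usage failures raise subclasses of :class:`TriadscopeError`
so callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class TriadscopeError(Exception):
    """Base class for all triadscope errors."""


class SchemaError(TriadscopeError):
    """A file is missing a required column or section."""


class ValidationError(TriadscopeError):
    """A value violates a domain invariant (range, uniqueness, consistency)."""


class ShapeError(TriadscopeError):
    """A matrix is not square or has the wrong dimensions."""


class AlignmentError(TriadscopeError):
    """Two networks or a network and roster do not share an actor order."""


class DegenerateInputError(TriadscopeError):
    """An operation is undefined on this input (zero triads, zero margin,
    zero-variance vector)."""


class UsageError(TriadscopeError):
    """Arguments outside the operation's contract (unknown level, empty list,
    n too small)."""
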
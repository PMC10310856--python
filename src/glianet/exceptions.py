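"""Exception hierarchy.

All validation failures raise :class:`GlianetError` subclasses so callers can
distinguish bad inputs from genuine bugs.
"""


class GlianetError(Exception):
    """Base class for all glianet errors."""


class ValidationError(GlianetError, ValueError):
    """Malformed or out-of-range input data."""


class EmptyResultError(GlianetError, ValueError):
    """An operation produced (or would operate on) an empty result."""


class ConvergenceError(GlianetError, RuntimeError):
    """An iterative procedure failed to converge; the message reports the residual."""
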
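"""Exception types shared across the package."""


class ParadetectError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ParadetectError, ValueError):
    """An input violates a documented precondition (domain error)."""


class RankDeficientError(InvalidInputError):
    """A design matrix is rank deficient; the message names the aliased column."""


class ModelFitError(ParadetectError, RuntimeError):
    """A likelihood fit is degenerate or cannot be evaluated."""
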
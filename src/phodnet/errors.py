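"""Exception hierarchy shared across the package."""


class PhodnetError(Exception):
    """Base class for all package errors."""


class FormatError(PhodnetError):
    """A file does not conform to the expected tabular/graph layout."""


class ValidationError(PhodnetError):
    """Input data violate a documented precondition or invariant."""


class GenerationError(PhodnetError):
    """The synthetic generator cannot realize the requested structure."""


class ConvergenceError(PhodnetError):
    """An iterative algorithm failed to converge on degenerate input."""
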
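"""Exception hierarchy shared across the package."""


class IdpdynError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IdpdynError):
    """A file could not be interpreted (atom-count mismatch, truncation, ...)."""


class ValidationError(IdpdynError):
    """An input value violates a documented precondition or invariant."""


class DegenerateInputError(IdpdynError):
    """The input is formally valid but carries no usable signal (e.g. zero variance)."""


class FitError(IdpdynError):
    """A nonlinear fit failed to converge from every start."""
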
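"""Exception types raised across the pipeline.

All inherit from :class:`DaboldError` (itself a ``ValueError``) so callers can
catch everything from this package with one clause while still getting
sensible behaviour from code that only knows about ``ValueError``.
"""


class DaboldError(ValueError):
    """Base class for all errors raised by dabold."""


class InvalidSpecError(DaboldError):
    """A frame-schedule or configuration specification is malformed."""


class InsufficientFramesError(DaboldError):
    """Too few frames remain after the fit-window cut for a stable fit."""


class DivisionByZeroActivityError(DaboldError):
    """A target TAC frame is zero inside the Logan fit window."""


class EmptyRoiError(DaboldError):
    """A region of interest contains no voxels."""


class SingularFitError(DaboldError):
    """All EM restarts collapsed to a degenerate mixture solution."""


class NotConvergedError(DaboldError):
    """An iterative fit did not converge and no usable result exists."""


class ConfigValidationError(DaboldError):
    """A pipeline configuration failed schema validation."""
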
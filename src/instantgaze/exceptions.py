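"""Exception hierarchy shared across the package."""


class InstantGazeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(InstantGazeError, ValueError):
    """An input violated a documented precondition or invariant."""


class MissingOriginError(ValidationError):
    """A corner/local space feature was requested without a session origin."""


class OriginAlreadySetError(ValidationError):
    """The per-session origin is immutable once captured."""


class NoSolutionError(InstantGazeError):
    """No admissible root of the inverse gaze model inside the search window."""


class ConditioningError(InstantGazeError):
    """The prior gaze model is too degenerate to invert (near-zero sensitivity)."""
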
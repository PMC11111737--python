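"""Coordinate spaces for eye-feature construction.

A raw fixation measurement consists of a pupil centre ``(x, y)`` and an eye
corner ``(m, n)``, both in video-image pixels with the origin at the image
centre.  Six feature representations can be built from such a measurement,
differing in the origin(s) the pupil and corner are referenced to:

================  =============================================  ==================
space             feature ``(e1, e2, e3, e4)``                   origin(s)
================  =============================================  ==================
global_absolute   ``(x, y, m, n)``                               global image
global_relative   ``(x - m, y - n, m, n)``                       global image
corner_absolute   ``(x - m0, y - n0, m - m0, n - n0)``           first eye corner
corner_relative   ``(x - m, y - n, m - m0, n - n0)``             first eye corner
local_absolute    ``(x - x0, y - y0, m - m0, n - n0)``           first pupil+corner
local_relative    ``(dx, dy, m - m0, n - n0)``                   first pupil+corner
================  =============================================  ==================

with ``dx = (x - x0) - (m - m0)`` and ``dy = (y - y0) - (n - n0)``: the
pupil pose relative to the eye corner, both indexed to their own first
recorded positions.  ``(x0, y0, m0, n0)`` is the per-session origin captured
from the first measured fixation and immutable afterwards.

The local-relative representation removes both the per-subject anatomical
disposition of the eye features and common-mode head translation, which is
what lets a gaze model trained on other subjects transfer to a new one
without calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

from .exceptions import MissingOriginError, OriginAlreadySetError, ValidationError

__all__ = [
    "SpaceKind",
    "RawObservation",
    "SessionOrigin",
    "FeatureVector",
    "OriginTracker",
    "requires_origin",
    "make_feature",
    "capture_origin",
]


class SpaceKind(str, Enum):
    """The six eye-feature coordinate spaces."""

    GLOBAL_ABSOLUTE = "global_absolute"
    GLOBAL_RELATIVE = "global_relative"
    CORNER_ABSOLUTE = "corner_absolute"
    CORNER_RELATIVE = "corner_relative"
    LOCAL_ABSOLUTE = "local_absolute"
    LOCAL_RELATIVE = "local_relative"


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value):
            raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class RawObservation:
    """One fixation's measured pupil/corner coordinates plus optional target.

    Coordinates are continuous (sub-pixel) video-image pixels with the origin
    at the image centre.  ``target``, when known, is the fixated on-screen
    point ``(tx, ty)`` in screen pixels with the origin at the screen centre.
    """

    pupil_x: float
    pupil_y: float
    corner_m: float
    corner_n: float
    target: Optional[Tuple[float, float]] = None
    fixation_index: int = 0
    subject_id: str = ""
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(
            pupil_x=self.pupil_x,
            pupil_y=self.pupil_y,
            corner_m=self.corner_m,
            corner_n=self.corner_n,
        )
        if self.target is not None:
            _require_finite(tx=self.target[0], ty=self.target[1])
        if self.fixation_index < 0:
            raise ValidationError("fixation_index must be >= 0")


@dataclass(frozen=True)
class SessionOrigin:
    """Per-session feature origin: first pupil ``(x0, y0)`` and corner ``(m0, n0)``."""

    x0: float
    y0: float
    m0: float
    n0: float

    def __post_init__(self) -> None:
        _require_finite(x0=self.x0, y0=self.y0, m0=self.m0, n0=self.n0)


@dataclass(frozen=True)
class FeatureVector:
    """A 4-component eye feature in a declared coordinate space.

    ``(e1, e2)`` carry gaze direction, ``(e3, e4)`` carry head position.
    """

    e1: float
    e2: float
    e3: float
    e4: float
    space: SpaceKind

    def __post_init__(self) -> None:
        _require_finite(e1=self.e1, e2=self.e2, e3=self.e3, e4=self.e4)

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.e1, self.e2, self.e3, self.e4)


def requires_origin(space: SpaceKind) -> bool:
    """Whether a space references the per-session origin (corner and local spaces)."""
    return space in (
        SpaceKind.CORNER_ABSOLUTE,
        SpaceKind.CORNER_RELATIVE,
        SpaceKind.LOCAL_ABSOLUTE,
        SpaceKind.LOCAL_RELATIVE,
    )


def make_feature(
    space: SpaceKind,
    obs: RawObservation,
    origin: Optional[SessionOrigin] = None,
) -> FeatureVector:
    """Construct the eye feature for ``obs`` in the requested space.

    ``origin`` is required for the corner and local spaces and ignored for
    the global spaces.
    """
    space = SpaceKind(space)
    if requires_origin(space) and origin is None:
        raise MissingOriginError(f"space {space.value} requires a session origin")

    x, y, m, n = obs.pupil_x, obs.pupil_y, obs.corner_m, obs.corner_n
    if space is SpaceKind.GLOBAL_ABSOLUTE:
        e = (x, y, m, n)
    elif space is SpaceKind.GLOBAL_RELATIVE:
        e = (x - m, y - n, m, n)
    elif space is SpaceKind.CORNER_ABSOLUTE:
        e = (x - origin.m0, y - origin.n0, m - origin.m0, n - origin.n0)
    elif space is SpaceKind.CORNER_RELATIVE:
        e = (x - m, y - n, m - origin.m0, n - origin.n0)
    elif space is SpaceKind.LOCAL_ABSOLUTE:
        e = (x - origin.x0, y - origin.y0, m - origin.m0, n - origin.n0)
    else:  # local_relative
        dx = (x - origin.x0) - (m - origin.m0)
        dy = (y - origin.y0) - (n - origin.n0)
        e = (dx, dy, m - origin.m0, n - origin.n0)
    return FeatureVector(*e, space=space)


def capture_origin(obs: RawObservation) -> SessionOrigin:
    """Copy the first fixation's measured coordinates into a session origin."""
    return SessionOrigin(obs.pupil_x, obs.pupil_y, obs.corner_m, obs.corner_n)


class OriginTracker:
    """One-shot origin holder enforcing the set-exactly-once session contract."""

    def __init__(self) -> None:
        self._origin: Optional[SessionOrigin] = None

    @property
    def origin(self) -> Optional[SessionOrigin]:
        return self._origin

    def capture(self, obs: RawObservation) -> SessionOrigin:
        if self._origin is not None:
            raise OriginAlreadySetError("session origin already captured")
        self._origin = capture_origin(obs)
        return self._origin
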
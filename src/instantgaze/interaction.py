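"""Dwell-time target selection and the boundary-distance gaze-error metric.

An interactive target is a disc-shaped visual object inside a larger,
invisible bounding collider.  While the estimated gaze stays inside the
collider the dwell timer accumulates and the visual object shrinks (down to
half size) as feedback; the collider itself never changes.  When the dwell
time exceeds a threshold (1.8 s by default) the target's event triggers and
the fixation can be recorded as a confirmed (feature, target) pair.  Leaving
the collider fully resets the timer.

Gaze error is measured to the visual object's *boundary*, not its centre —
a gaze can legitimately rest anywhere on the visible disc — and is expressed
as a fraction of the screen width:

    error = max(0, ||gaze - centre|| - R_visual) / width_px
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

from .engine import ScreenGeometry
from .exceptions import ValidationError
from .model import ScreenPoint

__all__ = [
    "InteractiveTarget",
    "DwellState",
    "TriggerRecord",
    "step_dwell",
    "gaze_error",
    "error_to_degrees",
    "DEFAULT_DWELL_THRESHOLD_S",
    "DEFAULT_VISUAL_RADIUS_FRACTION",
    "DEFAULT_COLLIDER_RATIO",
]

#: Dwell threshold in seconds before a target's event triggers.
DEFAULT_DWELL_THRESHOLD_S = 1.8
#: Default visual-object radius as a fraction of the screen width.
DEFAULT_VISUAL_RADIUS_FRACTION = 0.10
#: Default collider radius as a multiple of the visual radius.
DEFAULT_COLLIDER_RATIO = 1.25


@dataclass(frozen=True)
class InteractiveTarget:
    """A disc target: visible object of radius ``visual_radius`` inside a collider."""

    center: ScreenPoint
    visual_radius: float
    collider_radius: float
    event_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", ScreenPoint(*self.center))
        if not (0 < self.visual_radius <= self.collider_radius):
            raise ValidationError("require 0 < visual_radius <= collider_radius")

    @classmethod
    def at(
        cls,
        center: Tuple[float, float],
        screen: Optional[ScreenGeometry] = None,
        event_id: str = "",
        visual_fraction: float = DEFAULT_VISUAL_RADIUS_FRACTION,
        collider_ratio: float = DEFAULT_COLLIDER_RATIO,
    ) -> "InteractiveTarget":
        """Build a default-sized target at ``center`` for a given screen."""
        screen = screen or ScreenGeometry()
        r = visual_fraction * screen.width_px
        return cls(ScreenPoint(*center), r, collider_ratio * r, event_id)


@dataclass(frozen=True)
class DwellState:
    """Progress of a dwell on a single target."""

    engaged: bool = False
    dwell_elapsed: float = 0.0
    shrink_fraction: float = 1.0


@dataclass(frozen=True)
class TriggerRecord:
    """Emitted when the dwell threshold is exceeded on a target."""

    event_id: str
    gaze: ScreenPoint
    target_center: ScreenPoint
    trigger_time: float
    sample: Optional[object] = None  # caller-attached (feature, target) pair


def step_dwell(
    state: DwellState,
    gaze: ScreenPoint,
    target: InteractiveTarget,
    dt: float,
    threshold: float = DEFAULT_DWELL_THRESHOLD_S,
    *,
    time_s: float = 0.0,
    sample: Optional[object] = None,
) -> Tuple[DwellState, Optional[TriggerRecord]]:
    """Advance the dwell state by one gaze sample of duration ``dt``.

    Inside the collider the timer accumulates and the visual object shrinks
    linearly from full size toward 50% as the threshold approaches; outside,
    the state resets completely.  Returns the new state and, when the
    accumulated dwell reaches ``threshold``, a :class:`TriggerRecord` (the
    state resets after a trigger).
    """
    if not dt > 0:
        raise ValidationError("dt must be positive")
    gaze = ScreenPoint(*gaze)
    dist = math.hypot(gaze.gx - target.center.gx, gaze.gy - target.center.gy)
    if dist > target.collider_radius:
        return DwellState(), None
    elapsed = state.dwell_elapsed + dt
    if elapsed >= threshold:
        record = TriggerRecord(
            event_id=target.event_id,
            gaze=gaze,
            target_center=target.center,
            trigger_time=time_s,
            sample=sample,
        )
        return DwellState(), record
    shrink = 1.0 - 0.5 * min(elapsed / threshold, 1.0)
    return DwellState(engaged=True, dwell_elapsed=elapsed, shrink_fraction=shrink), None


def gaze_error(
    gaze: ScreenPoint, target: InteractiveTarget, screen: Optional[ScreenGeometry] = None
) -> float:
    """Distance from the gaze to the visual-object boundary, / screen width.

    Zero on the closed visual disc, ``(d - R_visual) / width_px`` outside.
    """
    screen = screen or ScreenGeometry()
    gaze = ScreenPoint(*gaze)
    dist = math.hypot(gaze.gx - target.center.gx, gaze.gy - target.center.gy)
    return max(0.0, dist - target.visual_radius) / screen.width_px


def error_to_degrees(fraction: float, screen: Optional[ScreenGeometry] = None) -> float:
    """Convert a fraction-of-screen-width error into visual degrees."""
    screen = screen or ScreenGeometry()
    return math.degrees(
        math.atan(fraction * screen.physical_width_mm / screen.viewing_distance_mm)
    )
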
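"""Synthetic subjects and gaze sessions with realistic cross-subject structure.

The generator emulates the statistical structure a regression gaze tracker
faces in practice:

* **Anatomical offsets** — each subject's pupil and eye corner rest at a
  different place in the camera image (tens of pixels of spread across
  subjects), and the pupil-to-corner vector itself differs between faces.
* **Oculomotor gain** — eye rotation toward a screen target moves the pupil
  by ``gain`` pixels per screen pixel of target offset; gains differ a little
  between subjects (eye geometry, camera placement).
* **Head translation** — a clamped random walk, common-mode on pupil and
  corner, with a bounded total excursion (default 120 px ≡ 30 mm at
  4 px/mm, matching a head restrained in a coil).  A small ``rot_gain``
  couples head shift into the pupil-corner vector, mimicking the apparent
  rotation a translated eye undergoes relative to a fixed camera.
* **Measurement noise** — i.i.d. Gaussian pixel noise on all coordinates.

The forward observation model is, per axis::

    corner = base_corner + head + noise
    pupil  = base_pupil  + head + rot_gain*head + disp(t) + cubic*t^3 + noise

where ``disp(t)`` is the pupil displacement produced by fixating target
offset ``t``.  Each subject's displacement-to-target response is a genuine
quadratic, ``t = disp/gain + quad*disp^2``, and ``disp(t)`` is its exact
inverse (to quadratic order this is the familiar series
``gain*t - quad*gain^3*t^2 + ...``).  Two consequences matter:

* for a single subject with the head still, the feature-to-target relation
  is *exactly* inside the quadratic model family the estimator fits, in any
  coordinate space — a shifted parabola is still a parabola;
* across subjects, the parabolas are shifted by each subject's anatomical
  offset.  One global quadratic cannot fit several shifted parabolas (the
  correction would need an ``e1*e3`` cross term the design row does not
  have), so absolute-space priors transfer poorly while locally-aligned
  features expose the shared response — the effect the local-relative
  representation exists to exploit.

``quad``'s population curvature defaults to 10% of the target extent at the
screen edge; ``cubic`` defaults to zero and is a misspecification knob.

Session scripts mirror the study protocol: a 9-point calibration pattern
(centre first — the first fixation doubles as the session origin), a 4 x 7
grid of interaction targets for free play, and session lengths of 40-107
fixations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .engine import ScreenGeometry
from .exceptions import ValidationError
from .model import ScreenPoint
from .spaces import RawObservation

__all__ = [
    "VariationConfig",
    "SubjectProfile",
    "SessionScript",
    "SimulatedSession",
    "generate_subject",
    "forward_observe",
    "simulate_session",
    "generate_cohort",
    "grid_targets",
    "calibration_9pt",
    "free_play_script",
    "calibration_samples",
    "full_trial",
]

#: Pixels of eye-corner motion per millimetre of head translation.
PX_PER_MM = 4.0
#: Seconds between consecutive fixation samples in simulated sessions.
FIXATION_PERIOD_S = 2.0
#: Reference target extent (screen px) at which curvature fractions are quoted.
REF_TARGET_EXTENT = 400.0


@dataclass(frozen=True)
class VariationConfig:
    """Population distributions the subject generator draws from.

    All positions/spreads are video-image pixels; gains are pixels of pupil
    motion per screen pixel of target offset.
    """

    base_corner_mean: Tuple[float, float] = (0.0, 0.0)
    base_corner_sd: Tuple[float, float] = (40.0, 25.0)
    anat_offset_mean: Tuple[float, float] = (30.0, -5.0)  # pupil minus corner
    anat_offset_sd: Tuple[float, float] = (12.0, 8.0)
    gain_x_mean: float = 0.09
    gain_x_sd: float = 0.008
    gain_y_mean: float = 0.10
    gain_y_sd: float = 0.010
    # curvature of the displacement->target response, as a fraction of the
    # target offset at REF_TARGET_EXTENT (dimensionless)
    curve_mean: float = 0.10
    curve_sd: float = 0.02
    cubic_mean: float = 0.0
    cubic_sd: float = 0.0
    rot_gain_mean: float = 0.10
    rot_gain_sd: float = 0.02
    noise_sd: float = 0.5
    head_step_sd: float = 4.0
    head_limit: float = 30.0 * PX_PER_MM  # excursion bound around the start posture, px
    # initial head posture offset per session (head placement varies between
    # trials even for the same rig), px
    posture_sd: float = 40.0

    def scaled(self, factor: float) -> "VariationConfig":
        """Scale every between-subject spread by ``factor`` (0 = identical subjects)."""
        return replace(
            self,
            base_corner_sd=tuple(s * factor for s in self.base_corner_sd),
            anat_offset_sd=tuple(s * factor for s in self.anat_offset_sd),
            gain_x_sd=self.gain_x_sd * factor,
            gain_y_sd=self.gain_y_sd * factor,
            curve_sd=self.curve_sd * factor,
            cubic_sd=self.cubic_sd * factor,
            rot_gain_sd=self.rot_gain_sd * factor,
        )


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated subject's anatomy, oculomotor response and noise levels.

    ``quad_x``/``quad_y`` are the quadratic coefficients of the subject's
    displacement-to-target response ``t = d/gain + quad*d**2`` (screen px per
    video px squared); pupil displacement is the exact inverse of that
    response, so a quadratic gaze model fitted to this subject's own data is
    exact.
    """

    base_pupil: Tuple[float, float]
    base_corner: Tuple[float, float]
    gain_x: float
    gain_y: float
    quad_x: float
    quad_y: float
    cubic_x: float
    cubic_y: float
    rot_gain: float
    noise_sd: float
    head_step_sd: float
    head_limit: float
    posture_sd: float = 0.0
    seed: int = 0
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        if not (self.gain_x > 0 and self.gain_y > 0):
            raise ValidationError("oculomotor gains must be positive")
        if self.noise_sd < 0 or self.head_step_sd < 0 or self.head_limit < 0:
            raise ValidationError("noise and head parameters must be non-negative")


def generate_subject(
    seed: int,
    variation: Optional[VariationConfig] = None,
    subject_id: Optional[str] = None,
) -> SubjectProfile:
    """Draw one subject profile; deterministic given ``seed``."""
    v = variation or VariationConfig()
    rng = np.random.default_rng(seed)
    corner = rng.normal(v.base_corner_mean, v.base_corner_sd)
    anat = rng.normal(v.anat_offset_mean, v.anat_offset_sd)
    pupil = corner + anat
    gain_x = max(1e-3, rng.normal(v.gain_x_mean, v.gain_x_sd))
    gain_y = max(1e-3, rng.normal(v.gain_y_mean, v.gain_y_sd))
    # convert dimensionless curvature fractions to screen-px / video-px^2
    curve_x = rng.normal(v.curve_mean, v.curve_sd)
    curve_y = rng.normal(v.curve_mean, v.curve_sd)
    quad_x = curve_x / (REF_TARGET_EXTENT * gain_x**2)
    quad_y = curve_y / (REF_TARGET_EXTENT * gain_y**2)
    cubic_x = rng.normal(v.cubic_mean, v.cubic_sd)
    cubic_y = rng.normal(v.cubic_mean, v.cubic_sd)
    rot = rng.normal(v.rot_gain_mean, v.rot_gain_sd)
    return SubjectProfile(
        base_pupil=(float(pupil[0]), float(pupil[1])),
        base_corner=(float(corner[0]), float(corner[1])),
        gain_x=gain_x,
        gain_y=gain_y,
        quad_x=float(quad_x),
        quad_y=float(quad_y),
        cubic_x=float(cubic_x),
        cubic_y=float(cubic_y),
        rot_gain=float(rot),
        noise_sd=v.noise_sd,
        head_step_sd=v.head_step_sd,
        head_limit=v.head_limit,
        posture_sd=v.posture_sd,
        seed=int(seed),
        subject_id=subject_id if subject_id is not None else f"S{seed}",
    )


def _displacement(gain: float, quad: float, t: float) -> float:
    """Invert the quadratic gaze response ``t = d/gain + quad*d**2`` for d.

    Picks the root on the branch continuous with the linear response
    (``d -> gain*t`` as ``quad -> 0``).
    """
    if abs(quad) < 1e-15:
        return gain * t
    disc = 1.0 / gain**2 + 4.0 * quad * t
    if disc < 0:
        raise ValidationError(
            "gaze response not invertible at this target (curvature too strong)"
        )
    return (-1.0 / gain + np.sqrt(disc)) / (2.0 * quad)


def forward_observe(
    profile: SubjectProfile,
    target: ScreenPoint,
    head_offset: Tuple[float, float] = (0.0, 0.0),
    rng: Optional[np.random.Generator] = None,
    *,
    fixation_index: int = 0,
    timestamp: float = 0.0,
) -> RawObservation:
    """Simulate the measured pupil/corner coordinates for one fixation."""
    tx, ty = float(target[0]), float(target[1])
    hx, hy = float(head_offset[0]), float(head_offset[1])
    if rng is not None and profile.noise_sd > 0:
        eps = rng.normal(0.0, profile.noise_sd, size=4)
    else:
        eps = np.zeros(4)
    corner_m = profile.base_corner[0] + hx + eps[2]
    corner_n = profile.base_corner[1] + hy + eps[3]
    pupil_x = (
        profile.base_pupil[0]
        + hx
        + profile.rot_gain * hx
        + _displacement(profile.gain_x, profile.quad_x, tx)
        + profile.cubic_x * tx**3
        + eps[0]
    )
    pupil_y = (
        profile.base_pupil[1]
        + hy
        + profile.rot_gain * hy
        + _displacement(profile.gain_y, profile.quad_y, ty)
        + profile.cubic_y * ty**3
        + eps[1]
    )
    return RawObservation(
        pupil_x=float(pupil_x),
        pupil_y=float(pupil_y),
        corner_m=float(corner_m),
        corner_n=float(corner_n),
        target=(tx, ty),
        fixation_index=fixation_index,
        subject_id=profile.subject_id,
        timestamp=timestamp,
    )


# ---------------------------------------------------------------------------
# Session scripts


@dataclass(frozen=True)
class SessionScript:
    """An ordered list of on-screen targets a subject fixates in turn."""

    targets: List[ScreenPoint]
    kind: str = "free_play"  # calibration_9pt | familiarization_grid | free_play

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", [ScreenPoint(*t) for t in self.targets])
        if self.kind == "calibration_9pt" and len(self.targets) != 9:
            raise ValidationError("calibration_9pt script must have exactly 9 targets")

    def __len__(self) -> int:
        return len(self.targets)


def grid_targets(
    screen: Optional[ScreenGeometry] = None, rows: int = 4, cols: int = 7
) -> List[ScreenPoint]:
    """Cell centres of the rows x cols interaction-target grid (row-major)."""
    screen = screen or ScreenGeometry()
    w, h = screen.width_px, screen.height_px
    return [
        ScreenPoint((c + 0.5) / cols * w - w / 2.0, (r + 0.5) / rows * h - h / 2.0)
        for r in range(rows)
        for c in range(cols)
    ]


def calibration_9pt(
    screen: Optional[ScreenGeometry] = None, margin: float = 0.1
) -> SessionScript:
    """The 3 x 3 explicit-calibration pattern, screen centre displayed first."""
    screen = screen or ScreenGeometry()
    xs = [-(0.5 - margin) * screen.width_px, 0.0, (0.5 - margin) * screen.width_px]
    ys = [-(0.5 - margin) * screen.height_px, 0.0, (0.5 - margin) * screen.height_px]
    pts = [ScreenPoint(x, y) for y in ys for x in xs]
    center = ScreenPoint(0.0, 0.0)
    ordered = [center] + [p for p in pts if p != center]
    return SessionScript(ordered, kind="calibration_9pt")


def free_play_script(
    length: int,
    seed: int,
    screen: Optional[ScreenGeometry] = None,
    rows: int = 4,
    cols: int = 7,
) -> SessionScript:
    """A seeded random walk over the interaction grid (neighbouring cells)."""
    if not 1 <= length:
        raise ValidationError("free-play length must be positive")
    rng = np.random.default_rng(seed)
    grid = grid_targets(screen, rows, cols)
    r, c = int(rng.integers(rows)), int(rng.integers(cols))
    targets = []
    for _ in range(length):
        targets.append(grid[r * cols + c])
        dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
        r = int(np.clip(r + dr, 0, rows - 1))
        c = int(np.clip(c + dc, 0, cols - 1))
    return SessionScript(targets, kind="free_play")


@dataclass(frozen=True)
class SimulatedSession:
    """A subject's full simulated trial: observations with targets attached."""

    observations: List[RawObservation]
    profile: SubjectProfile
    head_track: np.ndarray  # (n_fixations, 2) head offsets, px
    segments: List[str] = field(default_factory=list)  # per-fixation segment label

    def __post_init__(self) -> None:
        if len(self.head_track) != len(self.observations):
            raise ValidationError("head_track length must match observations")
        if self.segments and len(self.segments) != len(self.observations):
            raise ValidationError("segments length must match observations")

    def __len__(self) -> int:
        return len(self.observations)


def simulate_session(
    profile: SubjectProfile,
    script: SessionScript,
    seed: int,
    segments: Optional[List[str]] = None,
) -> SimulatedSession:
    """Run a subject through a script under a clamped head random walk.

    The walk starts at a per-session initial posture (drawn with spread
    ``posture_sd`` — head placement differs between trials) and its
    excursion is clamped to ``head_limit`` around that posture.
    """
    rng = np.random.default_rng(seed)
    n = len(script)
    head = np.zeros((n, 2))
    start = (
        rng.normal(0.0, profile.posture_sd, size=2)
        if profile.posture_sd > 0
        else np.zeros(2)
    )
    pos = start.copy()
    for i in range(n):
        head[i] = pos
        if profile.head_step_sd > 0:
            step = rng.normal(0.0, profile.head_step_sd, size=2)
            pos = np.clip(
                pos + step, start - profile.head_limit, start + profile.head_limit
            )
    noise_rng = rng if profile.noise_sd > 0 else None
    obs = [
        forward_observe(
            profile,
            t,
            (head[i, 0], head[i, 1]),
            noise_rng,
            fixation_index=i,
            timestamp=i * FIXATION_PERIOD_S,
        )
        for i, t in enumerate(script.targets)
    ]
    labels = segments if segments is not None else [script.kind] * n
    return SimulatedSession(obs, profile, head, list(labels))


def generate_cohort(
    n_subjects: int,
    seed: int,
    variation: Optional[VariationConfig] = None,
    screen: Optional[ScreenGeometry] = None,
    free_play_range: Tuple[int, int] = (40, 107),
) -> List[SimulatedSession]:
    """Simulate a cohort: each subject runs 9-pt calibration then free play.

    The first fixation of every session is the screen-centre calibration
    target, so the session origin convention (origin == centre gaze) holds
    by construction.  Free-play lengths are drawn uniformly from
    ``free_play_range`` per subject.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    screen = screen or ScreenGeometry()
    master = np.random.default_rng(seed)
    sessions = []
    for k in range(n_subjects):
        sub_seed = int(master.integers(2**31 - 1))
        profile = generate_subject(sub_seed, variation, subject_id=f"S{k:02d}")
        cal = calibration_9pt(screen)
        length = int(master.integers(free_play_range[0], free_play_range[1] + 1))
        play = free_play_script(length, int(master.integers(2**31 - 1)), screen)
        script = SessionScript(cal.targets + play.targets, kind="free_play")
        labels = ["calibration_9pt"] * 9 + ["free_play"] * length
        sessions.append(
            simulate_session(profile, script, int(master.integers(2**31 - 1)), labels)
        )
    return sessions


def calibration_samples(session: SimulatedSession) -> List[RawObservation]:
    """The observations recorded at the 9 calibration-pattern targets."""
    return [
        o for o, s in zip(session.observations, session.segments) if s == "calibration_9pt"
    ]


def full_trial(session: SimulatedSession) -> List[RawObservation]:
    """The complete time series for the session (calibration + interaction)."""
    return list(session.observations)
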
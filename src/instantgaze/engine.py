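"""Session lifecycle: prior models, instant initialization and adaptive refits.

A session replaces explicit per-user calibration with a *prior model* — eye
feature/target pairs pooled from previously recorded subjects.  The session
origin is captured from the user's first fixation on a single on-screen
target.  If that target is the screen centre the first fixation maps to the
zero feature directly; if it is an arbitrary target ``t_a``, the pupil
coordinates ``(x0, y0)`` that *would* correspond to the screen centre are
reconstructed by inverting the prior model,

    (x0, y0) = (x, y) - f^-1(t_a),

holding the head components at zero (the head pose at the first fixation
defines ``(m0, n0)``).  The inverse is solved numerically to a residual of
1e-8 with a damped least-squares iteration, multi-started across the search
window; because the model is quadratic there may be several roots, and only
roots inside a 200 x 200 px window centred on the measured pupil position
are admissible (the window reflects the extent of the eye region in the
camera image).  If several admissible roots exist, the one nearest the
measured pupil position is chosen.

During use, confirmed fixations (e.g. dwell-triggered selections) are
appended with a weight much larger than the prior samples' (default ratio
100:1) and the model is refit after every accepted sample, so the current
user's data rapidly dominates the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConditioningError, NoSolutionError, ValidationError
from .model import (
    Coefficients,
    FixationSample,
    ScreenPoint,
    TrainingSet,
    fit,
    predict,
)
from .spaces import (
    FeatureVector,
    RawObservation,
    SessionOrigin,
    SpaceKind,
    capture_origin,
    make_feature,
)

__all__ = [
    "ScreenGeometry",
    "PriorModel",
    "Session",
    "start_session_center",
    "start_session_arbitrary",
    "reconstruct_center_feature",
    "build_prior",
    "DEFAULT_WEIGHT_RATIO",
]

#: Default ratio of current-user sample weight to prior sample weight.
DEFAULT_WEIGHT_RATIO = 100.0

_LOCAL_SPACES = (SpaceKind.LOCAL_ABSOLUTE, SpaceKind.LOCAL_RELATIVE)


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry used for error metrics and angular conversion.

    Defaults describe an 800 x 372 px display region of physical width
    176 mm viewed from 310 mm, so a target radius of 10% of the screen
    width subtends about 3.3 degrees.
    """

    width_px: float = 800.0
    height_px: float = 372.0
    physical_width_mm: float = 176.0
    viewing_distance_mm: float = 310.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "physical_width_mm", "viewing_distance_mm"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def center(self) -> ScreenPoint:
        return ScreenPoint(0.0, 0.0)


@dataclass(frozen=True)
class PriorModel:
    """Multi-subject fixation samples standing in for per-user calibration."""

    training: TrainingSet
    base_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.base_weight > 0:
            raise ValidationError("base_weight must be positive")
        if len(self.training) < 8:
            raise ValidationError("prior model needs at least 8 samples")
        targets = {tuple(s.target) for s in self.training}
        if len(targets) < 2:
            raise ValidationError("prior model needs at least 2 distinct targets")

    @property
    def space(self) -> SpaceKind:
        return self.training.space

    def weighted_samples(self) -> List[FixationSample]:
        return [
            FixationSample(s.feature, s.target, s.weight * self.base_weight, s.provenance)
            for s in self.training
        ]

    def coefficients(self) -> Coefficients:
        return fit(TrainingSet(self.weighted_samples()))


class Session:
    """Live gaze-estimation state for one user and one camera stream.

    The model invariantly equals ``fit(prior ∪ current_samples)`` with the
    session's weights after every update; refits are from scratch, so the
    result does not depend on update order.
    """

    def __init__(
        self,
        prior: PriorModel,
        origin: SessionOrigin,
        *,
        current_weight: Optional[float] = None,
        adaptive: bool = True,
        screen: Optional[ScreenGeometry] = None,
    ) -> None:
        self.prior = prior
        self.space = prior.space
        self.origin = origin
        self.current_weight = (
            DEFAULT_WEIGHT_RATIO * prior.base_weight if current_weight is None else current_weight
        )
        if not self.current_weight > prior.base_weight:
            raise ValidationError("current_weight must exceed the prior base_weight")
        self.adaptive = adaptive
        self.screen = screen or ScreenGeometry()
        self.current_samples: List[FixationSample] = []
        self.model: Coefficients = prior.coefficients()

    # -- internal -----------------------------------------------------------
    def _refit(self) -> None:
        samples = self.prior.weighted_samples() + self.current_samples
        self.model = fit(TrainingSet(samples))

    def _append(self, feature: FeatureVector, target: ScreenPoint) -> None:
        self.current_samples.append(
            FixationSample(feature, ScreenPoint(*target), self.current_weight, "current")
        )
        self._refit()

    # -- public API ---------------------------------------------------------
    def feature(self, obs: RawObservation) -> FeatureVector:
        return make_feature(self.space, obs, self.origin)

    def estimate(self, obs: RawObservation) -> ScreenPoint:
        """Predict the on-screen gaze point for a raw observation."""
        return predict(self.model, self.feature(obs))

    def update(self, obs: RawObservation, target: ScreenPoint) -> "Session":
        """Absorb a confirmed fixation and refit (no-op in static mode)."""
        if not self.adaptive:
            return self
        self._append(self.feature(obs), ScreenPoint(*target))
        return self


def start_session_center(
    prior: PriorModel,
    first_obs: RawObservation,
    *,
    current_weight: Optional[float] = None,
    adaptive: bool = True,
    screen: Optional[ScreenGeometry] = None,
) -> Session:
    """Start a session from a first fixation on the screen-centre target.

    The session origin is the first fixation itself.  In adaptive sessions
    the pair (feature of the first fixation, screen centre) is absorbed with
    the elevated current-user weight as the first act of the adaptive loop;
    a static session keeps the bare prior fit.
    """
    origin = capture_origin(first_obs)
    session = Session(
        prior, origin, current_weight=current_weight, adaptive=adaptive, screen=screen
    )
    # Absorbing the starting fixation is the first act of the adaptive loop;
    # a static session keeps the bare prior fit (the origin convention is
    # what ties the zero feature to the screen centre).
    if session.adaptive:
        session._append(session.feature(first_obs), ScreenPoint(0.0, 0.0))
    return session


def _inverse_roots(
    coef: Coefficients,
    space: SpaceKind,
    t_a: ScreenPoint,
    window_px: float,
    tol: float,
) -> List[np.ndarray]:
    """All admissible roots d=(dx, dy) of f(dx, dy, 0, 0) = t_a, |d| in window."""
    half = window_px / 2.0

    def residual(d: np.ndarray) -> np.ndarray:
        g = predict(coef, FeatureVector(d[0], d[1], 0.0, 0.0, space))
        return np.array([g.gx - t_a.gx, g.gy - t_a.gy])

    # Linear gaze sensitivity at the origin; a singular Jacobian means the
    # prior has no usable directional response and the inverse is degenerate.
    J0 = np.array([[coef.cx[1], coef.cx[2]], [coef.cy[1], coef.cy[2]]])
    svals = np.linalg.svd(J0, compute_uv=False)
    # a usable gaze model moves the estimate by order screen-px per feature-px;
    # a directionally-degenerate or flat prior cannot be inverted
    if svals[-1] < 1e-6 or svals[0] / max(svals[-1], 1e-300) > 1e8:
        raise ConditioningError("prior model has near-zero gaze sensitivity")

    q = half / 2.0
    starts = [(0.0, 0.0), (q, q), (q, -q), (-q, q), (-q, -q)]
    roots: List[np.ndarray] = []
    for s in starts:
        sol = least_squares(
            residual, np.asarray(s, dtype=float), method="lm", xtol=tol, ftol=tol, gtol=tol
        )
        d = sol.x
        if np.linalg.norm(residual(d)) > 1e-8 * (1.0 + abs(t_a.gx) + abs(t_a.gy)):
            continue
        if abs(d[0]) > half or abs(d[1]) > half:
            continue
        if any(np.linalg.norm(d - r) < 1e-5 for r in roots):
            continue
        roots.append(d)
    return roots


def reconstruct_center_feature(
    prior: PriorModel,
    obs: RawObservation,
    t_a: ScreenPoint,
    window_px: float = 200.0,
    tol: float = 1e-8,
) -> Tuple[float, float]:
    """Reconstruct the centre-gaze pupil position from an arbitrary first target.

    Solves ``f(x - x0, y - y0, 0, 0) = t_a`` for ``(x0, y0)`` under the prior
    model, with the head components pinned at zero (``m = m0``, ``n = n0`` at
    the first fixation).  Only meaningful in the local spaces, where the
    pupil origin enters the feature definition.
    """
    if prior.space not in _LOCAL_SPACES:
        raise ValidationError(
            "centre-feature reconstruction requires a local space prior, got "
            f"{prior.space.value}"
        )
    t_a = ScreenPoint(*t_a)
    coef = prior.coefficients()
    roots = _inverse_roots(coef, prior.space, t_a, window_px, tol)
    if not roots:
        raise NoSolutionError(
            f"no admissible inverse of the prior model for target {tuple(t_a)} "
            f"within the {window_px:g}x{window_px:g} px window"
        )
    # Nearest root to the measured pupil position (smallest |d|).
    d = min(roots, key=lambda r: float(np.linalg.norm(r)))
    return (obs.pupil_x - float(d[0]), obs.pupil_y - float(d[1]))


def build_prior(
    trials: Sequence[Sequence[RawObservation]],
    space: SpaceKind,
    base_weight: float = 1.0,
) -> PriorModel:
    """Pool several subjects' trials into a prior model in the given space.

    For the corner and local spaces, each contributing subject's features are
    referenced to that subject's *own* first fixation (their session origin);
    observations without a known target are skipped.
    """
    samples: List[FixationSample] = []
    for trial in trials:
        if not trial:
            continue
        origin = capture_origin(trial[0])
        for obs in trial:
            if obs.target is None:
                continue
            samples.append(
                FixationSample(
                    make_feature(space, obs, origin),
                    ScreenPoint(*obs.target),
                    1.0,
                    obs.subject_id or "prior",
                )
            )
    return PriorModel(TrainingSet(samples), base_weight=base_weight)


def start_session_arbitrary(
    prior: PriorModel,
    obs: RawObservation,
    t_a: ScreenPoint,
    *,
    window_px: float = 200.0,
    current_weight: Optional[float] = None,
    adaptive: bool = True,
    screen: Optional[ScreenGeometry] = None,
) -> Session:
    """Start a session from a first fixation on an arbitrary target ``t_a``.

    The centre-gaze pupil position is reconstructed by inverting the prior
    model; the session origin is built from the reconstructed pupil position
    and the measured eye corner.  Both the reconstructed sample (zero
    feature -> screen centre) and the measured sample (first-fixation
    feature -> ``t_a``) are appended with the current-user weight.  When the
    two coincide (``t_a`` at the screen centre) the sample is stored once,
    so this construction reduces exactly to :func:`start_session_center`.
    """
    t_a = ScreenPoint(*t_a)
    x0, y0 = reconstruct_center_feature(prior, obs, t_a, window_px=window_px)
    origin = SessionOrigin(x0, y0, obs.corner_m, obs.corner_n)
    session = Session(
        prior, origin, current_weight=current_weight, adaptive=adaptive, screen=screen
    )
    e0 = make_feature(
        session.space,
        RawObservation(x0, y0, obs.corner_m, obs.corner_n),
        origin,
    )
    e1 = session.feature(obs)
    if session.adaptive:
        session._append(e0, ScreenPoint(0.0, 0.0))
        dup = (
            np.linalg.norm(np.subtract(e1.as_tuple(), e0.as_tuple())) < 1e-9
            and abs(t_a.gx) < 1e-9
            and abs(t_a.gy) < 1e-9
        )
        if not dup:
            session._append(e1, t_a)
    return session
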
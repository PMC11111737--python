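"""Experiment harness: session replays, prior-size sweeps and error summaries.

Replays drive the full estimation pipeline over simulated (or logged)
sessions and score every fixation with the boundary-distance gaze error.
Scoring is prequential: in adaptive mode the error at each fixation is
recorded *before* the (observation, target) pair is absorbed, so the model
is never graded on data it has already seen.  Error series are split into
first/second halves by fixation count, and segments are summarised by their
95th-percentile error (linear-interpolation order statistic), mirroring how
gaze-interaction sessions are usually reported.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    PriorModel,
    ScreenGeometry,
    build_prior,
    start_session_arbitrary,
    start_session_center,
)
from .exceptions import ValidationError
from .interaction import (
    DEFAULT_COLLIDER_RATIO,
    DEFAULT_VISUAL_RADIUS_FRACTION,
    InteractiveTarget,
    gaze_error,
)
from .model import ScreenPoint
from .spaces import SpaceKind, capture_origin, make_feature
from .synthetic import SimulatedSession, full_trial

logger = logging.getLogger(__name__)

__all__ = [
    "percentile",
    "run_session_replay",
    "cohort_replay",
    "prior_sweep",
    "arbitrary_target_experiment",
    "feature_dispersion",
    "compare_distributions",
    "RankSumResult",
]


def percentile(errors: Sequence[float], q: float) -> float:
    """Linear-interpolation order-statistic percentile of an error sample."""
    arr = np.asarray(list(errors), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot take a percentile of an empty sequence")
    return float(np.percentile(arr, q, method="linear"))


def _target_at(t: ScreenPoint, screen: ScreenGeometry, visual_fraction: float) -> InteractiveTarget:
    r = visual_fraction * screen.width_px
    return InteractiveTarget(ScreenPoint(*t), r, DEFAULT_COLLIDER_RATIO * r)


def run_session_replay(
    prior: PriorModel,
    session: SimulatedSession,
    mode: str = "adaptive",
    *,
    screen: Optional[ScreenGeometry] = None,
    visual_fraction: float = DEFAULT_VISUAL_RADIUS_FRACTION,
    current_weight: Optional[float] = None,
) -> pd.DataFrame:
    """Replay one session against a prior model and score every fixation.

    The session starts from its first fixation via the screen-centre
    convention.  Each later fixation is estimated, scored against its known
    target and — in adaptive mode — then absorbed into the model.  Returns a
    tidy frame with columns ``subject_id, fixation_index, error, half,
    space, mode``; halves split at ``ceil(len/2)`` of the scored series.
    """
    if mode not in ("static", "adaptive"):
        raise ValidationError(f"mode must be 'static' or 'adaptive', got {mode!r}")
    screen = screen or ScreenGeometry()
    obs_list = full_trial(session)
    if any(o.target is None for o in obs_list):
        raise ValidationError("replay requires a target for every fixation")
    sess = start_session_center(
        prior,
        obs_list[0],
        adaptive=(mode == "adaptive"),
        screen=screen,
        current_weight=current_weight,
    )
    rows = []
    for obs in obs_list[1:]:
        est = sess.estimate(obs)
        err = gaze_error(est, _target_at(ScreenPoint(*obs.target), screen, visual_fraction), screen)
        rows.append((obs.subject_id, obs.fixation_index, err))
        if mode == "adaptive":
            sess.update(obs, ScreenPoint(*obs.target))
    n = len(rows)
    split = math.ceil(n / 2)
    return pd.DataFrame(
        {
            "subject_id": [r[0] for r in rows],
            "fixation_index": [r[1] for r in rows],
            "error": [r[2] for r in rows],
            "half": ["first" if i < split else "second" for i in range(n)],
            "space": prior.space.value,
            "mode": mode,
        }
    )


def cohort_replay(
    cohort: Sequence[SimulatedSession],
    space: SpaceKind,
    mode: str = "adaptive",
    *,
    screen: Optional[ScreenGeometry] = None,
    base_weight: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-out replay: each subject is scored against a prior built
    from all other subjects' full trials."""
    if len(cohort) < 2:
        raise ValidationError("cohort_replay needs at least 2 subjects")
    frames = []
    for i, session in enumerate(cohort):
        others = [full_trial(s) for j, s in enumerate(cohort) if j != i]
        prior = build_prior(others, space, base_weight)
        frames.append(run_session_replay(prior, session, mode, screen=screen))
    return pd.concat(frames, ignore_index=True)


def prior_sweep(
    cohort: Sequence[SimulatedSession],
    spaces: Sequence[SpaceKind],
    modes: Sequence[str],
    n_values: Sequence[int],
    n_draws: int = 20,
    seed: int = 0,
    *,
    screen: Optional[ScreenGeometry] = None,
) -> pd.DataFrame:
    """Performance as a function of the number of subjects in the prior.

    For each ``n`` in ``n_values``, draws ``n_draws`` random n-subject
    subsets, builds a prior from their full trials, replays every held-out
    subject, and records the 95th-percentile error of each half of each
    held-out session.  Returns a tidy frame with columns
    ``n, draw, space, mode, subject_id, half, p95``.
    """
    N = len(cohort)
    if N < 3:
        raise ValidationError("prior_sweep needs at least 3 subjects")
    for n in n_values:
        if not 1 <= n < N:
            raise ValidationError(f"n={n} must be in [1, {N - 1}]")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        for draw in range(n_draws):
            chosen = rng.choice(N, size=n, replace=False)
            chosen_set = set(int(c) for c in chosen)
            trials = [full_trial(cohort[i]) for i in sorted(chosen_set)]
            for space in spaces:
                prior = build_prior(trials, SpaceKind(space))
                for mode in modes:
                    for i, session in enumerate(cohort):
                        if i in chosen_set:
                            continue
                        series = run_session_replay(prior, session, mode, screen=screen)
                        for half, grp in series.groupby("half"):
                            rows.append(
                                {
                                    "n": n,
                                    "draw": draw,
                                    "space": SpaceKind(space).value,
                                    "mode": mode,
                                    "subject_id": session.profile.subject_id,
                                    "half": half,
                                    "p95": percentile(grp["error"], 95),
                                }
                            )
    return pd.DataFrame(rows)


def space_ranking(
    cohort: Sequence[SimulatedSession],
    spaces: Sequence[SpaceKind],
    *,
    mode: str = "static",
    n_values: Sequence[int] = (2, 3, 5, 7),
    n_draws: int = 6,
    seed: int = 0,
    half: str = "first",
    screen: Optional[ScreenGeometry] = None,
) -> dict:
    """Median held-out error per space, pooled across the prior-size curve.

    For each space, priors of every size in ``n_values`` are drawn
    ``n_draws`` times, every held-out subject is replayed, and the
    ``half``-series per-fixation errors are pooled into one median.  Pooling
    across prior sizes mirrors comparing whole prior-size performance curves
    rather than a single operating point.
    """
    N = len(cohort)
    medians = {}
    for space in spaces:
        rng = np.random.default_rng(seed)
        errs: List[float] = []
        for n in n_values:
            if not 1 <= n < N:
                raise ValidationError(f"n={n} must be in [1, {N - 1}]")
            for _ in range(n_draws):
                chosen = set(int(c) for c in rng.choice(N, size=n, replace=False))
                prior = build_prior(
                    [full_trial(cohort[i]) for i in sorted(chosen)], SpaceKind(space)
                )
                for j, session in enumerate(cohort):
                    if j in chosen:
                        continue
                    series = run_session_replay(prior, session, mode, screen=screen)
                    errs.extend(series[series["half"] == half]["error"])
        medians[SpaceKind(space).value] = float(np.median(errs))
    return medians


def arbitrary_target_experiment(
    cohort: Sequence[SimulatedSession],
    sequence_length: int = 8,
    *,
    space: SpaceKind = SpaceKind.LOCAL_RELATIVE,
    screen: Optional[ScreenGeometry] = None,
    max_windows: Optional[int] = None,
) -> pd.DataFrame:
    """Instant-start robustness to the choice of the initial selection target.

    For each subject (prior = all other subjects, leave-one-out), rolling
    windows of ``sequence_length`` targets are taken from the free-play
    segment, each window starting one target later.  Each window is replayed
    twice in adaptive mode: once bootstrapped from its first target via the
    inverse-model reconstruction (arbitrary start), and once using the
    subject's actual recorded screen-centre fixation as the origin (centre
    start).  Errors are recorded per within-sequence position, together with
    the paired difference.  Sessions shorter than the window are skipped
    with a warning.
    """
    if sequence_length < 2:
        raise ValidationError("sequence_length must be >= 2")
    screen = screen or ScreenGeometry()
    rows = []
    for i, session in enumerate(cohort):
        others = [full_trial(s) for j, s in enumerate(cohort) if j != i]
        prior = build_prior(others, space)
        play = [
            o
            for o, seg in zip(session.observations, session.segments)
            if seg == "free_play"
        ]
        T = len(play)
        if T < sequence_length:
            logger.warning(
                "session %s too short for windows of %d (has %d free-play targets)",
                session.profile.subject_id,
                sequence_length,
                T,
            )
            continue
        n_windows = T - sequence_length + 1
        if max_windows is not None:
            n_windows = min(n_windows, max_windows)
        center_obs = session.observations[0]
        for w in range(n_windows):
            window = play[w : w + sequence_length]
            first = window[0]
            t_first = ScreenPoint(*first.target)
            sess_a = start_session_arbitrary(prior, first, t_first, screen=screen)
            sess_c = start_session_center(prior, center_obs, screen=screen)
            sess_c.update(first, t_first)
            for p, obs in enumerate(window):
                t = ScreenPoint(*obs.target)
                tgt = _target_at(t, screen, DEFAULT_VISUAL_RADIUS_FRACTION)
                err_a = gaze_error(sess_a.estimate(obs), tgt, screen)
                err_c = gaze_error(sess_c.estimate(obs), tgt, screen)
                if p > 0:
                    sess_a.update(obs, t)
                    sess_c.update(obs, t)
                rows.append(
                    {
                        "subject_id": session.profile.subject_id,
                        "window": w,
                        "position": p,
                        "error_arbitrary": err_a,
                        "error_center": err_c,
                        "diff": err_a - err_c,
                    }
                )
    return pd.DataFrame(rows)


def feature_dispersion(
    cohort: Sequence[SimulatedSession], space: SpaceKind
) -> dict:
    """Between- vs within-subject spread of gaze-direction features.

    Each subject's features are referenced to their own session origin, and
    the spread is measured on the gaze-direction components ``(e1, e2)`` —
    the head components ``(e3, e4)`` are shared between several spaces and
    track head state rather than representation quality.  ``between`` is the
    RMS distance of per-subject feature centroids from the grand centroid;
    ``within`` the mean per-subject RMS spread.  A small ``between``
    relative to ``within`` means the representation has collapsed individual
    differences — the property that lets a prior model transfer across
    subjects.
    """
    if len(cohort) < 2:
        raise ValidationError("feature dispersion needs at least 2 subjects")
    centroids = []
    withins = []
    for session in cohort:
        origin = capture_origin(session.observations[0])
        F = np.array(
            [make_feature(space, o, origin).as_tuple()[:2] for o in session.observations]
        )
        centroids.append(F.mean(axis=0))
        withins.append(float(np.sqrt(((F - F.mean(axis=0)) ** 2).sum(axis=1).mean())))
    C = np.array(centroids)
    grand = C.mean(axis=0)
    between = float(np.sqrt(((C - grand) ** 2).sum(axis=1).mean()))
    within = float(np.mean(withins))
    return {
        "space": SpaceKind(space).value,
        "between_subject_spread": between,
        "within_subject_spread": within,
        "ratio": between / within if within > 0 else np.inf,
    }


class RankSumResult(NamedTuple):
    statistic: float
    p_value: float
    median_a: float
    median_b: float


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney U comparison of two error samples."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankSumResult(
        float(res.statistic), float(res.pvalue), float(np.median(a)), float(np.median(b))
    )
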
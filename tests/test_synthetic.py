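import dataclasses

import numpy as np
import pytest

from instantgaze import (
    ScreenPoint,
    SpaceKind,
    capture_origin,
    fit,
    forward_observe,
    generate_cohort,
    generate_subject,
    make_feature,
    predict,
    simulate_session,
)
from instantgaze.model import FixationSample, design_row
from instantgaze.synthetic import (
    SessionScript,
    VariationConfig,
    calibration_9pt,
    calibration_samples,
    free_play_script,
    full_trial,
    grid_targets,
)

QUIET = VariationConfig(noise_sd=0.0, head_step_sd=0.0, posture_sd=0.0)


def test_generate_subject_deterministic():
    a = generate_subject(123)
    b = generate_subject(123)
    assert a == b
    assert generate_subject(124) != a


def test_zero_variation_collapses_population():
    v = VariationConfig().scaled(0.0)
    profiles = [generate_subject(s, v) for s in range(5)]
    assert len({p.base_pupil for p in profiles}) == 1
    assert len({p.gain_x for p in profiles}) == 1


def test_between_subject_spread_exceeds_measurement_noise():
    profiles = [generate_subject(s) for s in range(50)]
    px = np.array([p.base_pupil for p in profiles])
    assert px.std(axis=0).min() > profiles[0].noise_sd


def test_forward_observe_at_rest_returns_base_positions():
    p = generate_subject(5, QUIET)
    obs = forward_observe(p, ScreenPoint(0.0, 0.0))
    assert (obs.pupil_x, obs.pupil_y) == pytest.approx(p.base_pupil)
    assert (obs.corner_m, obs.corner_n) == pytest.approx(p.base_corner)


def test_head_translation_is_common_mode_when_rotation_free():
    p = dataclasses.replace(generate_subject(5, QUIET), rot_gain=0.0)
    t = ScreenPoint(100.0, -50.0)
    a = forward_observe(p, t, head_offset=(0.0, 0.0))
    b = forward_observe(p, t, head_offset=(37.0, -12.0))
    assert (a.pupil_x - a.corner_m) == pytest.approx(b.pupil_x - b.corner_m)
    assert (a.pupil_y - a.corner_n) == pytest.approx(b.pupil_y - b.corner_n)


def test_linear_response_doubles_with_target_when_uncurved():
    p = dataclasses.replace(generate_subject(5, QUIET), quad_x=0.0, quad_y=0.0)
    t1 = forward_observe(p, ScreenPoint(100.0, 60.0))
    t2 = forward_observe(p, ScreenPoint(200.0, 120.0))
    d1 = (t1.pupil_x - p.base_pupil[0], t1.pupil_y - p.base_pupil[1])
    d2 = (t2.pupil_x - p.base_pupil[0], t2.pupil_y - p.base_pupil[1])
    assert d2[0] == pytest.approx(2 * d1[0])
    assert d2[1] == pytest.approx(2 * d1[1])


def test_displacement_inverts_quadratic_gaze_response():
    p = generate_subject(5, QUIET)
    for tx in (-350.0, -10.0, 0.0, 120.0, 390.0):
        obs = forward_observe(p, ScreenPoint(tx, 0.0))
        d = obs.pupil_x - p.base_pupil[0]
        assert d / p.gain_x + p.quad_x * d * d == pytest.approx(tx, abs=1e-9)


def test_head_track_zero_without_steps_or_posture():
    p = generate_subject(5, QUIET)
    sess = simulate_session(p, calibration_9pt(), seed=1)
    assert np.all(sess.head_track == 0)


def test_head_walk_clamped_around_start_posture():
    p = generate_subject(5)
    script = SessionScript([ScreenPoint(0.0, 0.0)] * 5000)
    sess = simulate_session(p, script, seed=2)
    start = sess.head_track[0]
    excursion = np.abs(sess.head_track - start).max()
    assert excursion <= p.head_limit + 1e-9


def test_simulated_session_reproducible():
    p = generate_subject(5)
    s1 = simulate_session(p, calibration_9pt(), seed=3)
    s2 = simulate_session(p, calibration_9pt(), seed=3)
    assert s1.observations == s2.observations
    assert np.array_equal(s1.head_track, s2.head_track)


def test_scripts_have_study_geometry():
    cal = calibration_9pt()
    assert len(cal) == 9
    assert tuple(cal.targets[0]) == (0.0, 0.0)  # centre shown first
    grid = grid_targets()
    assert len(grid) == 28  # 4 x 7
    play = free_play_script(50, seed=1)
    assert len(play) == 50
    assert all(tuple(t) in {tuple(g) for g in grid} for t in play.targets)
    # neighbour walk: consecutive targets at most one cell apart
    w, h = 800 / 7, 372 / 4
    for a, b in zip(play.targets, play.targets[1:]):
        assert abs(a.gx - b.gx) <= w + 1e-9 and abs(a.gy - b.gy) <= h + 1e-9


def test_cohort_structure():
    cohort = generate_cohort(12, seed=3)
    assert len(cohort) == 12
    assert len({s.profile.base_pupil for s in cohort}) == 12
    for sess in cohort:
        assert 9 + 40 <= len(sess) <= 9 + 107
        cal = calibration_samples(sess)
        assert len(cal) == 9
        assert {tuple(o.target) for o in cal} == {
            tuple(t) for t in calibration_9pt().targets
        }
        assert sess.observations[0].target == (0.0, 0.0)
    single = generate_cohort(1, seed=4)
    assert len(single) == 1


def test_single_subject_fit_is_exact_in_every_space():
    """With no noise and no head motion, a single subject's data lies exactly
    inside the quadratic model family in every coordinate space."""
    prof = generate_subject(11, QUIET)
    script = SessionScript(
        calibration_9pt().targets + free_play_script(30, seed=5).targets
    )
    sess = simulate_session(prof, script, seed=6)
    trial = full_trial(sess)
    origin = capture_origin(trial[0])
    for space in SpaceKind:
        train = [
            FixationSample(make_feature(space, o, origin), ScreenPoint(*o.target))
            for o in trial[:20]
        ]
        coef = fit(train)
        for o in trial[20:]:
            g = predict(coef, make_feature(space, o, origin))
            err = np.hypot(g.gx - o.target[0], g.gy - o.target[1])
            assert err < 1e-3


def test_ignoring_head_components_hurts_under_head_motion():
    """rot_gain couples head translation into the gaze components; a model
    denied e3/e4 cannot compensate and must do strictly worse."""
    v = VariationConfig(noise_sd=0.0)
    prof = generate_subject(21, v)
    assert prof.rot_gain > 0
    script = SessionScript(
        calibration_9pt().targets + free_play_script(60, seed=7).targets
    )
    sess = simulate_session(prof, script, seed=8)
    trial = full_trial(sess)
    origin = capture_origin(trial[0])
    feats = [make_feature(SpaceKind.LOCAL_RELATIVE, o, origin) for o in trial]
    full = [FixationSample(f, ScreenPoint(*o.target)) for f, o in zip(feats, trial)]
    blind = [
        FixationSample(
            dataclasses.replace(f, e3=0.0, e4=0.0), ScreenPoint(*o.target)
        )
        for f, o in zip(feats, trial)
    ]

    def holdout_rmse(samples):
        coef = fit(samples[:40])
        errs = [
            np.hypot(
                predict(coef, s.feature).gx - s.target.gx,
                predict(coef, s.feature).gy - s.target.gy,
            )
            for s in samples[40:]
        ]
        return float(np.mean(errs))

    assert holdout_rmse(blind) > holdout_rmse(full)
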
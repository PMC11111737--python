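import numpy as np
import pytest

from instantgaze import (
    Coefficients,
    FeatureVector,
    FixationSample,
    PriorModel,
    RawObservation,
    ScreenPoint,
    SpaceKind,
    TrainingSet,
    fit,
    make_feature,
    predict,
    reconstruct_center_feature,
    start_session_arbitrary,
    start_session_center,
)
from instantgaze.engine import build_prior
from instantgaze.exceptions import (
    ConditioningError,
    NoSolutionError,
    ValidationError,
)
from conftest import make_coefficients, prior_from_coefficients

SP = SpaceKind.LOCAL_RELATIVE
OBS0 = RawObservation(120.0, -40.0, 90.0, -45.0)


def small_prior(rng, space=SP):
    return prior_from_coefficients(make_coefficients(rng, space), rng)


# -- prior validation -------------------------------------------------------


def test_prior_model_invariants(rng):
    f = FeatureVector(1, 2, 3, 4, SP)
    seven = [FixationSample(f, ScreenPoint(i, 0)) for i in range(7)]
    with pytest.raises(ValidationError):
        PriorModel(TrainingSet(seven))
    same_target = [
        FixationSample(FeatureVector(i, 0, 0, 0, SP), ScreenPoint(5, 5))
        for i in range(10)
    ]
    with pytest.raises(ValidationError):
        PriorModel(TrainingSet(same_target))


# -- centre start -----------------------------------------------------------


def test_center_start_first_sample_is_zero_feature_to_center(rng):
    sess = start_session_center(small_prior(rng), OBS0)
    s0 = sess.current_samples[0]
    assert s0.feature.as_tuple() == (0, 0, 0, 0)
    assert tuple(s0.target) == (0, 0)
    assert s0.weight == pytest.approx(100.0)


def test_center_start_prediction_near_center_with_100x_weight(rng):
    sess = start_session_center(small_prior(rng), OBS0)
    g = sess.estimate(OBS0)
    # high current weight pulls the model through (zero feature -> centre)
    assert np.hypot(g.gx, g.gy) < 1.0


def test_static_session_keeps_bare_prior_fit(rng):
    prior = small_prior(rng)
    sess = start_session_center(prior, OBS0, adaptive=False)
    ref = prior.coefficients()
    np.testing.assert_allclose(sess.model.cx, ref.cx)
    np.testing.assert_allclose(sess.model.cy, ref.cy)
    before = sess.model
    sess.update(RawObservation(121.0, -39.0, 90.0, -45.0), ScreenPoint(50, 50))
    assert sess.model is before
    assert sess.current_samples == []


def test_estimate_equals_manual_composition(rng):
    prior = small_prior(rng)
    sess = start_session_center(prior, OBS0)
    obs = RawObservation(131.0, -33.0, 92.0, -44.0)
    expected = predict(sess.model, make_feature(SP, obs, sess.origin))
    assert sess.estimate(obs) == pytest.approx(tuple(expected))


def test_update_refit_is_order_free_and_matches_scratch_fit(rng):
    prior = small_prior(rng)
    sess = start_session_center(prior, OBS0)
    for i in range(6):
        obs = RawObservation(120.0 + 3 * i, -40.0 + 2 * i, 90.0, -45.0)
        sess.update(obs, ScreenPoint(30.0 * i, -20.0 * i))
    scratch = fit(TrainingSet(prior.weighted_samples() + sess.current_samples))
    np.testing.assert_allclose(sess.model.cx, scratch.cx, atol=1e-9)
    np.testing.assert_allclose(sess.model.cy, scratch.cy, atol=1e-9)


def test_double_update_equals_sqrt2_weighted_single(rng):
    prior = small_prior(rng)
    obs = RawObservation(130.0, -35.0, 91.0, -44.0)
    t = ScreenPoint(80.0, -60.0)

    twice = start_session_center(prior, OBS0)
    twice.update(obs, t).update(obs, t)
    assert len(twice.current_samples) == 3  # start sample + two updates

    once = start_session_center(prior, OBS0)
    once.update(obs, t)
    boosted = fit(
        TrainingSet(
            prior.weighted_samples()
            + [once.current_samples[0]]
            + [
                FixationSample(
                    once.current_samples[1].feature, t, np.sqrt(2.0) * 100.0
                )
            ]
        )
    )
    np.testing.assert_allclose(twice.model.cx, boosted.cx, atol=1e-9)
    np.testing.assert_allclose(twice.model.cy, boosted.cy, atol=1e-9)


def test_current_weight_must_exceed_base_weight(rng):
    with pytest.raises(ValidationError):
        start_session_center(small_prior(rng), OBS0, current_weight=0.5)


# -- inverse-model bootstrap ------------------------------------------------


def test_reconstruct_identity_at_center(rng):
    coef = make_coefficients(rng)
    coef = Coefficients(
        np.r_[0.0, coef.cx[1:]], np.r_[0.0, coef.cy[1:]], space=SP
    )  # intercepts 0: zero feature maps to the screen centre
    prior = prior_from_coefficients(coef, rng)
    x0, y0 = reconstruct_center_feature(prior, OBS0, ScreenPoint(0.0, 0.0))
    assert (x0, y0) == pytest.approx((OBS0.pupil_x, OBS0.pupil_y), abs=1e-6)


def test_reconstruct_recovers_forward_constructed_offset(rng):
    for _ in range(10):
        coef = make_coefficients(rng)
        prior = prior_from_coefficients(coef, rng)
        true_d = rng.uniform(-60, 60, size=2)
        t_a = predict(coef, FeatureVector(true_d[0], true_d[1], 0.0, 0.0, SP))
        x0, y0 = reconstruct_center_feature(prior, OBS0, t_a)
        assert x0 == pytest.approx(OBS0.pupil_x - true_d[0], abs=1e-6)
        assert y0 == pytest.approx(OBS0.pupil_y - true_d[1], abs=1e-6)


def test_reconstruct_rejects_unreachable_target(rng):
    coef = make_coefficients(rng)
    prior = prior_from_coefficients(coef, rng)
    # a target far beyond what +-100 px of displacement can reach
    with pytest.raises(NoSolutionError):
        reconstruct_center_feature(prior, OBS0, ScreenPoint(1e5, 1e5))


def test_reconstruct_rejects_gaze_insensitive_prior(rng):
    flat = Coefficients(
        np.r_[5.0, 0, 0, 0, 0, 0, 0.1, 0.1], np.r_[3.0, 0, 0, 0, 0, 0, 0.1, 0.1], SP
    )
    feats = [FeatureVector(*rng.uniform(-40, 40, 4), space=SP) for _ in range(12)]
    prior = PriorModel(
        TrainingSet([FixationSample(f, predict(flat, f)) for f in feats])
    )
    with pytest.raises(ConditioningError):
        reconstruct_center_feature(prior, OBS0, ScreenPoint(0.0, 0.0))


def test_reconstruct_requires_local_space(rng):
    prior = small_prior(rng, SpaceKind.CORNER_RELATIVE)
    with pytest.raises(ValidationError):
        reconstruct_center_feature(prior, OBS0, ScreenPoint(0.0, 0.0))


def test_arbitrary_start_at_center_coincides_with_center_start(rng):
    coef = make_coefficients(rng)
    coef = Coefficients(np.r_[0.0, coef.cx[1:]], np.r_[0.0, coef.cy[1:]], space=SP)
    prior = prior_from_coefficients(coef, rng)
    a = start_session_arbitrary(prior, OBS0, ScreenPoint(0.0, 0.0))
    c = start_session_center(prior, OBS0)
    assert (a.origin.x0, a.origin.y0) == pytest.approx(
        (c.origin.x0, c.origin.y0), abs=1e-6
    )
    np.testing.assert_allclose(a.model.cx, c.model.cx, atol=1e-6)
    np.testing.assert_allclose(a.model.cy, c.model.cy, atol=1e-6)
    assert len(a.current_samples) == len(c.current_samples) == 1


def test_arbitrary_start_origin_matches_forward_construction(rng):
    coef = make_coefficients(rng)
    prior = prior_from_coefficients(coef, rng)
    true_d = rng.uniform(-50, 50, size=2)
    t_a = predict(coef, FeatureVector(true_d[0], true_d[1], 0.0, 0.0, SP))
    sess = start_session_arbitrary(prior, OBS0, t_a)
    assert sess.origin.x0 == pytest.approx(OBS0.pupil_x - true_d[0], abs=1e-6)
    assert sess.origin.y0 == pytest.approx(OBS0.pupil_y - true_d[1], abs=1e-6)
    assert (sess.origin.m0, sess.origin.n0) == (OBS0.corner_m, OBS0.corner_n)
    # both the reconstructed and the measured sample were absorbed
    assert len(sess.current_samples) == 2
    assert tuple(sess.current_samples[0].target) == (0.0, 0.0)
    assert tuple(sess.current_samples[1].target) == pytest.approx(tuple(t_a))


def test_arbitrary_start_failure_creates_no_session(rng):
    prior = prior_from_coefficients(make_coefficients(rng), rng)
    with pytest.raises(NoSolutionError):
        start_session_arbitrary(prior, OBS0, ScreenPoint(1e5, 1e5))


# -- prior building from trials --------------------------------------------


def test_build_prior_uses_each_subjects_own_origin(rng):
    trials = []
    for k in range(2):
        base = 50.0 * k
        trial = [
            RawObservation(
                base + 10 * i, base + 5 * i, base + 2 * i, base + i,
                target=(10.0 * i, -5.0 * i), subject_id=f"S{k}",
            )
            for i in range(5)
        ]
        trials.append(trial)
    prior = build_prior(trials, SP)
    assert len(prior.training) == 10
    # each trial's first observation maps to the zero feature in local space
    firsts = [s for s in prior.training if s.feature.as_tuple() == (0, 0, 0, 0)]
    assert len(firsts) == 2
    assert {s.provenance for s in prior.training} == {"S0", "S1"}
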
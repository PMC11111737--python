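import numpy as np
import pytest

from instantgaze import (
    Coefficients,
    FixationSample,
    FeatureVector,
    PriorModel,
    SpaceKind,
    TrainingSet,
    predict,
)


def make_coefficients(rng: np.random.Generator, space=SpaceKind.LOCAL_RELATIVE) -> Coefficients:
    """Draw gaze-model coefficients at realistic scales: a dominant linear
    gaze term (~11 screen px per feature px), mild curvature and weak head
    terms, so instances look like fitted gaze models."""
    cx = np.array(
        [
            rng.normal(0, 20),
            rng.normal(11, 1),
            rng.normal(0, 0.5),
            rng.normal(0, 0.01),
            rng.normal(0, 0.02),
            rng.normal(0, 0.01),
            rng.normal(0, 0.5),
            rng.normal(0, 0.5),
        ]
    )
    cy = np.array(
        [
            rng.normal(0, 20),
            rng.normal(0, 0.5),
            rng.normal(10, 1),
            rng.normal(0, 0.01),
            rng.normal(0, 0.01),
            rng.normal(0, 0.02),
            rng.normal(0, 0.5),
            rng.normal(0, 0.5),
        ]
    )
    return Coefficients(cx, cy, space=space)


def prior_from_coefficients(
    coef: Coefficients,
    rng: np.random.Generator,
    n: int = 24,
    scale: float = 40.0,
) -> PriorModel:
    """A prior whose weighted fit reproduces ``coef`` exactly (noiseless
    samples in general position)."""
    samples = []
    for _ in range(n):
        f = FeatureVector(*rng.uniform(-scale, scale, size=4), space=coef.space)
        samples.append(FixationSample(f, predict(coef, f), 1.0, "oracle"))
    return PriorModel(TrainingSet(samples))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
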
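"""Fit the quadratic gaze model and read a prediction off it.

The model is g = v.c with v = (1, e1, e2, e1*e2, e1^2, e2^2, e3, e4) and one
8-coefficient vector per screen axis, solved by weighted least squares.
"""

import numpy as np

from instantgaze import (
    FeatureVector,
    FixationSample,
    ScreenPoint,
    SpaceKind,
    fit,
    predict,
)

rng = np.random.default_rng(0)
SP = SpaceKind.LOCAL_RELATIVE

# a synthetic subject: ~11 screen px of gaze per px of pupil displacement,
# mild curvature, small head correction
true_cx = np.array([0.0, 11.0, 0.3, 0.0, 0.03, 0.0, -1.2, 0.0])
true_cy = np.array([0.0, 0.2, 10.0, 0.0, 0.0, 0.03, 0.0, -1.1])

samples = []
for _ in range(20):
    f = FeatureVector(*rng.uniform(-40, 40, 4), space=SP)
    v = np.array([1, f.e1, f.e2, f.e1 * f.e2, f.e1**2, f.e2**2, f.e3, f.e4])
    samples.append(FixationSample(f, ScreenPoint(v @ true_cx, v @ true_cy)))

coef = fit(samples)
print("recovered cx:", np.round(coef.cx, 6))
print("recovered cy:", np.round(coef.cy, 6))
print("max coefficient error:",
      max(np.abs(coef.cx - true_cx).max(), np.abs(coef.cy - true_cy).max()))

f = FeatureVector(10.0, -5.0, 2.0, 0.0, SP)
g = predict(coef, f)
print(f"\npupil displacement (10, -5) px with 2 px head shift"
      f" -> gaze ({g.gx:.1f}, {g.gy:.1f}) screen px")
print("Noiseless samples from a quadratic model are refit exactly, so the"
      " prediction is the generating model's own value.")
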
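"""Quadratic polynomial gaze mapping with weighted least-squares fitting.

The estimated gaze ``g = (gx, gy)`` on the screen is a quadratic polynomial
of the eye feature ``e = (e1, e2, e3, e4)``::

    g = v . c,   v = (1, e1, e2, e1*e2, e1**2, e2**2, e3, e4)

with separate coefficient vectors ``cx = (a0..a7)`` and ``cy = (b0..b7)``
for the two screen axes.  The gaze-direction components enter up to
quadratic order; the head components enter linearly.

Given M fixation samples ``(e_i, t_i)`` with per-sample weights ``w_i``
(diagonal of W), the fit minimises ``||W (V c - T)||^2`` per axis.  With a
full-rank design this equals the weighted normal-equation solution
``c = (V' W'W V)^-1 V' W'W T``; with a rank-deficient design the
minimum-norm least-squares solution is returned, so the model stays
well-defined from the very first sample of a session.  Weights enter the
objective squared, so duplicating a sample is equivalent to multiplying its
weight by sqrt(2).

No conditioning or normalisation of the design matrix is applied before
solving; the solve is a numpy SVD-based ``lstsq`` (or a ridge-regularised
normal-equation solve when ``ridge > 0`` is requested).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, NamedTuple, Optional, Sequence, Union

import numpy as np

from .exceptions import ValidationError
from .spaces import FeatureVector, SpaceKind

__all__ = [
    "ScreenPoint",
    "DESIGN_TERMS",
    "design_row",
    "design_matrix",
    "Coefficients",
    "FixationSample",
    "TrainingSet",
    "fit",
    "predict",
]


class ScreenPoint(NamedTuple):
    """A 2D point in screen pixels, origin at the screen centre."""

    gx: float
    gy: float


#: Term order of the design row v.
DESIGN_TERMS = ("1", "e1", "e2", "e1*e2", "e1^2", "e2^2", "e3", "e4")


def design_row(feature: FeatureVector) -> np.ndarray:
    """Map a feature to the 8-term design row ``v``."""
    e1, e2, e3, e4 = feature.as_tuple()
    row = np.array([1.0, e1, e2, e1 * e2, e1 * e1, e2 * e2, e3, e4])
    if not np.all(np.isfinite(row)):
        raise ValidationError("non-finite feature in design row")
    return row


def design_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    """Stack design rows for a sequence of features into the M x 8 matrix V."""
    return np.vstack([design_row(f) for f in features])


@dataclass(frozen=True)
class Coefficients:
    """The 8+8 gaze-model coefficients, one vector per screen axis."""

    cx: np.ndarray  # (a0..a7)
    cy: np.ndarray  # (b0..b7)
    space: Optional[SpaceKind] = None
    n_samples: int = 0
    weight_scheme: str = "uniform"

    def __post_init__(self) -> None:
        cx = np.asarray(self.cx, dtype=float)
        cy = np.asarray(self.cy, dtype=float)
        if cx.shape != (8,) or cy.shape != (8,):
            raise ValidationError("coefficient vectors must have length 8")
        if not (np.all(np.isfinite(cx)) and np.all(np.isfinite(cy))):
            raise ValidationError("coefficients must be finite")
        object.__setattr__(self, "cx", cx)
        object.__setattr__(self, "cy", cy)

    def to_json(self) -> str:
        payload = {
            "cx": self.cx.tolist(),
            "cy": self.cy.tolist(),
            "space": self.space.value if self.space else None,
            "n_samples": self.n_samples,
            "weight_scheme": self.weight_scheme,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Coefficients":
        d = json.loads(text)
        return cls(
            cx=np.asarray(d["cx"], dtype=float),
            cy=np.asarray(d["cy"], dtype=float),
            space=SpaceKind(d["space"]) if d.get("space") else None,
            n_samples=int(d.get("n_samples", 0)),
            weight_scheme=str(d.get("weight_scheme", "uniform")),
        )


@dataclass(frozen=True)
class FixationSample:
    """A paired (eye feature, on-screen target) measurement with a weight."""

    feature: FeatureVector
    target: ScreenPoint
    weight: float = 1.0
    provenance: str = "current"

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", ScreenPoint(*self.target))
        if not (self.weight > 0 and np.isfinite(self.weight)):
            raise ValidationError("sample weight must be positive and finite")


class TrainingSet:
    """An ordered, space-homogeneous collection of fixation samples."""

    def __init__(self, samples: Iterable[FixationSample]):
        self.samples: List[FixationSample] = list(samples)
        if not self.samples:
            raise ValidationError("training set must contain at least one sample")
        spaces = {s.feature.space for s in self.samples}
        if len(spaces) != 1:
            raise ValidationError(f"mixed coordinate spaces in training set: {spaces}")
        self.space: SpaceKind = next(iter(spaces))

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[FixationSample]:
        return iter(self.samples)

    def design(self) -> np.ndarray:
        return design_matrix([s.feature for s in self.samples])

    def targets(self) -> np.ndarray:
        return np.array([[s.target.gx, s.target.gy] for s in self.samples])

    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.samples])


def fit(training: Union[TrainingSet, Sequence[FixationSample]], ridge: float = 0.0) -> Coefficients:
    """Weighted least-squares fit of the gaze model.

    Minimises ``||W (V c - T)||^2`` for each screen axis (both axes share V
    and W, so they are solved in one call).  ``ridge > 0`` adds an optional
    L2 penalty ``ridge * ||c||^2`` (off by default).
    """
    if not isinstance(training, TrainingSet):
        training = TrainingSet(training)
    V = training.design()
    T = training.targets()
    w = training.weights()
    Vw = V * w[:, None]
    Tw = T * w[:, None]
    if ridge > 0.0:
        A = Vw.T @ Vw + ridge * np.eye(8)
        c = np.linalg.solve(A, Vw.T @ Tw)
    else:
        c, *_ = np.linalg.lstsq(Vw, Tw, rcond=None)
    uniform = bool(np.all(w == w[0]))
    return Coefficients(
        cx=c[:, 0],
        cy=c[:, 1],
        space=training.space,
        n_samples=len(training),
        weight_scheme="uniform" if uniform else "per-sample",
    )


def predict(c: Coefficients, feature: FeatureVector) -> ScreenPoint:
    """Evaluate the gaze model at a feature: ``g = v . c``."""
    v = design_row(feature)
    return ScreenPoint(float(v @ c.cx), float(v @ c.cy))
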
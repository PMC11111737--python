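"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written along a different computational path
from the library: explicit normal equations instead of lstsq, term-by-term
summation instead of vector dot products, exhaustive grid search instead of
damped iteration, and a sort-based percentile.
"""

import numpy as np
from scipy.optimize import least_squares

from instantgaze import Coefficients, FeatureVector, SpaceKind


def normal_equation_fit(V: np.ndarray, T: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Literal weighted normal equations c = (V'W'WV)^-1 V'W'W T."""
    W2 = np.diag(w**2)
    return np.linalg.solve(V.T @ W2 @ V, V.T @ W2 @ T)


def manual_predict(coef: Coefficients, f: FeatureVector) -> tuple:
    """Term-by-term evaluation of g = v.c."""
    e1, e2, e3, e4 = f.as_tuple()
    terms = [1.0, e1, e2, e1 * e2, e1**2, e2**2, e3, e4]
    gx = sum(t * c for t, c in zip(terms, coef.cx))
    gy = sum(t * c for t, c in zip(terms, coef.cy))
    return gx, gy


def sort_percentile(values, q):
    """Linear-interpolation percentile from first principles on sorted data."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 1:
        return float(v[0])
    pos = (q / 100.0) * (v.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def grid_inverse(
    coef: Coefficients,
    t_a,
    window: float = 200.0,
    step: float = 0.1,
    space: SpaceKind = SpaceKind.LOCAL_RELATIVE,
):
    """Exhaustive 0.1 px grid search for roots of f(dx, dy, 0, 0) = t_a,
    refined by local polish; returns the admissible root nearest the
    measured pupil position (smallest |d|), or None."""
    half = window / 2.0
    xs = np.arange(-half, half + step / 2, step)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    a, b = coef.cx, coef.cy
    gx = a[0] + a[1] * X + a[2] * Y + a[3] * X * Y + a[4] * X**2 + a[5] * Y**2
    gy = b[0] + b[1] * X + b[2] * Y + b[3] * X * Y + b[4] * X**2 + b[5] * Y**2
    r = np.hypot(gx - t_a[0], gy - t_a[1])
    # near-root grid cells; at 0.1 px resolution a true root's nearest grid
    # point has residual of at most ~|J| * 0.1, so a few px is a safe net
    mask = r < 5.0
    if not mask.any():
        return None
    pts = np.column_stack([X[mask], Y[mask]])
    res = r[mask]
    # cluster near-root points and polish each cluster's argmin
    roots = []
    order = np.argsort(res)
    used = np.zeros(len(pts), dtype=bool)
    for idx in order:
        if used[idx]:
            continue
        close = np.linalg.norm(pts - pts[idx], axis=1) < 2.0
        used |= close

        def resid(d):
            e = FeatureVector(d[0], d[1], 0.0, 0.0, space)
            return np.array(
                [
                    manual_predict(coef, e)[0] - t_a[0],
                    manual_predict(coef, e)[1] - t_a[1],
                ]
            )

        sol = least_squares(resid, pts[idx], method="lm", xtol=1e-12, ftol=1e-12)
        d = sol.x
        if (
            np.linalg.norm(resid(d)) < 1e-8 * (1 + abs(t_a[0]) + abs(t_a[1]))
            and abs(d[0]) <= half
            and abs(d[1]) <= half
        ):
            if not any(np.linalg.norm(d - q) < 1e-5 for q in roots):
                roots.append(d)
    if not roots:
        return None
    return min(roots, key=lambda d: float(np.linalg.norm(d)))
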
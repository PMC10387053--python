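"""Locally weighted polynomial regression (LOESS) with tricube weights.

Small, deterministic implementation suited to smoothing a handful of depth
means and evaluating the fit on an arbitrary prediction grid, including
beyond the deepest measured point (the boundary local fit simply extends).
statsmodels' ``lowess`` cannot predict off the training grid or fit local
degree 0/2, hence this purpose-built smoother; the two agree at degree 1
with span 1 on the training points (checked in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Loess", "fit_loess"]


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube kernel (1 − u³)³ on [0, 1), zero outside."""
    u = np.abs(u)
    w = (1.0 - u**3) ** 3
    w[u >= 1.0] = 0.0
    return w


@dataclass(frozen=True)
class Loess:
    """A fitted LOESS smoother.

    At each target point the ``q = floor(span · n)`` nearest observations
    receive tricube weights on distance scaled by the q-th nearest distance
    (Cleveland's convention; for span > 1 the scale is stretched by the
    span), and a weighted polynomial of the given degree is solved by
    least squares.  Deterministic; no randomness anywhere.
    """

    x: np.ndarray
    y: np.ndarray
    span: float
    degree: int

    def predict(self, x_new) -> np.ndarray:
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        out = np.empty_like(x_new)
        n = len(self.x)
        q = min(int(np.floor(self.span * n)), n)
        for k, x0 in enumerate(x_new):
            d = np.abs(self.x - x0)
            d_sorted = np.sort(d)
            d_q = d_sorted[q - 1]
            if self.span > 1.0:
                d_q *= self.span
            if d_q == 0.0:  # all points at the target: plain weighted mean
                w = np.ones(n)
            else:
                w = tricube(d / d_q)
            out[k] = self._local_fit(x0, w)
        return out

    def _local_fit(self, x0: float, w: np.ndarray) -> float:
        keep = w > 0
        xc = self.x[keep] - x0
        sw = np.sqrt(w[keep])
        basis = np.vander(xc, self.degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], self.y[keep] * sw, rcond=None)
        return float(coef[0])

    def __call__(self, x_new) -> np.ndarray:
        return self.predict(x_new)


def fit_loess(x, y, span: float = 1.0, degree: int = 1) -> Loess:
    """Fit a LOESS smoother to (x, y).

    ``span`` is the fraction of points entering each local fit (values > 1
    stretch the weighting window beyond the data range); ``degree`` is the
    local polynomial degree (0, 1 or 2).  Raises if the span leaves a local
    fit with fewer positively weighted points than ``degree + 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    n = len(x)
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    # the furthest of the q included points carries zero tricube weight,
    # so q - 1 points must still support the polynomial
    q = int(np.floor(span * n)) if span <= 1.0 else n
    min_span = (degree + 2) / n
    if q - 1 < degree + 1 and span <= 1.0:
        raise ValueError(
            f"span {span} too small: local fits of degree {degree} on {n} points "
            f"need span >= {min_span:.3f}"
        )
    order = np.argsort(x)
    return Loess(x=x[order], y=y[order], span=span, degree=degree)
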
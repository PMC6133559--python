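"""Locally weighted polynomial regression (LOESS).

Tricube-weighted local polynomial fit of one response on one predictor,
the smoother used throughout the residual (ΔNoise / ΔFitness) analysis.
For each target point the ``q = floor(n * span)`` nearest neighbours are
weighted by the tricube kernel of their scaled distance and a weighted
polynomial of the requested degree is fitted; the smoothed value is the
local intercept.  With ``degree=2`` and exact-neighbour distances this
reproduces R's ``loess(..., degree=2, surface="direct")`` to within
floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LoessFit", "loess_fit"]


@dataclass
class LoessFit:
    """Result of a LOESS fit: fitted values, residuals and a predictor."""

    x: np.ndarray
    y: np.ndarray
    span: float
    degree: int
    fitted: np.ndarray
    residuals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.residuals = self.y - self.fitted

    def predict(self, xnew: np.ndarray) -> np.ndarray:
        """Evaluate the smoother at new predictor values."""
        return _smooth(self.x, self.y, np.asarray(xnew, dtype=float),
                       self.span, self.degree)


def loess_fit(x, y, span: float = 2 / 3, degree: int = 2) -> LoessFit:
    """Fit LOESS of ``y`` on ``x``.

    Parameters
    ----------
    x, y
        Data arrays of equal length ``n >= max(4, degree + 2)``.
    span
        Smoothing fraction in ``(0, 1]``; the neighbourhood holds
        ``floor(n * span)`` points.
    degree
        Local polynomial degree (2 = local quadratic, the default used
        in the analysis; 1 = local linear).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < max(4, degree + 2):
        raise ValueError(f"need at least {max(4, degree + 2)} points, got {n}")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if int(np.floor(n * span + 1e-9)) < degree + 2:
        raise ValueError(
            f"span {span} gives a neighbourhood of "
            f"{int(np.floor(n * span + 1e-9))} < {degree + 2} points")
    fitted = _smooth(x, y, x, span, degree)
    return LoessFit(x=x, y=y, span=span, degree=degree, fitted=fitted)


def _smooth(x: np.ndarray, y: np.ndarray, xpred: np.ndarray,
            span: float, degree: int) -> np.ndarray:
    n = x.size
    q = int(np.floor(n * span + 1e-9))
    out = np.empty(xpred.size)
    for j, x0 in enumerate(xpred):
        d = np.abs(x - x0)
        # stable sort breaks distance ties by input order
        idx = np.argsort(d, kind="stable")[:q]
        dq = d[idx[-1]]
        if dq > 0:
            w = (1.0 - np.minimum(d[idx] / dq, 1.0) ** 3) ** 3
        else:
            w = np.ones(q)
        X = np.vander(x[idx] - x0, degree + 1, increasing=True)
        Xw = X.T * w
        beta = np.linalg.lstsq(Xw @ X, Xw @ y[idx], rcond=None)[0]
        out[j] = beta[0]
    return out
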
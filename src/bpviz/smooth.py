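"""Robust locally weighted scatterplot smoothing (LOWESS) of the BP series.

Mean BP carries far more clinical signal than visit-to-visit variability,
yet viewers give outlier readings substantial weight.  The display therefore
overlays a LOWESS trend on the (slightly faded) raw line: at each point a
degree-1 weighted least-squares fit over the nearest ceil(frac*n) neighbors
with tricube weights, followed by optional bisquare robustness passes that
down-weight large residuals.

The abscissa is numeric time (days since window start), not point index, so
neighborhoods span missing-data gaps with time-proportional weights.  The
systolic and diastolic channels are smoothed independently but share one
parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import SmoothParams

__all__ = ["tricube_weight", "lowess", "SmoothCurve", "TooFewPoints"]


class TooFewPoints(ValueError):
    """Not enough points to fit a local line; smoothing is disabled and the
    raw line is rendered at full opacity."""


def tricube_weight(d: float, dmax: float) -> float:
    """Cleveland's tricube kernel: w = (1 - (d/dmax)^3)^3, clipped to [0, 1].

    Distances at or beyond dmax get weight 0; d = 0 gets weight 1.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    u = min(abs(d), dmax) / dmax
    return (1.0 - u**3) ** 3


@dataclass(frozen=True)
class SmoothCurve:
    """Fitted values at each input abscissa, one array per call."""

    x: np.ndarray
    fitted: np.ndarray


def _neighborhood(x: np.ndarray, i: int, k: int) -> tuple[int, int]:
    """Contiguous window of k points minimizing the span around x[i]."""
    n = len(x)
    lo = min(max(0, i - k // 2), n - k)
    # slide toward the side with nearer points
    while True:
        if lo > 0 and x[i] - x[lo - 1] < x[lo + k - 1] - x[i]:
            lo -= 1
        elif lo + k < n and x[lo + k] - x[i] < x[i] - x[lo]:
            lo += 1
        else:
            return lo, lo + k


def lowess(
    x: np.ndarray,
    y: np.ndarray,
    params: SmoothParams | None = None,
) -> SmoothCurve:
    """Smooth y(x) by robust locally weighted linear regression.

    x must be strictly increasing.  Output has the same length and abscissae
    as the input.  Raises TooFewPoints when fewer than two points exist or
    the neighborhood ceil(frac*n) would hold fewer than two points.
    """
    params = params or SmoothParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 2:
        raise TooFewPoints(f"need >= 2 points, got {n}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    k = math.ceil(params.frac * n)
    if k < 2:
        raise TooFewPoints(
            f"frac*n = {params.frac * n:.2f} < 2; widen frac or add points"
        )

    robust = np.ones(n)
    fitted = np.empty(n)
    for _ in range(params.robust_iterations + 1):
        for i in range(n):
            lo, hi = _neighborhood(x, i, k)
            xs, ys = x[lo:hi], y[lo:hi]
            d = np.abs(xs - x[i])
            dmax = d.max()
            if dmax <= 0:
                w = np.ones_like(d)
            else:
                w = (1.0 - np.minimum(d / dmax, 1.0) ** 3) ** 3
            w = w * robust[lo:hi]
            sw = w.sum()
            if sw <= 0:
                fitted[i] = y[i]
                continue
            xm = (w * xs).sum() / sw
            ym = (w * ys).sum() / sw
            sxx = (w * (xs - xm) ** 2).sum()
            if sxx <= 1e-12 * max(1.0, xm * xm):
                fitted[i] = ym
            else:
                beta = (w * (xs - xm) * (ys - ym)).sum() / sxx
                fitted[i] = ym + beta * (x[i] - xm)
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)
        robust = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return SmoothCurve(x=x, fitted=fitted)
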
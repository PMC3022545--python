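"""Local linear (loess-style) smoothing with tricube weights.

Degree-1 locally weighted regression, no robustness iterations, so the fit
is deterministic. Used for Bland-Altman trend lines and as the smoother
inside the pairwise cyclic-loess normalization reference. The neighborhood
is the ``ceil(span * n)`` nearest points to each evaluation abscissa.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import ParameterError


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.6,
    eval_x: np.ndarray | None = None,
) -> np.ndarray:
    """Fit y ~ x locally and return fitted values at ``eval_x`` (default: x).

    For each evaluation point the ``q = ceil(span*n)`` nearest x values get
    tricube weights ``(1-(d/dmax)^3)^3`` and a weighted straight line is
    solved in closed form. Degenerate neighborhoods (zero x spread) fall
    back to the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ParameterError("need at least 2 points for local regression")
    if not 0 < span <= 1:
        raise ParameterError(f"span must be in (0, 1], got {span}")
    q = max(2, math.ceil(span * n))
    targets = x if eval_x is None else np.asarray(eval_x, dtype=float)

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted = np.empty(targets.size)
    lo = np.searchsorted(xs, targets)
    for i, x0 in enumerate(targets):
        # slide a q-wide window over the sorted abscissae to the nearest q
        left = min(max(lo[i] - q // 2, 0), n - q)
        while left > 0 and x0 - xs[left - 1] < xs[left + q - 1] - x0:
            left -= 1
        while left + q < n and xs[left + q] - x0 < x0 - xs[left]:
            left += 1
        xi = xs[left : left + q]
        yi = ys[left : left + q]
        d = np.abs(xi - x0)
        dmax = d.max()
        if dmax == 0:
            fitted[i] = yi.mean()
            continue
        w = (1 - (d / dmax) ** 3) ** 3
        sw = w.sum()
        xm = (w * xi).sum() / sw
        ym = (w * yi).sum() / sw
        sxx = (w * (xi - xm) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xm * xm):
            fitted[i] = ym
        else:
            beta = (w * (xi - xm) * (yi - ym)).sum() / sxx
            fitted[i] = ym + beta * (x0 - xm)
    return fitted
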
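"""Tricube-weighted local polynomial regression (loess).

Local quadratic fits are the workhorse of pooled-QC signal-drift estimation:
for each evaluation point the ``span`` fraction of nearest reference points is
weighted by the tricube kernel and a degree-``degree`` polynomial is fitted by
weighted least squares.
"""

from __future__ import annotations

import numpy as np


def loess(x, y, x_eval, span: float = 1.0, degree: int = 2) -> np.ndarray:
    """Evaluate a loess fit of ``y`` on ``x`` at the points ``x_eval``.

    Parameters
    ----------
    x, y : 1-D arrays of equal length (the reference points).
    x_eval : points at which the smooth is evaluated.
    span : fraction of reference points entering each local fit, in (0, 1].
    degree : local polynomial degree (2 by default).

    Notes
    -----
    With fewer reference points than ``degree + 1`` the degree is reduced so
    the local system stays determined.  Points at the edge of the local window
    receive tricube weight 0; a small floor keeps the weighted system
    non-singular when the window is tight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = x.size
    if n != y.size or n == 0:
        raise ValueError("x and y must be non-empty arrays of equal length")

    q = int(np.ceil(span * n))
    q = max(q, min(degree + 1, n))
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        h = d[idx].max()
        if h == 0:
            w = np.ones(idx.size)
        else:
            w = (1.0 - np.clip(d[idx] / h, 0.0, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        deg = min(degree, np.unique(x[idx]).size - 1)
        # np.polyfit weights multiply the residuals, hence sqrt of kernel weights
        coef = np.polyfit(x[idx] - x0, y[idx], deg, w=np.sqrt(w))
        out[i] = coef[-1]
    return out
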
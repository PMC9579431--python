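"""Restricted (natural) cubic spline bases.

The truncated-power parameterisation with the natural constraint (linear beyond the
boundary knots) gives ``n_knots - 1`` basis columns: the identity column plus
``n_knots - 2`` restricted cubic terms.  Three knots therefore contribute two degrees
of freedom, the configuration used for univariable screening.
"""

from __future__ import annotations

import numpy as np


def default_knots(x: np.ndarray, n_knots: int = 3) -> np.ndarray:
    """Knots at equally spaced quantiles, 10th/50th/90th percentile for n_knots=3."""
    x = np.asarray(x, dtype=float)
    if n_knots == 3:
        probs = [0.10, 0.50, 0.90]
    else:
        probs = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(x, probs)
    if len(np.unique(knots)) < n_knots:
        raise ValueError("fewer distinct knot locations than requested knots")
    return np.asarray(knots, dtype=float)


def rcs_basis(x: np.ndarray, knots: np.ndarray | None = None, n_knots: int = 3) -> np.ndarray:
    """Restricted cubic spline design columns for ``x``.

    Parameters
    ----------
    x : array of shape (n,)
    knots : strictly increasing knot locations; computed from quantiles when None.

    Returns
    -------
    Array of shape (n, len(knots) - 1): column 0 is ``x`` itself, the remaining
    columns are the restricted truncated-power cubic terms

        C_j(x) = (x - t_j)^3_+ - (x - t_{K-1})^3_+ * (t_K - t_j)/(t_K - t_{K-1})
                 + (x - t_K)^3_+ * (t_{K-1} - t_j)/(t_K - t_{K-1})

    for interior knots t_j, j = 1..K-2, scaled by (t_K - t_1)^{-2} so the columns
    share the scale of x.  Every column is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = default_knots(x, n_knots)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("need at least 3 strictly increasing knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    t = knots
    K = len(t)
    tK, tKm1 = t[-1], t[-2]
    scale = (tK - t[0]) ** 2

    def pos3(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    for j in range(K - 2):
        tj = t[j]
        cj = (
            pos3(x - tj)
            - pos3(x - tKm1) * (tK - tj) / (tK - tKm1)
            + pos3(x - tK) * (tKm1 - tj) / (tK - tKm1)
        ) / scale
        cols.append(cj)
    return np.column_stack(cols)
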
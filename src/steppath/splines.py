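"""Restricted cubic spline (natural spline) basis, truncated-power form.

With 3 knots the basis contributes two columns: the variable itself and
one nonlinear term; the fitted function is cubic between the knots and
linear beyond the boundary knots.
"""

from __future__ import annotations

import numpy as np


def rcs_knots(x: np.ndarray, quantiles=(0.10, 0.50, 0.90)) -> np.ndarray:
    """Default 3-knot placement at the 10th/50th/90th percentiles."""
    k = np.quantile(np.asarray(x, dtype=float), quantiles)
    if np.any(np.diff(k) <= 0):
        raise ValueError(f"knots not strictly increasing: {k}")
    return k


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Two-column restricted cubic spline basis for 3 knots.

    Column 0 is x; column 1 is the truncated-power nonlinear term

        [(x-t1)+^3 - (x-t2)+^3 (t3-t1)/(t3-t2) + (x-t3)+^3 (t2-t1)/(t3-t2)]
        / (t3-t1)^2

    which vanishes below t1 and is linear in x above t3.
    """
    x = np.asarray(x, dtype=float)
    t1, t2, t3 = np.asarray(knots, dtype=float)
    if not (t1 < t2 < t3):
        raise ValueError(f"knots must be strictly increasing, got {knots}")
    d = (t3 - t1) ** 2

    def plus3(v):
        return np.maximum(v, 0.0) ** 3

    nonlin = (
        plus3(x - t1)
        - plus3(x - t2) * (t3 - t1) / (t3 - t2)
        + plus3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / d
    return np.column_stack([x, nonlin])
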
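"""Allometry: multivariate regression of shape on centroid size.

Shape variables (Procrustes/tangent coordinates) are regressed jointly on
centroid size by ordinary least squares with a single shared predictor.
The percentage of shape variance predicted by size quantifies allometry;
the residuals, re-centered on the mean shape, are the size-free shape
variables used by downstream analyses "without allometric components".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class RegressionUndefinedError(ValueError):
    """Centroid sizes are constant: slope is undefined."""


@dataclass
class AllometryResult:
    """Multivariate shape-on-size regression.

    ``predicted + residuals`` reconstructs the input exactly;
    ``pct_variance_predicted`` is 100 x SS(predicted, centered) /
    SS(shape variables, centered), the statistic morphometric software
    reports as "% predicted".
    """

    slope_vector: np.ndarray
    intercept_vector: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    pct_variance_predicted: float
    sizes: np.ndarray


def regress_on_size(
    shape_vars: np.ndarray, sizes: np.ndarray, *, log_size: bool = False
) -> AllometryResult:
    """OLS regression of every shape variable on centroid size.

    The predictor is raw centroid size by default (``log_size=True``
    switches to its natural log).  Because the predictor is shared, the
    multivariate fit reduces to one slope per shape variable:
    ``b_j = cov(x_j, s) / var(s)``.
    """
    x = np.asarray(shape_vars, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if x.ndim != 2 or x.shape[0] != s.shape[0]:
        raise ValueError("shape_vars must be n x p with one size per row")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 specimens")
    if log_size:
        s = np.log(s)
    s_c = s - s.mean()
    ss_s = float(s_c @ s_c)
    if ss_s <= 0.0:
        raise RegressionUndefinedError("constant centroid sizes")
    x_mean = x.mean(axis=0)
    x_c = x - x_mean
    slope = (s_c @ x_c) / ss_s
    intercept = x_mean - slope * s.mean()
    predicted = np.outer(s, slope) + intercept
    residuals = x - predicted
    ss_pred = float(((predicted - predicted.mean(axis=0)) ** 2).sum())
    ss_tot = float((x_c**2).sum())
    pct = 100.0 * ss_pred / ss_tot if ss_tot > 0 else 0.0
    return AllometryResult(
        slope_vector=slope,
        intercept_vector=intercept,
        predicted=predicted,
        residuals=residuals,
        pct_variance_predicted=pct,
        sizes=s,
    )


def remove_allometry(
    shape_vars: np.ndarray, sizes: np.ndarray, *, log_size: bool = False
) -> np.ndarray:
    """Size-free shape variables: regression residuals re-centered on the
    mean shape.  Idempotent, and the residuals' covariance with size is
    zero by the OLS normal equations."""
    x = np.asarray(shape_vars, dtype=float)
    res = regress_on_size(x, sizes, log_size=log_size)
    return res.residuals + x.mean(axis=0)
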
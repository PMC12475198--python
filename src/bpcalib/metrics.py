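"""Calibration and discrimination metrics.

The headline calibration metric is the Integrated Calibration Index (ICI):
the mean absolute difference between predicted probabilities and a smoothed
estimate of the observed event rate at those predictions.  The smoother is a
local polynomial regression in the R ``loess`` dialect (tricube weights,
span 0.75, degree 2, gaussian family), written here because no installed
Python smoother offers degree-2 loess.  Averaging over observations makes the
ICI automatically weighted by the density of the predictions.

Also provided: calibration slope/intercept (OLS of outcome on prediction),
the Mann-Whitney AUC, and the regression-based liability-scale R^2 (observed
0/1 R^2 pushed through the ascertainment-aware conversion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .liability_core import r2_liability_from_observed

__all__ = [
    "loess_smooth",
    "ici",
    "calibration_slope_intercept",
    "auc_empirical",
    "r2_liability_regression",
    "CalibrationReport",
]


@dataclass(frozen=True)
class CalibrationReport:
    """Aggregated performance of one method under one condition."""

    method: str
    ici: float
    slope: float
    intercept: float
    auc: float
    r2_liability_regression: float
    n_runs: int = 1
    ici_sem: float | None = None
    slope_sem: float | None = None


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray | None = None,
    span: float = 0.75,
    degree: int = 2,
    _chunk: int = 512,
) -> np.ndarray:
    """Local polynomial regression with tricube weights (R ``loess`` dialect).

    For each evaluation point the nearest ``ceil(span * n)`` observations get
    tricube weights on their scaled distances and a degree-``degree``
    weighted polynomial is fitted; the fitted value at the point is returned.
    Exact evaluation (no interpolation surface), gaussian family (no
    robustness iterations) — the defaults relevant to calibration curves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_eval is None:
        x_eval = x
    x_eval = np.asarray(x_eval, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    q = min(n, int(np.ceil(span * n)))
    q = max(q, degree + 1)
    out = np.empty(x_eval.size)
    for start in range(0, x_eval.size, _chunk):
        x0 = x_eval[start : start + _chunk][:, None]  # (c, 1)
        d = np.abs(x[None, :] - x0)  # (c, n)
        h = np.partition(d, q - 1, axis=1)[:, q - 1 : q]  # (c, 1)
        h = np.where(h > 0, h, 1.0)  # all-ties window: uniform weights
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        # weighted polynomial in (x - x0); fitted value = coefficient 0
        t = x[None, :] - x0
        basis = np.stack([t**p for p in range(degree + 1)], axis=-1)  # (c, n, p)
        wb = w[:, :, None] * basis
        xtx = np.einsum("cnp,cnq->cpq", wb, basis)
        xty = np.einsum("cnp,cn->cp", wb, y[None, :])
        # tiny ridge keeps degenerate windows (few distinct x) solvable
        xtx += 1e-10 * np.eye(degree + 1) * np.maximum(
            np.trace(xtx, axis1=1, axis2=2)[:, None, None], 1.0
        )
        coef = np.linalg.solve(xtx, xty[..., None])[..., 0]
        out[start : start + _chunk] = coef[:, 0]
    return out


def ici(
    p_pred: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    grid: bool = False,
) -> float:
    """Integrated Calibration Index of predicted probabilities.

    Smooths the binary outcome on the predictions with loess and returns the
    mean absolute difference between the smoothed observed probability and
    the prediction, averaged over observations (density-weighted).  With
    ``grid=True`` the average is instead taken over an equally spaced grid
    spanning the predictions (sensitivity variant).
    """
    p = np.asarray(p_pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and outcomes must align")
    if np.any((p < -1e-9) | (p > 1 + 1e-9)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if np.ptp(p) == 0:
        warnings.warn("constant predictions; ICI computed against mean outcome")
        return float(abs(y.mean() - p[0]))
    x_eval = np.linspace(p.min(), p.max(), 100) if grid else p
    fitted = loess_smooth(p, y, x_eval=x_eval, span=span, degree=degree)
    return float(np.mean(np.abs(fitted - x_eval)))


def calibration_slope_intercept(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS of the outcome on the prediction; (1, 0) indicates calibration."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(pred) == 0:
        raise ValueError("constant predictions have no calibration slope")
    slope, intercept = np.polyfit(pred, y, 1)
    return float(slope), float(intercept)


def auc_empirical(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC: P(case score > control score), ties counted half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    cases = scores[y == 1]
    controls = scores[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes required for AUC")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    # midranks for ties
    sorted_scores = scores[order]
    ranks_sorted = np.arange(1, scores.size + 1, dtype=float)
    _, inv, counts = np.unique(sorted_scores, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    mid = cum - (counts - 1) / 2.0
    ranks[order] = mid[inv]
    u = ranks[y == 1].sum() - cases.size * (cases.size + 1) / 2.0
    return float(u / (cases.size * controls.size))


def r2_liability_regression(pgs: np.ndarray, y: np.ndarray, K: float, P: float) -> float:
    """Liability-scale R^2 from regressing status on the PGS in a case-control sample.

    The observed-scale OLS R^2 (squared Pearson correlation for a single
    predictor) is converted to the liability scale with the
    ascertainment-aware transformation at case fraction ``P``.
    """
    pgs = np.asarray(pgs, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(pgs) == 0:
        return 0.0
    r = np.corrcoef(pgs, y)[0, 1]
    return r2_liability_from_observed(float(r * r), K, P)
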
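"""Complex measures for ordered dimensions.

Absolute/relative concentration index (ACI/RCI) and slope/relative index
of inequality (SII/RII).  All four place subgroups on [0, 1] via
midpoint (ridit) ranks computed from population shares, running from the
least advantaged (rank 1) to the most advantaged subgroup.

Sign convention: positive ACI/RCI/SII and RII > 1 indicate higher
indicator values among the most advantaged.

SII/RII come in two fitting variants because reference implementations
disagree slightly depending on the regression algorithm:

``linear``
    weighted least squares of the percent-scale estimates on the
    midpoint ranks (default); SII is the fitted slope, RII the ratio of
    the fitted values at rank 1 and rank 0.
``logit``
    a GLM with logit link on the proportion scale, predictions
    back-transformed to percent.  Keeps predictions inside (0, 100), so
    RII stays defined for steep gradients where the linear intercept
    goes negative.

The variant used is recorded in the result metadata.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .data_model import DisaggregatedSeries, ordered_arrays
from .results import MeasureResult

__all__ = ["aci", "rci", "sii", "rii", "wls_fit", "logit_fit"]

#: Relative variance of midpoint ranks below which the design is
#: considered degenerate (effectively a single subgroup).
_DEGENERATE_VAR = 1e-12


def aci(series: DisaggregatedSeries) -> MeasureResult:
    """Absolute concentration index, percentage points.

    ACI = sum_j p_j * y_j * (2 X_j - 1), equivalently twice the
    share-weighted covariance between estimates and midpoint ranks.
    """
    y, p, x = ordered_arrays(series)
    est = float(np.sum(p * y * (2.0 * x - 1.0)))
    return MeasureResult(measure="ACI", estimate=est)


def rci(series: DisaggregatedSeries) -> MeasureResult:
    """Relative concentration index: 100 * ACI / setting average.

    Reported on a x100 scale for consistency with the other relative
    measures (IDIS, COV); undefined when the setting average is zero.
    """
    mu = series.mu
    if mu == 0.0:
        return MeasureResult.undefined("RCI", "setting average is zero")
    est = 100.0 * aci(series).estimate / mu
    return MeasureResult(measure="RCI", estimate=float(est), metadata={"scale": "x100"})


def wls_fit(series: DisaggregatedSeries) -> tuple[float, float, Optional[np.ndarray]]:
    """Share-weighted least squares of estimates on midpoint ranks.

    Returns ``(intercept, slope, cov_beta)`` where ``cov_beta`` is the
    2x2 covariance of (intercept, slope) propagated from the subgroup
    standard errors (None when any SE is missing).  Raises
    ``ZeroDivisionError`` on a degenerate design.
    """
    y, p, x = ordered_arrays(series)
    xbar = float(np.sum(p * x))          # = 0.5 by construction
    ybar = float(np.sum(p * y))
    sxx = float(np.sum(p * (x - xbar) ** 2))
    if sxx < _DEGENERATE_VAR:
        raise ZeroDivisionError("degenerate design: no variation in ranks")
    slope = float(np.sum(p * (x - xbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * xbar

    cov = None
    ses = series.ses
    if ses is not None:
        order = np.argsort([g.order_rank for g in series.subgroups], kind="stable")
        se = np.asarray(ses, dtype=float)[order]
        # beta = A^{-1} X' W y with W = diag(p); propagate diag(se^2).
        X = np.column_stack([np.ones_like(x), x])
        W = np.diag(p)
        A = X.T @ W @ X
        Ainv = np.linalg.inv(A)
        H = Ainv @ X.T @ W        # beta = H y
        cov = H @ np.diag(se**2) @ H.T
    return intercept, slope, cov


def logit_fit(series: DisaggregatedSeries) -> tuple[float, float]:
    """GLM fit with logit link on the proportion scale.

    Returns ``(eta0, eta1)``: the linear predictor at rank 0 and rank 1.
    Subgroup proportions at exactly 0 or 1 are nudged inside the open
    interval so the link stays finite.
    """
    import statsmodels.api as sm

    y, p, x = ordered_arrays(series)
    eps = 1e-6
    prop = np.clip(y / 100.0, eps, 1.0 - eps)
    X = sm.add_constant(x)
    model = sm.GLM(prop, X, family=sm.families.Binomial(), var_weights=p)
    fit = model.fit()
    b0, b1 = fit.params
    return float(b0), float(b0 + b1)


def _expit(eta: float) -> float:
    from scipy.special import expit

    return float(expit(eta))


def sii(series: DisaggregatedSeries, model: str = "linear") -> MeasureResult:
    """Slope index of inequality: predicted value at rank 1 minus
    predicted value at rank 0, percentage points."""
    if model not in ("linear", "logit"):
        raise ValueError(f"unknown SII model {model!r}")
    try:
        if model == "linear":
            intercept, slope, _ = wls_fit(series)
            est = slope  # predicted(1) - predicted(0)
        else:
            eta0, eta1 = logit_fit(series)
            est = 100.0 * (_expit(eta1) - _expit(eta0))
    except ZeroDivisionError as exc:
        return MeasureResult.undefined("SII", str(exc), model=model)
    return MeasureResult(measure="SII", estimate=float(est), metadata={"model": model})


def rii(series: DisaggregatedSeries, model: str = "linear") -> MeasureResult:
    """Relative index of inequality: ratio of the predicted values at
    rank 1 and rank 0.  RII = 1 means no inequality.

    Undefined under the linear variant when the predicted value at rank
    0 is not positive (the logit variant cannot produce that).
    """
    if model not in ("linear", "logit"):
        raise ValueError(f"unknown RII model {model!r}")
    try:
        if model == "linear":
            intercept, slope, _ = wls_fit(series)
            pred0, pred1 = intercept, intercept + slope
            if pred0 <= 0.0:
                return MeasureResult.undefined(
                    "RII",
                    f"linear predicted value at rank 0 is {pred0:.4g} <= 0",
                    model=model,
                )
        else:
            eta0, eta1 = logit_fit(series)
            pred0, pred1 = 100.0 * _expit(eta0), 100.0 * _expit(eta1)
    except ZeroDivisionError as exc:
        return MeasureResult.undefined("RII", str(exc), model=model)
    return MeasureResult(
        measure="RII", estimate=float(pred1 / pred0), metadata={"model": model}
    )
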
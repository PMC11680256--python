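"""Complex measures for non-ordered dimensions (e.g. subnational regions).

All deviations are taken from the setting average ``mu`` — the
population-weighted subgroup mean unless the series carries an external
``setting_average``, in which case that value is used consistently for
every measure here.

Absolute measures (percentage points, except BGV in squared points):

* MDMU — mean absolute deviation from mu, each subgroup weighted equally
* MDMW — mean absolute deviation from mu, subgroups weighted by share
* BGV  — share-weighted variance about mu (squared percentage points)
* BGSD — square root of BGV

Relative measures (x100, dimensionless):

* IDISU / IDISW — 100 * MDMU / mu and 100 * MDMW / mu
* COV — 100 * BGSD / mu
* TI  — Theil index: 1000 * sum_j p_j (y_j/mu) ln(y_j/mu), with
  0 * ln 0 := 0 so zero-valued subgroups contribute nothing.
"""

from __future__ import annotations

import numpy as np

from .data_model import DisaggregatedSeries
from .results import MeasureResult

__all__ = ["mdmu", "mdmw", "idisu", "idisw", "bgv", "bgsd", "cov", "theil"]


def mdmu(series: DisaggregatedSeries) -> MeasureResult:
    y = series.estimates
    est = float(np.mean(np.abs(y - series.mu)))
    return MeasureResult(measure="MDMU", estimate=est)


def mdmw(series: DisaggregatedSeries) -> MeasureResult:
    y, p = series.estimates, series.shares
    est = float(np.sum(p * np.abs(y - series.mu)))
    return MeasureResult(measure="MDMW", estimate=est)


def _relative(code: str, absolute: float, mu: float) -> MeasureResult:
    if mu == 0.0:
        return MeasureResult.undefined(code, "setting average is zero")
    return MeasureResult(measure=code, estimate=float(100.0 * absolute / mu),
                         metadata={"scale": "x100"})


def idisu(series: DisaggregatedSeries) -> MeasureResult:
    return _relative("IDISU", mdmu(series).estimate, series.mu)


def idisw(series: DisaggregatedSeries) -> MeasureResult:
    return _relative("IDISW", mdmw(series).estimate, series.mu)


def bgv(series: DisaggregatedSeries) -> MeasureResult:
    y, p = series.estimates, series.shares
    est = float(np.sum(p * (y - series.mu) ** 2))
    return MeasureResult(measure="BGV", estimate=est, metadata={"units": "squared pp"})


def bgsd(series: DisaggregatedSeries) -> MeasureResult:
    return MeasureResult(measure="BGSD", estimate=float(np.sqrt(bgv(series).estimate)))


def cov(series: DisaggregatedSeries) -> MeasureResult:
    return _relative("COV", bgsd(series).estimate, series.mu)


def theil(series: DisaggregatedSeries) -> MeasureResult:
    mu = series.mu
    if mu == 0.0:
        return MeasureResult.undefined("TI", "setting average is zero")
    y, p = series.estimates, series.shares
    r = y / mu
    terms = np.zeros_like(r)
    pos = r > 0.0
    terms[pos] = p[pos] * r[pos] * np.log(r[pos])
    est = float(1000.0 * terms.sum())
    return MeasureResult(measure="TI", estimate=est, metadata={"scale": "x1000"})
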
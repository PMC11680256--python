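"""Standard errors and confidence intervals for the summary measures.

Analytic forms are used where they are standard and stable:

* D — Wald interval with SE = sqrt(se_a^2 + se_b^2);
* R — delta method on the log scale;
* SII — Wald interval from the weighted-regression slope variance
  propagated from the subgroup SEs;
* RII — delta method on the log of the predicted-value ratio, with a
  bootstrap fallback when the linear prediction at rank 0 is near zero.

Everything else (ACI, RCI, the mean-difference / variance / entropy
family, PAR, PAF) uses a parametric bootstrap: subgroup estimates are
resampled from Normal(y_j, se_j) truncated to [0, 100], the measure is
recomputed, and a percentile interval is taken.  Fully deterministic
under a fixed seed.

When any subgroup SE is missing the CI fields stay unset and the result
is annotated instead of raising.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .data_model import DisaggregatedSeries
from .results import MeasureResult
from .simple_measures import comparison_pair

__all__ = [
    "CIConfig",
    "ci_difference",
    "ci_ratio",
    "ci_regression",
    "ci_bootstrap",
    "attach_ci",
    "ANALYTIC_MEASURES",
]

#: Measures with an analytic CI under ``method="auto"``.
ANALYTIC_MEASURES = ("D", "R", "SII", "RII")

#: Linear prediction at rank 0 below this fraction of the slope magnitude
#: triggers the bootstrap fallback for the RII delta-method interval.
_RII_FALLBACK_REL = 0.05


@dataclass(frozen=True)
class CIConfig:
    """Confidence-interval settings.

    method: ``analytic`` (D/R/SII/RII only), ``bootstrap`` (any measure)
    or ``auto`` (analytic where available, bootstrap otherwise).
    """

    level: float = 0.95
    method: str = "auto"
    bootstrap_reps: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.method not in ("analytic", "bootstrap", "auto"):
            raise ValueError(f"unknown CI method {self.method!r}")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be >= 100")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(0.5 + self.level / 2.0))


def _pair_ses(series: DisaggregatedSeries) -> Optional[tuple[float, float, float, float]]:
    """(y_a, y_b, se_a, se_b) for the comparison pair, or None if SEs
    are missing."""
    i_a, i_b, _ = comparison_pair(series)
    a, b = series.subgroups[i_a], series.subgroups[i_b]
    if a.se is None or b.se is None:
        return None
    return a.estimate, b.estimate, a.se, b.se


def ci_difference(
    series: DisaggregatedSeries, config: CIConfig = CIConfig()
) -> Optional[tuple[float, float, float]]:
    """(se, lower, upper) for D; None when SEs are missing."""
    vals = _pair_ses(series)
    if vals is None:
        return None
    y_a, y_b, se_a, se_b = vals
    d = y_a - y_b
    se = float(np.hypot(se_a, se_b))
    return se, d - config.z * se, d + config.z * se


def ci_ratio(
    series: DisaggregatedSeries, config: CIConfig = CIConfig()
) -> Optional[tuple[float, float, float]]:
    """(se, lower, upper) for R via the log-scale delta method.

    Returns None when SEs are missing or either estimate is zero (the
    log-scale SE is then undefined).
    """
    vals = _pair_ses(series)
    if vals is None:
        return None
    y_a, y_b, se_a, se_b = vals
    if y_a == 0.0 or y_b == 0.0:
        return None
    r = y_a / y_b
    se_log = float(np.sqrt((se_a / y_a) ** 2 + (se_b / y_b) ** 2))
    lower = float(r * np.exp(-config.z * se_log))
    upper = float(r * np.exp(config.z * se_log))
    se_r = float(r * se_log)  # delta method back to the ratio scale
    return se_r, lower, upper


def ci_regression(
    series: DisaggregatedSeries,
    config: CIConfig = CIConfig(),
    variant: str = "linear",
    measure: str = "SII",
) -> Optional[tuple[float, float, float]]:
    """(se, lower, upper) for SII or RII.

    Analytic for the linear variant; the logit variant and ill-
    conditioned RII cases fall back to the parametric bootstrap.
    """
    from .ordered_measures import rii as rii_fn
    from .ordered_measures import sii as sii_fn
    from .ordered_measures import wls_fit

    if measure not in ("SII", "RII"):
        raise ValueError(f"ci_regression handles SII/RII, got {measure!r}")
    if series.ses is None:
        return None
    if variant == "logit":
        fn = sii_fn if measure == "SII" else rii_fn
        return ci_bootstrap(series, lambda s: fn(s, model="logit"), config)

    try:
        intercept, slope, cov = wls_fit(series)
    except ZeroDivisionError:
        return None
    if cov is None:
        return None

    if measure == "SII":
        se = float(np.sqrt(cov[1, 1]))
        return se, slope - config.z * se, slope + config.z * se

    pred0, pred1 = intercept, intercept + slope
    if pred0 <= 0.0 or pred1 <= 0.0:
        return None  # point estimate itself is undefined
    if pred0 < _RII_FALLBACK_REL * abs(slope):
        return ci_bootstrap(series, lambda s: rii_fn(s, model="linear"), config)
    # g = log(pred1/pred0); grad wrt (intercept, slope)
    grad = np.array([1.0 / pred1 - 1.0 / pred0, 1.0 / pred1])
    var_log = float(grad @ cov @ grad)
    se_log = float(np.sqrt(max(var_log, 0.0)))
    r = pred1 / pred0
    return (
        float(r * se_log),
        float(r * np.exp(-config.z * se_log)),
        float(r * np.exp(config.z * se_log)),
    )


def ci_bootstrap(
    series: DisaggregatedSeries,
    measure: Callable[[DisaggregatedSeries], MeasureResult],
    config: CIConfig = CIConfig(),
) -> Optional[tuple[float, float, float]]:
    """Parametric bootstrap percentile interval for any measure.

    Subgroup estimates are resampled from Normal(y_j, se_j) truncated to
    [0, 100]; the measure is recomputed on each replicate.  Returns None
    when SEs are missing or the measure is undefined in more than half
    of the replicates.
    """
    ses = series.ses
    if ses is None:
        return None
    rng = np.random.default_rng(config.seed)
    y = series.estimates
    draws = rng.normal(
        loc=y[None, :], scale=ses[None, :], size=(config.bootstrap_reps, len(y))
    )
    np.clip(draws, 0.0, 100.0, out=draws)
    values = []
    for row in draws:
        res = measure(series.with_estimates(row))
        if res.defined:
            values.append(res.estimate)
    if len(values) < config.bootstrap_reps / 2.0:
        return None
    values = np.asarray(values, dtype=float)
    alpha = 1.0 - config.level
    lower, upper = np.percentile(values, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    return float(values.std(ddof=1)) if len(values) > 1 else 0.0, float(lower), float(upper)


def attach_ci(
    series: DisaggregatedSeries,
    result: MeasureResult,
    config: CIConfig = CIConfig(),
    sii_model: str = "linear",
) -> MeasureResult:
    """Return a copy of ``result`` with se / ci_lower / ci_upper filled.

    Dispatches per measure and ``config.method``; annotates the result
    metadata instead of raising when a CI cannot be produced.
    """
    if not result.defined:
        return result

    code = result.measure
    out: Optional[tuple[float, float, float]] = None
    method_used = None

    use_analytic = config.method == "analytic" or (
        config.method == "auto" and code in ANALYTIC_MEASURES
    )
    if config.method == "analytic" and code not in ANALYTIC_MEASURES:
        new = dataclasses.replace(result)
        new.metadata = dict(result.metadata, ci_note=f"no analytic CI for {code}")
        return new

    if use_analytic:
        method_used = "analytic"
        if code == "D":
            out = ci_difference(series, config)
        elif code == "R":
            out = ci_ratio(series, config)
        else:
            out = ci_regression(series, config, variant=sii_model, measure=code)
    else:
        method_used = "bootstrap"
        from .registry import measure_function

        out = ci_bootstrap(series, measure_function(code, sii_model=sii_model), config)

    new = dataclasses.replace(result)
    new.metadata = dict(result.metadata, ci_method=method_used, ci_level=config.level)
    if out is None:
        new.metadata["ci_note"] = "CI unavailable (missing SEs or unstable)"
        return new
    se, lower, upper = out
    new.se = se
    # guard against percentile jitter putting the point estimate on an edge
    new.ci_lower = min(lower, result.estimate)
    new.ci_upper = max(upper, result.estimate)
    return new
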
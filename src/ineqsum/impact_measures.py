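"""Impact measures: population attributable risk (PAR) and fraction (PAF).

PAR is the change in the setting average that would be achieved if every
subgroup matched the reference subgroup:

* ordered dimensions — the reference is the *most advantaged* subgroup,
  even when it is not the best performer;
* non-ordered dimensions — the reference is the *best-performing*
  subgroup (highest estimate for favourable indicators, lowest for
  adverse ones).

PAR is signed as a change in the indicator: positive for favourable
indicators (coverage could rise), negative for adverse ones (prevalence
could fall).  When the reference is worse than the average the raw value
is truncated to 0 and flagged; the pre-truncation value is kept in
``metadata["raw"]``.  PAF = 100 * PAR / mu.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model import DisaggregatedSeries
from .results import MeasureResult

__all__ = ["par", "paf", "aggregate_par", "ParAggregate"]


def _reference(series: DisaggregatedSeries) -> tuple[int, str]:
    """Index and label of the reference subgroup."""
    y = series.estimates
    if series.dimension_type == "ordered":
        ranks = [g.order_rank for g in series.subgroups]
        idx = int(np.argmax(ranks))
        rule = "most advantaged"
    else:
        idx = int(np.argmax(y)) if series.favourable else int(np.argmin(y))
        rule = "best performer"
    return idx, rule


def par(series: DisaggregatedSeries) -> MeasureResult:
    """Population attributable risk, percentage points (signed)."""
    mu = series.mu
    idx, rule = _reference(series)
    y_ref = float(series.estimates[idx])
    raw = y_ref - mu
    # truncate when the reference performs worse than the average
    if series.favourable:
        est = max(raw, 0.0)
    else:
        est = min(raw, 0.0)
    truncated = est != raw
    return MeasureResult(
        measure="PAR",
        estimate=float(est),
        compared_subgroups=(series.labels[idx], "setting average"),
        metadata={
            "raw": float(raw),
            "truncated": truncated,
            "reference_rule": rule,
            "magnitude": abs(float(est)),
        },
    )


def paf(series: DisaggregatedSeries) -> MeasureResult:
    """Population attributable fraction: 100 * PAR / mu."""
    mu = series.mu
    if mu == 0.0:
        return MeasureResult.undefined("PAF", "setting average is zero")
    p = par(series)
    return MeasureResult(
        measure="PAF",
        estimate=float(100.0 * p.estimate / mu),
        compared_subgroups=p.compared_subgroups,
        metadata=dict(p.metadata, scale="x100"),
    )


@dataclass(frozen=True)
class ParAggregate:
    """Population-weighted current and potential averages across settings."""

    current: float
    potential: float

    @property
    def gain(self) -> float:
        return self.potential - self.current


def aggregate_par(
    entries: Iterable[tuple[float, float]],
    weights: Sequence[float],
) -> ParAggregate:
    """Aggregate (mu, signed PAR) pairs across settings.

    ``weights`` are the applicable populations (e.g. one-year-old
    children) per setting.  Returns the weighted current average and the
    weighted potential average mu + PAR.
    """
    entries = list(entries)
    w = np.asarray(list(weights), dtype=float)
    if len(entries) != len(w):
        raise ValueError("entries and weights length mismatch")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    mu = np.array([e[0] for e in entries], dtype=float)
    gain = np.array([e[1] for e in entries], dtype=float)
    current = float(np.sum(w * mu) / w.sum())
    potential = float(np.sum(w * (mu + gain)) / w.sum())
    return ParAggregate(current=current, potential=potential)
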
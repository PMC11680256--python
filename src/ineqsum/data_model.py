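"""Core data structures for disaggregated indicator data.

The unit of analysis is a :class:`DisaggregatedSeries`: one setting's
estimates of one indicator across the subgroups of a single inequality
dimension.  Dimensions are *binary* (exactly two subgroups, e.g.
urban/rural), *ordered* (subgroups with an inherent advantage ranking,
e.g. wealth quintiles) or *nonordered* (e.g. subnational regions).

Estimates are held on the percent scale (0-100) throughout; explicit
converters are provided in :func:`to_proportion` / :func:`to_percent`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DIMENSION_TYPES",
    "SubgroupRecord",
    "DisaggregatedSeries",
    "RankInfo",
    "SeriesValidationError",
    "validate_series",
    "compute_ranks",
    "to_proportion",
    "to_percent",
]

DIMENSION_TYPES = ("binary", "ordered", "nonordered")

#: Subgroups whose normalized population share sums to less than this are
#: treated as a zero-population series (invalid).
_SHARE_TOL = 1e-9


class SeriesValidationError(ValueError):
    """Structural violation in a candidate series, with context."""

    def __init__(self, message: str, series: "DisaggregatedSeries | None" = None):
        if series is not None:
            message = (
                f"[setting={series.setting!r} indicator={series.indicator!r} "
                f"dimension={series.dimension_name!r}] {message}"
            )
        super().__init__(message)


@dataclass(frozen=True)
class SubgroupRecord:
    """One subgroup's estimate within a series.

    Parameters
    ----------
    label
        Subgroup name (e.g. ``"urban"``, ``"quintile 1"``, a region name).
    estimate
        Indicator value in percent, on [0, 100].
    population
        Non-negative population count or share; normalized within the
        series when measures are computed.
    se
        Standard error of ``estimate``, percent scale.  Optional: when
        absent, confidence intervals are flagged undefined.
    order_rank
        Advantage rank for ordered dimensions, 1 = least advantaged
        (poorest / lowest HDI) up to the most advantaged subgroup.
    is_reference
        Marks the comparator subgroup for binary pairwise measures when
        the orientation cannot be inferred from labels.
    """

    label: str
    estimate: float
    population: float
    se: Optional[float] = None
    order_rank: Optional[int] = None
    is_reference: bool = False


@dataclass(frozen=True)
class RankInfo:
    """Population share and cumulative midpoint rank of an ordered subgroup.

    ``midpoint_rank`` is the ridit-style rank: cumulative share of all
    lower-ranked subgroups plus half the subgroup's own share, so it lies
    strictly inside (0, 1) whenever the share is positive.
    """

    share: float
    midpoint_rank: float


@dataclass
class DisaggregatedSeries:
    """One setting x indicator x dimension block of subgroup estimates."""

    setting: str
    indicator: str
    favourable: bool
    dimension_name: str
    dimension_type: str
    subgroups: list[SubgroupRecord]
    setting_average: Optional[float] = None
    year: Optional[int] = None
    income_group: Optional[str] = None

    # -- array views -------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.subgroups]

    @property
    def estimates(self) -> np.ndarray:
        return np.array([g.estimate for g in self.subgroups], dtype=float)

    @property
    def populations(self) -> np.ndarray:
        return np.array([g.population for g in self.subgroups], dtype=float)

    @property
    def ses(self) -> Optional[np.ndarray]:
        """Standard errors, or None if any subgroup lacks one."""
        if any(g.se is None for g in self.subgroups):
            return None
        return np.array([g.se for g in self.subgroups], dtype=float)

    @property
    def shares(self) -> np.ndarray:
        """Population shares normalized to sum to 1."""
        pop = self.populations
        total = pop.sum()
        if total <= 0:
            raise SeriesValidationError("total population is zero", self)
        return pop / total

    @property
    def mu(self) -> float:
        """Setting average: supplied value if present, else the
        population-weighted mean of subgroup estimates.

        A supplied ``setting_average`` deliberately overrides the
        re-aggregated mean, since source averages typically come from
        survey-weighted microdata rather than from the subgroups.
        """
        if self.setting_average is not None:
            return float(self.setting_average)
        return float(np.dot(self.shares, self.estimates))

    def with_estimates(self, estimates: Sequence[float]) -> "DisaggregatedSeries":
        """Copy of the series with subgroup estimates replaced (used by
        the parametric bootstrap)."""
        if len(estimates) != len(self.subgroups):
            raise ValueError("estimate vector length mismatch")
        new_groups = [
            dataclasses.replace(g, estimate=float(e))
            for g, e in zip(self.subgroups, estimates)
        ]
        return dataclasses.replace(self, subgroups=new_groups)


def to_proportion(percent: float | np.ndarray) -> float | np.ndarray:
    """Percent (0-100) -> proportion (0-1)."""
    return np.asarray(percent, dtype=float) / 100.0 if isinstance(percent, np.ndarray) else percent / 100.0


def to_percent(proportion: float | np.ndarray) -> float | np.ndarray:
    """Proportion (0-1) -> percent (0-100)."""
    return np.asarray(proportion, dtype=float) * 100.0 if isinstance(proportion, np.ndarray) else proportion * 100.0


def validate_series(series: DisaggregatedSeries) -> DisaggregatedSeries:
    """Check every structural invariant of a candidate series.

    Returns the series unchanged on success (populations are retained
    as given; normalization to shares happens lazily via ``.shares`` so
    the raw counts stay available for PAR aggregation).  Raises
    :class:`SeriesValidationError` with setting/indicator/dimension
    context otherwise.
    """
    if series.dimension_type not in DIMENSION_TYPES:
        raise SeriesValidationError(
            f"unknown dimension_type {series.dimension_type!r}", series
        )
    n = len(series.subgroups)
    if series.dimension_type == "binary":
        if n != 2:
            raise SeriesValidationError(
                f"binary series must have exactly 2 subgroups, got {n}", series
            )
    elif n < 2:
        raise SeriesValidationError(
            f"series must have at least 2 subgroups, got {n}", series
        )

    for g in series.subgroups:
        if not (0.0 <= g.estimate <= 100.0) or not math.isfinite(g.estimate):
            raise SeriesValidationError(
                f"estimate {g.estimate!r} for subgroup {g.label!r} outside [0, 100]",
                series,
            )
        if g.se is not None and (g.se < 0 or not math.isfinite(g.se)):
            raise SeriesValidationError(
                f"negative or non-finite se {g.se!r} for subgroup {g.label!r}", series
            )
        if g.population < 0 or not math.isfinite(g.population):
            raise SeriesValidationError(
                f"negative or non-finite population for subgroup {g.label!r}", series
            )

    if series.populations.sum() <= 0:
        raise SeriesValidationError("all subgroup populations are zero", series)

    if series.dimension_type == "ordered":
        ranks = [g.order_rank for g in series.subgroups]
        if any(r is None for r in ranks):
            raise SeriesValidationError("ordered series with missing order_rank", series)
        if len(set(ranks)) != n:
            raise SeriesValidationError(f"duplicate order_rank values {sorted(ranks)}", series)
        lo = min(ranks)
        if sorted(ranks) != list(range(lo, lo + n)):
            raise SeriesValidationError(
                f"order_rank values {sorted(ranks)} are not contiguous", series
            )

    if series.setting_average is not None and not (
        0.0 <= series.setting_average <= 100.0
    ):
        raise SeriesValidationError(
            f"setting_average {series.setting_average!r} outside [0, 100]", series
        )

    # shares property validates total population > 0
    assert abs(series.shares.sum() - 1.0) < _SHARE_TOL
    return series


def compute_ranks(series: DisaggregatedSeries) -> list[RankInfo]:
    """Midpoint (ridit) ranks for an ordered series.

    Subgroups are placed on [0, 1] from least to most advantaged; each
    subgroup sits at the cumulative share of all lower-ranked subgroups
    plus half its own share.  The returned list follows increasing
    ``order_rank``.  The share-weighted mean of midpoint ranks is 0.5
    for any share vector.
    """
    if series.dimension_type != "ordered":
        raise SeriesValidationError(
            f"compute_ranks requires an ordered series, got {series.dimension_type!r}",
            series,
        )
    if any(g.order_rank is None for g in series.subgroups):
        raise SeriesValidationError("missing order_rank", series)

    order = np.argsort([g.order_rank for g in series.subgroups], kind="stable")
    shares = series.shares[order]
    cum = np.concatenate([[0.0], np.cumsum(shares)])[:-1]
    mid = cum + shares / 2.0
    return [RankInfo(share=float(p), midpoint_rank=float(x)) for p, x in zip(shares, mid)]


def ordered_arrays(series: DisaggregatedSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(estimates, shares, midpoint ranks) sorted from least to most
    advantaged. Convenience for the ordered-dimension measures."""
    ranks = compute_ranks(series)
    order = np.argsort([g.order_rank for g in series.subgroups], kind="stable")
    y = series.estimates[order]
    p = np.array([r.share for r in ranks])
    x = np.array([r.midpoint_rank for r in ranks])
    return y, p, x
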
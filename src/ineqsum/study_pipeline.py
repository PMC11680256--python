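"""Cross-setting comparison workflow.

Mirrors the multi-country study design: filter series for completeness,
compute the full measure set per dimension type, summarize with medians
and interquartile ranges (overall and by income group), correlate
measures across settings with Spearman's rank coefficient, and aggregate
PAR across settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DisaggregatedSeries
from .impact_measures import ParAggregate, aggregate_par
from .registry import MEASURES_BY_DIMENSION, measure_function
from .results import MeasureResult
from .uncertainty import CIConfig, attach_ci

__all__ = [
    "eligibility_filter",
    "compute_all",
    "results_table",
    "correlate_measures",
    "summarize",
    "strength_class",
    "CrossSettingSummary",
]

#: Maximum tolerated fraction of missing subnational regions; exactly
#: this fraction missing is kept ("more than 15%" excludes).
MISSING_REGION_THRESHOLD = 0.15

#: Below this many settings the Spearman p-value uses an exact
#: permutation test instead of the t approximation.
_EXACT_P_MAX_N = 10


@dataclass
class CrossSettingSummary:
    """Bundle of cross-setting outputs."""

    medians: Optional[pd.DataFrame] = None
    correlations: Optional[pd.DataFrame] = None
    correlation_pvalues: Optional[pd.DataFrame] = None
    correlation_classes: Optional[pd.DataFrame] = None
    par_aggregate: Optional[ParAggregate] = None


def eligibility_filter(
    series_set: Iterable[DisaggregatedSeries],
    expected_regions: Optional[Mapping[str, int]] = None,
    expected_quintiles: int = 5,
) -> tuple[list[DisaggregatedSeries], list[tuple[DisaggregatedSeries, str]]]:
    """Split series into (kept, excluded-with-reason).

    Rules: binary series must have both subgroups; ordered (quintile)
    series must have the full complement; non-ordered series may miss at
    most ``MISSING_REGION_THRESHOLD`` of the expected region inventory.
    ``expected_regions`` maps setting id -> expected region count; when
    a setting is absent from it the region rule is skipped with a
    warning rather than guessed.
    """
    kept: list[DisaggregatedSeries] = []
    excluded: list[tuple[DisaggregatedSeries, str]] = []
    for s in series_set:
        n = len(s.subgroups)
        if s.dimension_type == "binary":
            if n != 2:
                excluded.append((s, f"missing urban or rural subgroup ({n} of 2 present)"))
                continue
        elif s.dimension_type == "ordered":
            if n < expected_quintiles:
                excluded.append(
                    (s, f"missing wealth quintile ({n} of {expected_quintiles} present)")
                )
                continue
        else:
            expected = None if expected_regions is None else expected_regions.get(s.setting)
            if expected is None:
                warnings.warn(
                    f"no expected region count for setting {s.setting!r}; "
                    "missing-region rule skipped",
                    stacklevel=2,
                )
            else:
                missing_frac = (expected - n) / expected
                if missing_frac > MISSING_REGION_THRESHOLD:
                    excluded.append(
                        (s, f"more than 15% of subnational regions missing "
                            f"({expected - n} of {expected})")
                    )
                    continue
        kept.append(s)
    return kept, excluded


def compute_all(
    series: DisaggregatedSeries,
    ci: Optional[CIConfig] = None,
    sii_model: str = "linear",
    measures: Optional[Sequence[str]] = None,
) -> list[MeasureResult]:
    """All measures applicable to the series' dimension type.

    binary -> {D, R}; ordered -> {D, R, ACI, RCI, SII, RII, PAR, PAF};
    nonordered -> {D, R, MDMU, MDMW, IDISU, IDISW, BGV, BGSD, COV, TI,
    PAR, PAF}.  ``measures`` restricts to a subset of that dispatch set.
    """
    codes = MEASURES_BY_DIMENSION[series.dimension_type]
    if measures is not None:
        requested = set(measures)
        codes = tuple(c for c in codes if c in requested)
    out = []
    for code in codes:
        res = measure_function(code, sii_model=sii_model)(series)
        if ci is not None:
            res = attach_ci(series, res, ci, sii_model=sii_model)
        out.append(res)
    return out


def results_table(
    pairs: Iterable[tuple[DisaggregatedSeries, Sequence[MeasureResult]]],
) -> pd.DataFrame:
    """Long-format results table: one row per series x measure."""
    rows = []
    for series, results in pairs:
        for r in results:
            rows.append(
                {
                    "setting": series.setting,
                    "year": series.year,
                    "indicator": series.indicator,
                    "dimension": series.dimension_name,
                    "dimension_type": series.dimension_type,
                    "income_group": series.income_group,
                    "measure": r.measure,
                    "estimate": r.estimate,
                    "se": r.se,
                    "ci_lower": r.ci_lower,
                    "ci_upper": r.ci_upper,
                    "defined": r.defined,
                    "undefined_reason": r.undefined_reason,
                    "compared_subgroups": (
                        "|".join(r.compared_subgroups) if r.compared_subgroups else None
                    ),
                }
            )
    return pd.DataFrame(rows)


def strength_class(rho: float) -> str:
    """Correlation strength label from |rho|: >=0.9 very strong,
    >=0.7 strong, >=0.4 moderate, else weak."""
    a = abs(rho)
    if a >= 0.9:
        return "very strong"
    if a >= 0.7:
        return "strong"
    if a >= 0.4:
        return "moderate"
    return "weak"


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from the full permutation null of Spearman's rho,
    enumerated and correlated in one vectorized pass (feasible for the
    small n where the t approximation is poor)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rho_null = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rho_null) >= abs(rho_obs) - 1e-12))


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rho, p = stats.spearmanr(x, y)
    if len(x) < _EXACT_P_MAX_N and np.isfinite(rho):
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def correlate_measures(
    table: pd.DataFrame,
    value_col: str = "estimate",
    use_absolute: bool = False,
) -> CrossSettingSummary:
    """Pairwise Spearman correlations of measure estimates across settings.

    ``table`` is a long-format results table (see :func:`results_table`)
    for one indicator x dimension; it is pivoted to settings x measures
    and correlated pairwise on the settings where both measures are
    defined.  ``use_absolute`` correlates |estimate| instead of the
    signed value (relevant for adverse indicators).
    """
    df = table[table["defined"].astype(bool)] if "defined" in table else table
    wide = df.pivot_table(index="setting", columns="measure", values=value_col)
    if use_absolute:
        wide = wide.abs()
    codes = list(wide.columns)
    k = len(codes)
    rho = pd.DataFrame(np.eye(k), index=codes, columns=codes)
    pval = pd.DataFrame(np.zeros((k, k)), index=codes, columns=codes)
    for i in range(k):
        for j in range(i + 1, k):
            sub = wide[[codes[i], codes[j]]].dropna()
            if len(sub) < 3:
                r, p = np.nan, np.nan
            else:
                r, p = _spearman(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy())
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    classes = rho.map(lambda v: strength_class(v) if np.isfinite(v) else "n/a")
    return CrossSettingSummary(
        correlations=rho, correlation_pvalues=pval, correlation_classes=classes
    )


def summarize(
    table: pd.DataFrame,
    value_col: str = "estimate",
    by_income_group: bool = True,
) -> pd.DataFrame:
    """Medians and interquartile ranges per measure x indicator x
    dimension, overall and stratified by income group.

    Percentiles use linear interpolation (type 7).
    """
    df = table[table["defined"].astype(bool)] if "defined" in table else table

    def _agg(g: pd.Series) -> pd.Series:
        v = g.dropna().to_numpy(dtype=float)
        if len(v) == 0:
            return pd.Series({"n": 0, "median": np.nan, "q25": np.nan, "q75": np.nan})
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        return pd.Series({"n": len(v), "median": med, "q25": q25, "q75": q75})

    keys = ["indicator", "dimension", "measure"]
    overall = df.groupby(keys)[value_col].apply(_agg).unstack()
    overall = overall.assign(income_group="all").reset_index()
    frames = [overall]
    if by_income_group and "income_group" in df and df["income_group"].notna().any():
        strat = (
            df.dropna(subset=["income_group"])
            .groupby(keys + ["income_group"])[value_col]
            .apply(_agg)
            .unstack()
            .reset_index()
        )
        frames.append(strat)
    out = pd.concat(frames, ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out[keys + ["income_group", "n", "median", "q25", "q75"]]
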
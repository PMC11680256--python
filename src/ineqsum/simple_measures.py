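"""Simple pairwise measures: difference (D) and ratio (R).

Both compare the two extreme subgroups of a series.  Orientation:

* binary -- group of interest minus reference (urban - rural for place
  of residence, from the orientation table below; extensible via an
  explicit ``is_reference`` flag on the comparator subgroup);
* ordered -- most advantaged minus least advantaged (richest - poorest);
* nonordered -- max minus min, so D >= 0 and R >= 1 whenever defined.

The favourable/adverse indicator flag does not change D or R: the
pairing is fixed by subgroup identity, the flag only affects
interpretation and the impact measures.
"""

from __future__ import annotations

import numpy as np

from .data_model import DisaggregatedSeries
from .results import MeasureResult

__all__ = ["BINARY_ORIENTATION", "difference", "ratio", "comparison_pair"]

#: label of the group of interest -> label of the reference group, both
#: lower-case.  D > 0 means a higher estimate in the group of interest.
BINARY_ORIENTATION: dict[str, str] = {
    "urban": "rural",
    "male": "female",
}


def comparison_pair(series: DisaggregatedSeries) -> tuple[int, int, dict]:
    """Indices ``(i_interest, i_reference)`` of the two compared
    subgroups, plus pairing metadata (tie labels, orientation source)."""
    meta: dict = {}
    labels = series.labels
    if series.dimension_type == "binary":
        lowered = [l.strip().lower() for l in labels]
        for interest, reference in BINARY_ORIENTATION.items():
            if interest in lowered and reference in lowered:
                meta["orientation"] = f"{interest}-{reference}"
                return lowered.index(interest), lowered.index(reference), meta
        flags = [g.is_reference for g in series.subgroups]
        if sum(flags) == 1:
            ref = flags.index(True)
            meta["orientation"] = "is_reference flag"
            return 1 - ref, ref, meta
        meta["orientation"] = "input order (first minus second)"
        return 0, 1, meta

    if series.dimension_type == "ordered":
        ranks = [g.order_rank for g in series.subgroups]
        i_most = int(np.argmax(ranks))
        i_least = int(np.argmin(ranks))
        meta["orientation"] = "most minus least advantaged"
        return i_most, i_least, meta

    # nonordered: max vs min estimate, ties broken by input order
    y = series.estimates
    i_max = int(np.argmax(y))
    i_min = int(np.argmin(y))
    max_ties = [labels[i] for i in np.flatnonzero(y == y[i_max])]
    min_ties = [labels[i] for i in np.flatnonzero(y == y[i_min])]
    if len(max_ties) > 1:
        meta["max_ties"] = max_ties
    if len(min_ties) > 1:
        meta["min_ties"] = min_ties
    meta["orientation"] = "max minus min"
    return i_max, i_min, meta


def difference(series: DisaggregatedSeries) -> MeasureResult:
    """Difference between the two extreme subgroups, percentage points."""
    i_a, i_b, meta = comparison_pair(series)
    y = series.estimates
    return MeasureResult(
        measure="D",
        estimate=float(y[i_a] - y[i_b]),
        compared_subgroups=(series.labels[i_a], series.labels[i_b]),
        metadata=meta,
    )


def ratio(series: DisaggregatedSeries) -> MeasureResult:
    """Ratio between the two extreme subgroups.

    Undefined (not an exception) when the denominator estimate is zero.
    """
    i_a, i_b, meta = comparison_pair(series)
    y = series.estimates
    pair = (series.labels[i_a], series.labels[i_b])
    if y[i_b] == 0.0:
        res = MeasureResult.undefined("R", "zero denominator", **meta)
        res.compared_subgroups = pair
        return res
    return MeasureResult(
        measure="R",
        estimate=float(y[i_a] / y[i_b]),
        compared_subgroups=pair,
        metadata=meta,
    )
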
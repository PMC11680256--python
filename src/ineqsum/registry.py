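"""Measure-code -> callable registry shared by the pipeline, the
uncertainty module and the CLI."""

from __future__ import annotations

from functools import partial
from typing import Callable

from . import impact_measures, nonordered_measures, ordered_measures, simple_measures
from .data_model import DisaggregatedSeries
from .results import MeasureResult

__all__ = ["measure_function", "MEASURES_BY_DIMENSION"]

#: Measure set dispatched per dimension type.
MEASURES_BY_DIMENSION: dict[str, tuple[str, ...]] = {
    "binary": ("D", "R"),
    "ordered": ("D", "R", "ACI", "RCI", "SII", "RII", "PAR", "PAF"),
    "nonordered": (
        "D", "R", "MDMU", "MDMW", "IDISU", "IDISW",
        "BGV", "BGSD", "COV", "TI", "PAR", "PAF",
    ),
}

_PLAIN: dict[str, Callable[[DisaggregatedSeries], MeasureResult]] = {
    "D": simple_measures.difference,
    "R": simple_measures.ratio,
    "ACI": ordered_measures.aci,
    "RCI": ordered_measures.rci,
    "MDMU": nonordered_measures.mdmu,
    "MDMW": nonordered_measures.mdmw,
    "IDISU": nonordered_measures.idisu,
    "IDISW": nonordered_measures.idisw,
    "BGV": nonordered_measures.bgv,
    "BGSD": nonordered_measures.bgsd,
    "COV": nonordered_measures.cov,
    "TI": nonordered_measures.theil,
    "PAR": impact_measures.par,
    "PAF": impact_measures.paf,
}


def measure_function(
    code: str, sii_model: str = "linear"
) -> Callable[[DisaggregatedSeries], MeasureResult]:
    """Callable computing the point estimate for a measure code."""
    if code == "SII":
        return partial(ordered_measures.sii, model=sii_model)
    if code == "RII":
        return partial(ordered_measures.rii, model=sii_model)
    try:
        return _PLAIN[code]
    except KeyError:
        raise KeyError(f"unknown measure code {code!r}") from None
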
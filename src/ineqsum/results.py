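"""Shared result container for all summary measures."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

__all__ = ["MEASURE_CODES", "MeasureResult"]

#: All measure codes, grouped by family.
MEASURE_CODES = (
    "D", "R",                                      # simple
    "ACI", "RCI", "SII", "RII",                    # ordered / disproportionality
    "MDMU", "MDMW", "IDISU", "IDISW",              # mean-difference family
    "BGV", "BGSD", "COV", "TI",                    # variance / entropy family
    "PAR", "PAF",                                  # impact
)


@dataclass
class MeasureResult:
    """A single measure estimate with optional uncertainty and metadata.

    ``defined`` is False when the measure cannot be computed for the
    series (e.g. a ratio with a zero denominator); then ``estimate`` is
    None and ``undefined_reason`` explains why.  CI fields are filled by
    the :mod:`ineqsum.uncertainty` module.
    """

    measure: str
    estimate: Optional[float] = None
    se: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    compared_subgroups: Optional[tuple[str, str]] = None
    defined: bool = True
    undefined_reason: Optional[str] = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.measure not in MEASURE_CODES:
            raise ValueError(f"unknown measure code {self.measure!r}")
        if not self.defined:
            if self.estimate is not None:
                raise ValueError("undefined result must not carry an estimate")
            if not self.undefined_reason:
                raise ValueError("undefined result requires an undefined_reason")
        if (
            self.ci_lower is not None
            and self.ci_upper is not None
            and self.estimate is not None
        ):
            if not (self.ci_lower <= self.estimate <= self.ci_upper):
                raise ValueError(
                    f"CI ({self.ci_lower}, {self.ci_upper}) does not bracket "
                    f"estimate {self.estimate} for {self.measure}"
                )

    @classmethod
    def undefined(cls, measure: str, reason: str, **metadata: Any) -> "MeasureResult":
        return cls(measure=measure, defined=False, undefined_reason=reason,
                   metadata=dict(metadata))
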
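"""Synthetic disaggregated series with controlled inequality structure.

Emulates survey-derived coverage data: true subgroup values are built
from a chosen effect shape, observed estimates are binomial proportions
at a configurable effective sample size (so exact 0% can occur for
low-prevalence adverse indicators), and population shares come from a
symmetric Dirichlet draw.

Effect shapes
-------------
``null``
    all true values equal to ``base_level``.
``linear-gradient``
    true values evenly spaced from base - g/2 to base + g/2 across
    subgroups ordered least to most advantaged (g = ``gradient_size``;
    may be negative to favour the least advantaged).
``outlier``
    all subgroups at ``base_level`` except the last, offset by
    ``outlier_offset`` and pinned to population share ``outlier_share``.
``step``
    lower half at base - g/2, upper half at base + g/2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import DisaggregatedSeries, SubgroupRecord, validate_series
from .registry import measure_function

__all__ = ["SyntheticScenario", "generate", "true_series", "recover_parameters"]

EFFECT_SHAPES = ("null", "linear-gradient", "outlier", "step")


@dataclass(frozen=True)
class SyntheticScenario:
    """Generator parameters for a batch of synthetic series.

    ``noise`` is the effective per-subgroup sample size for binomial
    noise; ``None`` disables noise (estimates equal the true values and
    SEs are zero).  ``share_concentration`` is the symmetric Dirichlet
    concentration for population shares; ``None`` gives equal shares.
    """

    n_settings: int = 1
    dimension_type: str = "ordered"
    n_subgroups: int = 5
    effect_shape: str = "linear-gradient"
    gradient_size: float = 20.0
    outlier_offset: float = 30.0
    outlier_share: float = 0.05
    base_level: float = 50.0
    noise: Optional[int] = 1000
    share_concentration: Optional[float] = 50.0
    favourable: bool = True
    seed: int = 0
    indicator: str = "synthetic"
    dimension_name: str = "synthetic-dimension"

    def __post_init__(self) -> None:
        if self.effect_shape not in EFFECT_SHAPES:
            raise ValueError(f"unknown effect_shape {self.effect_shape!r}")
        if self.dimension_type not in ("binary", "ordered", "nonordered"):
            raise ValueError(f"unknown dimension_type {self.dimension_type!r}")
        if self.dimension_type == "binary" and self.n_subgroups != 2:
            raise ValueError("binary scenarios require n_subgroups == 2")
        if self.n_subgroups < 2:
            raise ValueError("need at least 2 subgroups")
        if self.noise is not None and self.noise < 1:
            raise ValueError("noise (effective n) must be >= 1")
        if not (0.0 < self.outlier_share < 1.0):
            raise ValueError("outlier_share must be in (0, 1)")
        bad = [v for v in self.true_values() if not (0.0 <= v <= 100.0)]
        if bad:
            raise ValueError(
                f"effect shape pushes true values outside [0, 100]: {bad}"
            )

    def true_values(self) -> np.ndarray:
        """Noise-free subgroup values, least to most advantaged."""
        k = self.n_subgroups
        if self.effect_shape == "null":
            return np.full(k, self.base_level, dtype=float)
        if self.effect_shape == "linear-gradient":
            return self.base_level + np.linspace(
                -self.gradient_size / 2.0, self.gradient_size / 2.0, k
            )
        if self.effect_shape == "outlier":
            vals = np.full(k, self.base_level, dtype=float)
            vals[-1] += self.outlier_offset
            return vals
        # step
        vals = np.full(k, self.base_level - self.gradient_size / 2.0, dtype=float)
        vals[k // 2 :] = self.base_level + self.gradient_size / 2.0
        return vals


def _labels(scenario: SyntheticScenario) -> list[str]:
    if scenario.dimension_type == "binary":
        return ["rural", "urban"]  # urban = more advantaged, gets the higher value
    if scenario.dimension_type == "ordered":
        return [f"quintile {i + 1}" for i in range(scenario.n_subgroups)]
    return [f"region {i + 1}" for i in range(scenario.n_subgroups)]


def _shares(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    k = scenario.n_subgroups
    if scenario.effect_shape == "outlier":
        rest = (
            np.full(k - 1, 1.0 / (k - 1))
            if scenario.share_concentration is None
            else rng.dirichlet(np.full(k - 1, scenario.share_concentration))
        )
        return np.concatenate([rest * (1.0 - scenario.outlier_share),
                               [scenario.outlier_share]])
    if scenario.share_concentration is None:
        return np.full(k, 1.0 / k)
    return rng.dirichlet(np.full(k, scenario.share_concentration))


def _one_series(
    scenario: SyntheticScenario, setting: str, rng: np.random.Generator
) -> DisaggregatedSeries:
    truth = scenario.true_values()
    shares = _shares(scenario, rng)
    if scenario.noise is None:
        est = truth.copy()
        se = np.zeros_like(truth)
    else:
        n = scenario.noise
        counts = rng.binomial(n, truth / 100.0)
        phat = counts / n
        est = 100.0 * phat
        se = 100.0 * np.sqrt(phat * (1.0 - phat) / n)
    labels = _labels(scenario)
    ordered = scenario.dimension_type in ("binary", "ordered")
    groups = [
        SubgroupRecord(
            label=labels[j],
            estimate=float(est[j]),
            se=float(se[j]),
            population=float(shares[j]),
            order_rank=(j + 1) if scenario.dimension_type == "ordered" else None,
        )
        for j in range(scenario.n_subgroups)
    ]
    return validate_series(
        DisaggregatedSeries(
            setting=setting,
            indicator=scenario.indicator,
            favourable=scenario.favourable,
            dimension_name=scenario.dimension_name,
            dimension_type=scenario.dimension_type,
            subgroups=groups,
        )
    )


def generate(scenario: SyntheticScenario) -> list[DisaggregatedSeries]:
    """Deterministic batch of ``n_settings`` series for the scenario."""
    rng = np.random.default_rng(scenario.seed)
    return [
        _one_series(scenario, f"setting-{i + 1:03d}", rng)
        for i in range(scenario.n_settings)
    ]


def true_series(scenario: SyntheticScenario) -> DisaggregatedSeries:
    """The noise-free series with equal (or pinned-outlier) shares,
    used as ground truth for parameter recovery."""
    noiseless = dataclasses.replace(
        scenario, noise=None, share_concentration=None, n_settings=1
    )
    return generate(noiseless)[0]


def recover_parameters(
    scenario: SyntheticScenario,
    measures: Sequence[str],
    n_reps: int = 100,
    sii_model: str = "linear",
):
    """Bias/RMSE of measure estimates against the scenario's truth.

    Runs ``n_reps`` independent replications (seeds ``scenario.seed``,
    ``scenario.seed + 1``, ...), computing each measure on every
    generated series.  Returns a DataFrame indexed by measure code with
    columns ``truth``, ``mean``, ``bias``, ``rmse``, ``n_defined``.
    """
    import pandas as pd

    truth_series_ = true_series(scenario)
    rows = {}
    truth_vals = {}
    for code in measures:
        t = measure_function(code, sii_model=sii_model)(truth_series_)
        truth_vals[code] = t.estimate if t.defined else np.nan
        rows[code] = []

    for rep in range(n_reps):
        rep_scenario = dataclasses.replace(scenario, seed=scenario.seed + rep)
        for series in generate(rep_scenario):
            for code in measures:
                res = measure_function(code, sii_model=sii_model)(series)
                if res.defined:
                    rows[code].append(res.estimate)

    records = []
    for code in measures:
        vals = np.asarray(rows[code], dtype=float)
        truth = truth_vals[code]
        mean = vals.mean() if len(vals) else np.nan
        records.append(
            {
                "measure": code,
                "truth": truth,
                "mean": mean,
                "bias": mean - truth,
                "rmse": float(np.sqrt(np.mean((vals - truth) ** 2))) if len(vals) else np.nan,
                "n_defined": len(vals),
            }
        )
    return pd.DataFrame(records).set_index("measure")
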
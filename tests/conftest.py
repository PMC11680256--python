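from __future__ import annotations

import numpy as np
import pytest

from ineqsum.data_model import DisaggregatedSeries, SubgroupRecord, validate_series


def make_series(
    estimates,
    populations=None,
    ses=None,
    dimension_type="nonordered",
    favourable=True,
    setting="s1",
    indicator="dtp3",
    dimension_name=None,
    setting_average=None,
    labels=None,
    validate=True,
    **kwargs,
):
    """Build a series from plain vectors (ordered: least -> most advantaged)."""
    n = len(estimates)
    if populations is None:
        populations = [1.0] * n
    if ses is None:
        ses = [None] * n
    if labels is None:
        if dimension_type == "binary":
            labels = ["urban", "rural"]
        elif dimension_type == "ordered":
            labels = [f"q{i + 1}" for i in range(n)]
        else:
            labels = [f"r{i + 1}" for i in range(n)]
    if dimension_name is None:
        dimension_name = {
            "binary": "residence",
            "ordered": "wealth",
            "nonordered": "region",
        }[dimension_type]
    subgroups = [
        SubgroupRecord(
            label=labels[i],
            estimate=float(estimates[i]),
            population=float(populations[i]),
            se=None if ses[i] is None else float(ses[i]),
            order_rank=(i + 1) if dimension_type == "ordered" else None,
        )
        for i in range(n)
    ]
    series = DisaggregatedSeries(
        setting=setting,
        indicator=indicator,
        favourable=favourable,
        dimension_name=dimension_name,
        dimension_type=dimension_type,
        subgroups=subgroups,
        setting_average=setting_average,
        **kwargs,
    )
    return validate_series(series) if validate else series


def random_series(rng, dimension_type="nonordered", n_min=2, n_max=8, with_se=False):
    """One random valid series for property tests."""
    n = int(rng.integers(max(n_min, 2), n_max + 1))
    if dimension_type == "binary":
        n = 2
    estimates = rng.uniform(0.5, 99.5, size=n)
    populations = rng.dirichlet(np.full(n, 2.0)) * rng.uniform(1e3, 1e6)
    ses = rng.uniform(0.2, 5.0, size=n) if with_se else [None] * n
    return make_series(
        estimates, populations, ses=ses, dimension_type=dimension_type
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
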
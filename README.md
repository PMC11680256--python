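# ineqsum

Summary measures of health inequality computed from disaggregated
indicator data (subgroup estimates with standard errors and population
sizes), with confidence intervals and a cross-setting comparison
workflow.

Sixteen measures are implemented, dispatched by the type of the
inequality dimension:

| Dimension type | Measures |
|---|---|
| binary (e.g. urban/rural) | D, R |
| ordered (e.g. wealth quintiles) | D, R, ACI, RCI, SII, RII, PAR, PAF |
| non-ordered (e.g. subnational regions) | D, R, MDMU, MDMW, IDISU, IDISW, BGV, BGSD, COV, TI, PAR, PAF |

Codes: difference (D), ratio (R), absolute/relative concentration index
(ACI/RCI), slope/relative index of inequality (SII/RII), unweighted and
weighted mean difference from the mean (MDMU/MDMW), unweighted/weighted
index of disparity (IDISU/IDISW), between-group variance and standard
deviation (BGV/BGSD), coefficient of variation (COV), Theil index (TI),
population attributable risk/fraction (PAR/PAF).

Conventions: estimates live on the percent scale (0–100); ordered
subgroups are ranked 1 = least advantaged upward and placed on [0, 1]
with ridit-style midpoint ranks; RCI, IDIS, COV and PAF are reported
×100 and TI ×1000; positive ACI/RCI/SII (RII > 1) means higher values
among the most advantaged. SII/RII offer a linear WLS variant (default)
and a logit-link GLM variant; the variant used is recorded in the
result metadata.

Confidence intervals are analytic for D, R, SII and RII (Wald /
delta-method forms) and a seeded parametric bootstrap (normal resampling
of subgroup estimates, truncated to [0, 100], percentile interval) for
everything else.

## Library quick start

```python
from ineqsum import (DisaggregatedSeries, SubgroupRecord, validate_series,
                     compute_all, CIConfig)

series = validate_series(DisaggregatedSeries(
    setting="KEN", indicator="dtp3", favourable=True,
    dimension_name="wealth", dimension_type="ordered",
    subgroups=[
        SubgroupRecord("q1", estimate=40.0, population=1200, se=1.1, order_rank=1),
        SubgroupRecord("q2", estimate=45.0, population=1100, se=1.2, order_rank=2),
        SubgroupRecord("q3", estimate=52.0, population=1000, se=1.3, order_rank=3),
        SubgroupRecord("q4", estimate=58.0, population=900,  se=1.4, order_rank=4),
        SubgroupRecord("q5", estimate=66.0, population=800,  se=1.5, order_rank=5),
    ],
))
for result in compute_all(series, ci=CIConfig(seed=1)):
    print(result.measure, result.estimate, result.ci_lower, result.ci_upper)
```

## CLI

The `ineqsum` entry point reads/writes delimiter-separated long-format
tables (comma default, tab accepted) with columns
`setting, year, indicator, dimension, dimension_type, subgroup,
estimate, se, population, subgroup_order, favourable, setting_average`.

```sh
# all applicable measures with CIs
ineqsum compute input.csv results.csv --measure all --ci auto --seed 7

# medians/IQR and Spearman correlation matrices across settings
ineqsum compare results.csv --summary-out summary.csv --corr-out corr.csv

# synthetic data from a JSON scenario
ineqsum simulate scenario.json synthetic.csv --seed 3

# completeness filtering (binary pairs, full quintile sets, <=15% of
# expected regions missing)
ineqsum filter input.csv kept.csv --expected-regions regions.csv --log excluded.csv
```

`simulate` scenario files mirror `ineqsum.synthetic_data.SyntheticScenario`,
e.g. `{"n_settings": 10, "dimension_type": "ordered", "n_subgroups": 5,
"effect_shape": "linear-gradient", "gradient_size": 20, "noise": 1000,
"seed": 3}`.

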
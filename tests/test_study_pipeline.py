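import numpy as np
import pandas as pd
import pytest

from ineqsum.study_pipeline import (
    compute_all,
    correlate_measures,
    eligibility_filter,
    results_table,
    strength_class,
    summarize,
)
from ineqsum.uncertainty import CIConfig

from conftest import make_series, random_series


class TestEligibilityFilter:
    def test_incomplete_quintiles_excluded(self):
        s = make_series([40, 50, 55, 60], dimension_type="ordered")
        kept, excluded = eligibility_filter([s])
        assert kept == []
        assert "missing wealth quintile" in excluded[0][1]

    def test_full_quintiles_kept(self):
        s = make_series([40, 45, 50, 55, 60], dimension_type="ordered")
        kept, excluded = eligibility_filter([s])
        assert len(kept) == 1 and not excluded

    def test_boundary_15_percent_kept(self):
        # 17 of 20 regions present: exactly 15% missing -> kept
        s = make_series(np.linspace(30, 70, 17), setting="A")
        kept, excluded = eligibility_filter([s], expected_regions={"A": 20})
        assert len(kept) == 1 and not excluded

    def test_over_15_percent_excluded(self):
        # 16 of 20 regions present: 20% missing -> excluded
        s = make_series(np.linspace(30, 70, 16), setting="A")
        kept, excluded = eligibility_filter([s], expected_regions={"A": 20})
        assert kept == []
        assert "more than 15%" in excluded[0][1]

    def test_binary_missing_subgroup_excluded(self):
        s = make_series([50.0, 52.0], dimension_type="binary", validate=False)
        s.subgroups = s.subgroups[:1]
        kept, excluded = eligibility_filter([s])
        assert kept == []
        assert "urban or rural" in excluded[0][1]

    def test_unknown_inventory_warns_and_keeps(self):
        s = make_series([40, 50, 60], setting="B")
        with pytest.warns(UserWarning, match="expected region count"):
            kept, excluded = eligibility_filter([s], expected_regions={"A": 10})
        assert len(kept) == 1


class TestComputeAll:
    def test_cardinality_binary(self):
        s = make_series([50.0, 52.0], dimension_type="binary")
        results = compute_all(s)
        assert sorted(r.measure for r in results) == ["D", "R"]

    def test_cardinality_ordered(self):
        s = make_series([40, 45, 50, 55, 60], dimension_type="ordered")
        codes = {r.measure for r in compute_all(s)}
        assert codes == {"D", "R", "ACI", "RCI", "SII", "RII", "PAR", "PAF"}
        assert len(compute_all(s)) == 8

    def test_cardinality_nonordered(self):
        s = make_series([40, 50, 60])
        codes = {r.measure for r in compute_all(s)}
        assert codes == {"D", "R", "MDMU", "MDMW", "IDISU", "IDISW",
                         "BGV", "BGSD", "COV", "TI", "PAR", "PAF"}
        assert len(compute_all(s)) == 12

    def test_measure_subset(self):
        s = make_series([40, 50, 60])
        results = compute_all(s, measures=["D", "TI"])
        assert sorted(r.measure for r in results) == ["D", "TI"]

    def test_with_ci(self):
        s = make_series([40, 50, 60], ses=[1.0] * 3)
        results = compute_all(s, ci=CIConfig(seed=0, bootstrap_reps=200))
        for r in results:
            if r.defined:
                assert r.ci_lower is not None, r.measure


class TestResultsTable:
    def test_long_format(self, rng):
        series = [random_series(rng) for _ in range(3)]
        pairs = [(s, compute_all(s)) for s in series]
        df = results_table(pairs)
        assert len(df) == 36  # 3 settings x 12 nonordered measures
        assert {"setting", "measure", "estimate", "defined"} <= set(df.columns)

    def test_no_series_silently_dropped(self, rng):
        series = [random_series(rng, dimension_type=d)
                  for d in ("binary", "ordered", "nonordered")]
        df = results_table([(s, compute_all(s)) for s in series])
        assert set(df["setting"]) == {s.setting for s in series}


class TestCorrelations:
    def _table(self, rng, n=30):
        series = []
        for i in range(n):
            s = random_series(rng)
            s.setting = f"c{i}"
            series.append(s)
        return results_table([(s, compute_all(s)) for s in series])

    def test_self_correlation(self, rng):
        out = correlate_measures(self._table(rng))
        rho = out.correlations
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)
        assert out.correlation_classes.loc["D", "D"] == "very strong"

    def test_bgv_bgsd_exactly_one(self, rng):
        out = correlate_measures(self._table(rng))
        assert out.correlations.loc["BGV", "BGSD"] == pytest.approx(1.0)

    def test_matrix_symmetric(self, rng):
        rho = correlate_measures(self._table(rng)).correlations.to_numpy()
        assert np.allclose(rho, rho.T, equal_nan=True)

    def test_antimonotone_pair(self):
        rows = []
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0]):
            rows.append({"setting": f"s{i}", "measure": "D", "estimate": v,
                         "defined": True})
            rows.append({"setting": f"s{i}", "measure": "R", "estimate": -v,
                         "defined": True})
        out = correlate_measures(pd.DataFrame(rows))
        assert out.correlations.loc["D", "R"] == pytest.approx(-1.0)
        assert out.correlation_classes.loc["D", "R"] == "very strong"

    def test_small_n_exact_pvalue(self):
        rows = []
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            rows.append({"setting": f"s{i}", "measure": "D", "estimate": v,
                         "defined": True})
            rows.append({"setting": f"s{i}", "measure": "R", "estimate": v**2,
                         "defined": True})
        out = correlate_measures(pd.DataFrame(rows))
        # perfectly concordant, n=4: exact two-sided p = 2/4! = 1/12
        assert out.correlation_pvalues.loc["D", "R"] == pytest.approx(2 / 24)


class TestStrengthClass:
    @pytest.mark.parametrize(
        "rho,label",
        [(1.0, "very strong"), (0.9, "very strong"), (-0.95, "very strong"),
         (0.7, "strong"), (0.89, "strong"), (0.4, "moderate"),
         (-0.5, "moderate"), (0.39, "weak"), (0.0, "weak")],
    )
    def test_thresholds(self, rho, label):
        assert strength_class(rho) == label


class TestSummarize:
    def _table(self):
        rows = []
        for i, v in enumerate([1.0, 2.0, 3.0]):
            rows.append({"setting": f"s{i}", "indicator": "dtp3",
                         "dimension": "region", "measure": "D",
                         "estimate": v, "defined": True,
                         "income_group": "low" if i < 2 else "mid"})
        return pd.DataFrame(rows)

    def test_median_and_iqr(self):
        out = summarize(self._table())
        overall = out[out["income_group"] == "all"].iloc[0]
        assert overall["median"] == pytest.approx(2.0)
        assert overall["q25"] == pytest.approx(1.5)
        assert overall["q75"] == pytest.approx(2.5)

    def test_single_setting_zero_iqr(self):
        df = self._table().iloc[:1]
        out = summarize(df)
        row = out.iloc[0]
        assert row["median"] == row["q25"] == row["q75"] == 1.0

    def test_stratified_recomputation(self):
        out = summarize(self._table())
        low = out[(out["income_group"] == "low")].iloc[0]
        assert low["median"] == pytest.approx(1.5)
        mid = out[(out["income_group"] == "mid")].iloc[0]
        assert mid["median"] == pytest.approx(3.0)

    def test_undefined_rows_ignored(self):
        df = self._table()
        df.loc[2, "defined"] = False
        out = summarize(df)
        overall = out[out["income_group"] == "all"].iloc[0]
        assert overall["n"] == 2
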
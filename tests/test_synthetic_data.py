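import dataclasses

import numpy as np
import pytest

from ineqsum.nonordered_measures import mdmu, mdmw
from ineqsum.ordered_measures import sii
from ineqsum.synthetic_data import (
    SyntheticScenario,
    generate,
    recover_parameters,
    true_series,
)

from ineqsum.io_cli import frame_to_series, series_to_frame


class TestScenario:
    def test_gradient_truth(self):
        sc = SyntheticScenario(effect_shape="linear-gradient", gradient_size=25,
                               base_level=50, n_subgroups=5)
        np.testing.assert_allclose(sc.true_values(),
                                   [37.5, 43.75, 50.0, 56.25, 62.5])

    def test_true_sii_on_gradient(self):
        # extreme gap g over equal-quintile midpoint ranks spanning 0.8
        # gives a fitted slope of g / 0.8
        sc = SyntheticScenario(effect_shape="linear-gradient", gradient_size=20,
                               base_level=50, n_subgroups=5)
        assert sii(true_series(sc)).estimate == pytest.approx(25.0, abs=1e-9)
        sc25 = SyntheticScenario(effect_shape="linear-gradient",
                                 gradient_size=25, base_level=50, n_subgroups=5)
        assert sii(true_series(sc25)).estimate == pytest.approx(31.25, abs=1e-9)

    def test_null_truth(self):
        sc = SyntheticScenario(effect_shape="null", base_level=42)
        assert set(sc.true_values()) == {42.0}

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SyntheticScenario(effect_shape="linear-gradient",
                              gradient_size=80, base_level=90)
        with pytest.raises(ValueError, match="outside"):
            SyntheticScenario(effect_shape="outlier", outlier_offset=60,
                              base_level=50, dimension_type="nonordered")

    def test_bad_params(self):
        with pytest.raises(ValueError):
            SyntheticScenario(effect_shape="quadratic")
        with pytest.raises(ValueError):
            SyntheticScenario(dimension_type="binary", n_subgroups=5)


class TestGenerate:
    def test_seed_determinism(self):
        sc = SyntheticScenario(n_settings=5, noise=500, seed=11)
        a, b = generate(sc), generate(sc)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.estimates, sb.estimates)
            np.testing.assert_array_equal(sa.populations, sb.populations)
        c = generate(dataclasses.replace(sc, seed=12))
        assert not np.array_equal(a[0].estimates, c[0].estimates)

    def test_estimates_in_range_and_shares_sum(self):
        sc = SyntheticScenario(n_settings=20, dimension_type="nonordered",
                               n_subgroups=8, noise=200, seed=3,
                               effect_shape="outlier", base_level=40)
        for s in generate(sc):
            assert np.all((s.estimates >= 0) & (s.estimates <= 100))
            assert s.shares.sum() == pytest.approx(1.0)

    def test_noise_free(self):
        sc = SyntheticScenario(noise=None, seed=0)
        s = generate(sc)[0]
        np.testing.assert_allclose(s.estimates, sc.true_values())
        assert np.all(s.ses == 0.0)

    def test_outlier_share_pinned(self):
        sc = SyntheticScenario(dimension_type="nonordered",
                               effect_shape="outlier", outlier_share=0.01,
                               outlier_offset=40, base_level=50, seed=5)
        s = generate(sc)[0]
        assert s.shares[-1] == pytest.approx(0.01)

    def test_outlier_mdmu_exceeds_mdmw(self):
        sc = SyntheticScenario(dimension_type="nonordered", n_subgroups=10,
                               effect_shape="outlier", outlier_share=0.01,
                               outlier_offset=40, base_level=50, noise=None)
        s = generate(sc)[0]
        assert mdmu(s).estimate > 5 * mdmw(s).estimate

    def test_adverse_zero_dose_yields_exact_zeros(self):
        sc = SyntheticScenario(n_settings=30, dimension_type="nonordered",
                               effect_shape="null", base_level=0.5,
                               favourable=False, noise=200, seed=2)
        ests = np.concatenate([s.estimates for s in generate(sc)])
        assert np.any(ests == 0.0)

    def test_se_matches_binomial_model(self):
        # empirical SD across replicates within 15% of the reported SE
        n_eff = 10_000
        sc = SyntheticScenario(n_settings=400, effect_shape="null",
                               base_level=50, noise=n_eff, seed=9,
                               share_concentration=None)
        series = generate(sc)
        ests = np.array([s.estimates[0] for s in series])
        reported = np.median([s.ses[0] for s in series])
        assert abs(ests.std(ddof=1) - reported) / reported < 0.15

    def test_binary_labels(self):
        sc = SyntheticScenario(dimension_type="binary", n_subgroups=2,
                               noise=None)
        s = generate(sc)[0]
        assert s.labels == ["rural", "urban"]
        assert s.dimension_type == "binary"


class TestRoundTrip:
    def test_writer_reader_round_trip(self, tmp_path):
        sc = SyntheticScenario(n_settings=4, dimension_type="ordered",
                               noise=300, seed=21)
        series = generate(sc)
        path = tmp_path / "synthetic.csv"
        from ineqsum.io_cli import read_disaggregated, write_disaggregated

        write_disaggregated(series, path)
        back = read_disaggregated(path)
        assert len(back) == len(series)
        for a, b in zip(series, back):
            np.testing.assert_allclose(a.estimates, b.estimates)
            np.testing.assert_allclose(a.populations, b.populations)
            assert a.labels == b.labels


class TestRecovery:
    def test_d_unbiased_on_gradient(self):
        sc = SyntheticScenario(effect_shape="linear-gradient", gradient_size=20,
                               noise=2000, seed=17, n_settings=2)
        report = recover_parameters(sc, measures=["D"], n_reps=50)
        assert abs(report.loc["D", "bias"]) < 1.0

    def test_bgv_positive_bias_on_null_shrinks_with_n(self):
        biases = []
        for n_eff in (100, 10_000):
            sc = SyntheticScenario(dimension_type="nonordered",
                                   effect_shape="null", base_level=50,
                                   noise=n_eff, seed=31, n_settings=2)
            report = recover_parameters(sc, measures=["BGV"], n_reps=60)
            biases.append(report.loc["BGV", "bias"])
        assert biases[0] > biases[1] > 0.0

    def test_report_shape(self):
        sc = SyntheticScenario(seed=1)
        report = recover_parameters(sc, measures=["D", "SII", "ACI"], n_reps=5)
        assert set(report.index) == {"D", "SII", "ACI"}
        assert {"truth", "mean", "bias", "rmse", "n_defined"} <= set(report.columns)
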
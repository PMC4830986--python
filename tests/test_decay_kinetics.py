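"""Pseudo-first-order decay fitting, model selection and bench summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nitrodust import (
    DecayScenario,
    DecaySeries,
    degradation_percent,
    dnp_flag,
    fit_plateau_decay,
    fit_simple_decay,
    generate_decay_series,
    product_yield,
    read_decay_csv,
    select_decay_model,
    write_decay_csv,
)


def series_from_model(k, p=0.0, times=(0, 600, 1800, 3600, 7200), scale=1.0):
    pts = [
        (float(t), scale * (p + (1 - p) * np.exp(-k * t)), "r1") for t in times
    ]
    return DecaySeries(substrate="test", points=pts)


class TestSimpleFit:
    def test_noiseless_generative_identity(self):
        fit = fit_simple_decay(series_from_model(1.0e-3))
        assert fit.k_obs == pytest.approx(1.0e-3, rel=1e-6)
        assert fit.model == "simple"
        assert fit.plateau == 0.0

    def test_constant_data_gives_zero_rate(self):
        s = DecaySeries("flat", points=[(t, 1.0, "r1") for t in (0, 600, 1800, 3600)])
        with pytest.warns(UserWarning, match="identical"):
            fit = fit_simple_decay(s)
        assert fit.k_obs == 0.0

    def test_mean_recovery_under_noise(self):
        ks = []
        for seed in range(200):
            sc = DecayScenario(k_true=8.6e-4, noise_cv=0.05, replicates=3, seed=seed)
            ks.append(fit_simple_decay(generate_decay_series(sc)).k_obs)
        assert np.mean(ks) == pytest.approx(8.6e-4, rel=0.02)

    @given(k=st.floats(1e-5, 5e-3))
    def test_noiseless_recovery_over_rate_range(self, k):
        fit = fit_simple_decay(series_from_model(k, times=(0, 300, 1200, 3600, 9000)))
        assert fit.k_obs == pytest.approx(k, rel=1e-6)


class TestPlateauFit:
    def test_noiseless_generative_identity(self):
        fit = fit_plateau_decay(series_from_model(2.9e-4, p=0.16))
        assert fit.k_obs == pytest.approx(2.9e-4, rel=1e-6)
        assert fit.plateau == pytest.approx(0.16, abs=1e-6)

    def test_nested_limit_matches_simple(self):
        s = series_from_model(5e-4, p=0.0)
        k_simple = fit_simple_decay(s).k_obs
        fit = fit_plateau_decay(s)
        assert fit.k_obs == pytest.approx(k_simple, rel=1e-5)
        assert fit.plateau == pytest.approx(0.0, abs=1e-5)

    def test_pinned_plateau_is_flagged(self):
        # rising "decay" forces the plateau against its lower bound
        pts = [(0.0, 1.0, "r1"), (600.0, 1.1, "r1"), (1800.0, 1.3, "r1"),
               (3600.0, 1.6, "r1"), (7200.0, 2.0, "r1")]
        with pytest.warns(UserWarning):
            s = DecaySeries("rising", points=pts)
            fit = fit_plateau_decay(s)
        assert fit.plateau_pinned

    def test_plateau_rss_never_exceeds_simple_rss(self):
        for seed in range(10):
            sc = DecayScenario(k_true=5e-4, plateau_true=0.2, noise_cv=0.05, seed=seed)
            s = generate_decay_series(sc)
            assert fit_plateau_decay(s).rss <= fit_simple_decay(s).rss + 1e-12

    def test_median_plateau_bias_small(self):
        ps = [
            fit_plateau_decay(
                generate_decay_series(
                    DecayScenario(
                        k_true=2.9e-4, plateau_true=0.16, noise_cv=0.05, seed=seed
                    )
                )
            ).plateau
            for seed in range(100)
        ]
        assert abs(np.median(ps) - 0.16) <= 0.03

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError, match="4 distinct times"):
            fit_plateau_decay(series_from_model(1e-3, times=(0, 600, 3600)))


class TestModelSelection:
    def test_no_plateau_data_selects_simple(self):
        fit = select_decay_model(series_from_model(8.6e-4, p=0.0))
        assert fit.model == "simple"

    def test_plateau_data_selects_plateau(self):
        wins = 0
        for seed in range(20):
            sc = DecayScenario(k_true=2.9e-4, plateau_true=0.3, noise_cv=0.01, seed=seed)
            if select_decay_model(generate_decay_series(sc)).model == "plateau":
                wins += 1
        assert wins >= 19

    def test_three_point_series_forces_simple(self):
        s = series_from_model(1e-3, p=0.3, times=(0, 1800, 7200))
        with pytest.warns(UserWarning, match="distinct times"):
            fit = select_decay_model(s)
        assert fit.model == "simple"


class TestNormalization:
    def test_k_invariant_under_common_rescaling(self):
        base = series_from_model(7e-4)
        with pytest.warns(UserWarning, match="above 1"):
            scaled = series_from_model(7e-4, scale=2.3)
        k1 = fit_simple_decay(base, normalize=True).k_obs
        k2 = fit_simple_decay(scaled, normalize=True).k_obs
        assert k2 == pytest.approx(k1, rel=1e-8)


class TestBenchSummaries:
    def test_degradation_percent_examples(self):
        s = DecaySeries(
            "cdd", points=[(0, 1.0, "r1"), (3600, 0.2, "r1"), (7200, 0.04, "r1")]
        )
        assert degradation_percent(s, 7200) == pytest.approx(96.0)
        flat = DecaySeries("q", points=[(0, 1.0, "r1"), (3600, 1.0, "r1"), (7200, 1.0, "r1")])
        assert degradation_percent(flat, 7200) == pytest.approx(0.0)

    def test_degradation_averages_replicates(self):
        pts = [(0, 1.0, "r1"), (3600, 0.5, "r1")]
        pts += [(7200, f, r) for f, r in [(0.10, "r1"), (0.12, "r2"), (0.14, "r3")]]
        assert degradation_percent(DecaySeries("m", points=pts), 7200) == pytest.approx(88.0)

    def test_missing_time_is_error_not_interpolation(self):
        s = series_from_model(1e-3, times=(0, 600, 3600))
        with pytest.raises(ValueError, match="interpolate"):
            degradation_percent(s, 7200)

    def test_product_yield_and_species_listing(self):
        s = series_from_model(1e-3)
        s.product_points = [(7200.0, "1-NP", 0.53, "r1")]
        assert product_yield(s, "1-NP", 7200) == pytest.approx(53.0)
        with pytest.raises(ValueError, match="1-NP"):
            product_yield(s, "DNP", 7200)

    def test_dnp_flag_threshold(self):
        s = series_from_model(1e-3)
        s.product_points = [(43200.0, "DNP", 0.02, "r1")]
        assert dnp_flag(s) == "+"
        s.product_points = [(43200.0, "DNP", 0.001, "r1")]
        assert dnp_flag(s) == "-"
        s.product_points = []
        assert dnp_flag(s) == "-"


class TestSeriesValidation:
    def test_fraction_above_one_warns_not_rejects(self):
        with pytest.warns(UserWarning, match="above 1"):
            DecaySeries("n", points=[(0, 1.05, "r1"), (600, 0.9, "r1"), (1800, 0.5, "r1")])

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            DecaySeries("n", points=[(-1, 1.0, "r1"), (600, 0.9, "r1"), (1800, 0.5, "r1")])


def test_decay_csv_round_trip(tmp_path):
    series = [
        generate_decay_series(DecayScenario(seed=1, substrate="dustA", no2_ppmv=3.0)),
        generate_decay_series(DecayScenario(seed=2, substrate="dustB", no2_ppmv=6.0)),
    ]
    path = tmp_path / "decay.csv"
    write_decay_csv(series, path)
    back = read_decay_csv(path)
    assert len(back) == 2
    by_name = {s.substrate: s for s in back}
    for orig in series:
        got = by_name[orig.substrate]
        np.testing.assert_allclose(got.times, orig.times, rtol=0, atol=0)
        np.testing.assert_allclose(got.fractions, orig.fractions, rtol=1e-15)
        assert got.conditions.ppmv == pytest.approx(orig.conditions.ppmv)
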
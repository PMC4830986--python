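"""Langmuir-Hinshelwood / N2O4 mechanism fits, prediction and discrimination."""

import numpy as np
import pytest

from nitrodust import (
    GasConditions,
    RateCurve,
    apparent_reaction_order,
    compare_mechanisms,
    fit_lh_no2,
    fit_n2o4,
    generate_rate_curve,
    predict_k_obs,
)
from nitrodust.mechanism_fitting import (
    read_rate_curve_csv,
    write_rate_curve_csv,
)

K_MAX, K_LH = 1.0e-3, 2.0e-20  # s^-1, m^3
K_N2O4 = 4.0e-40  # m^6 (lumped dimerization x gas-to-surface constant)


class TestGenerativeIdentity:
    def test_lh_noiseless_recovery(self, lab_concentrations_m3):
        curve = generate_rate_curve("LH_NO2", K_MAX, K_LH, lab_concentrations_m3)
        fit = fit_lh_no2(curve)
        assert fit.k_max == pytest.approx(K_MAX, rel=1e-6)
        assert fit.K == pytest.approx(K_LH, rel=1e-6)

    def test_n2o4_noiseless_recovery(self, lab_concentrations_m3):
        curve = generate_rate_curve("N2O4", K_MAX, K_N2O4, lab_concentrations_m3)
        fit = fit_n2o4(curve)
        assert fit.k_max == pytest.approx(K_MAX, rel=1e-6)
        assert fit.K == pytest.approx(K_N2O4, rel=1e-6)

    def test_prediction_reproduces_generating_values(self, lab_concentrations_m3):
        curve = generate_rate_curve("LH_NO2", K_MAX, K_LH, lab_concentrations_m3)
        fit = fit_lh_no2(curve)
        for c, k in zip(curve.concentrations, curve.k_obs):
            assert predict_k_obs(fit, c)[0] == pytest.approx(k, rel=1e-6)


class TestLimits:
    def test_low_concentration_regime_is_linear(self, lab_concentrations_m3):
        fit = fit_lh_no2(
            generate_rate_curve("LH_NO2", K_MAX, K_LH, lab_concentrations_m3)
        )
        c = 1e-8 / K_LH  # K c = 1e-8 << 1
        assert predict_k_obs(fit, c)[0] == pytest.approx(
            fit.k_max * fit.K * c, rel=1e-6
        )

    def test_prediction_at_zero_and_saturation(self, lab_concentrations_m3):
        fit = fit_lh_no2(
            generate_rate_curve("LH_NO2", K_MAX, K_LH, lab_concentrations_m3)
        )
        value, se = predict_k_obs(fit, 0.0)
        assert value == 0.0 and se == 0.0
        assert predict_k_obs(fit, 1e12 / K_LH)[0] == pytest.approx(
            fit.k_max, rel=1e-9
        )

    @pytest.mark.parametrize(
        "model,K,c_factor,expected",
        [
            ("LH_NO2", K_LH, 1e-6, 1.0),  # K c << 1
            ("LH_NO2", K_LH, 1e6, 0.0),  # K c >> 1
            ("N2O4", K_N2O4, 1e-6, 2.0),  # K' c^2 << 1 (factor applied to c)
            ("N2O4", K_N2O4, 1e6, 0.0),
        ],
    )
    def test_apparent_reaction_order_limits(
        self, lab_concentrations_m3, model, K, c_factor, expected
    ):
        curve = generate_rate_curve(model, K_MAX, K, lab_concentrations_m3)
        fit = {"LH_NO2": fit_lh_no2, "N2O4": fit_n2o4}[model](curve)
        c = c_factor / K if model == "LH_NO2" else np.sqrt(c_factor**2 / K)
        assert apparent_reaction_order(fit, c) == pytest.approx(expected, abs=1e-4)

    def test_curves_increasing_and_bounded(self, lab_concentrations_m3):
        fit = fit_lh_no2(
            generate_rate_curve("LH_NO2", K_MAX, K_LH, lab_concentrations_m3)
        )
        cs = np.geomspace(1e16, 1e22, 30)
        vals = np.array([predict_k_obs(fit, c)[0] for c in cs])
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals <= fit.k_max)


class TestUncertainty:
    def test_delta_method_matches_parametric_bootstrap(self, lab_concentrations_m3, rng):
        fit = fit_lh_no2(
            generate_rate_curve(
                "LH_NO2", K_MAX, K_LH, lab_concentrations_m3, noise_cv=0.10, seed=7
            )
        )
        c0 = GasConditions.from_ppbv(100.0).number_density
        _, se = predict_k_obs(fit, c0)
        draws = rng.multivariate_normal([fit.k_max, fit.K], fit.covariance, size=100_000)
        boot = draws[:, 0] * draws[:, 1] * c0 / (1.0 + draws[:, 1] * c0)
        assert se == pytest.approx(boot.std(), rel=0.10)

    def test_kmax_bias_small_under_noise(self, lab_concentrations_m3):
        kmaxes = [
            fit_lh_no2(
                generate_rate_curve(
                    "LH_NO2", K_MAX, K_LH, lab_concentrations_m3, noise_cv=0.10, seed=s
                )
            ).k_max
            for s in range(200)
        ]
        assert abs(np.mean(kmaxes) / K_MAX - 1.0) < 0.05

    def test_covariance_symmetric_psd(self, lab_concentrations_m3):
        fit = fit_lh_no2(
            generate_rate_curve(
                "LH_NO2", K_MAX, K_LH, lab_concentrations_m3, noise_cv=0.10, seed=3
            )
        )
        C = fit.covariance
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) >= -1e-30)


class TestDiscrimination:
    def test_wrong_model_fits_worse_on_noisy_lh_data(self, lab_concentrations_m3):
        worse = 0
        for seed in range(200):
            curve = generate_rate_curve(
                "LH_NO2", K_MAX, K_LH, lab_concentrations_m3, noise_cv=0.10, seed=seed
            )
            if fit_n2o4(curve).rss >= fit_lh_no2(curve).rss:
                worse += 1
        assert worse >= 190  # the wrong model loses in >= 95% of replicates

    def test_n2o4_truth_preferred_by_aicc(self, lab_concentrations_m3):
        hits = 0
        for seed in range(20):
            curve = generate_rate_curve(
                "N2O4", K_MAX, K_N2O4, lab_concentrations_m3, noise_cv=0.10, seed=seed
            )
            if compare_mechanisms(curve)["preferred_by_aicc"] == "N2O4":
                hits += 1
        assert hits >= 18

    def test_report_is_deterministic(self, lab_concentrations_m3):
        curve = generate_rate_curve(
            "LH_NO2", K_MAX, K_LH, lab_concentrations_m3, noise_cv=0.10, seed=11
        )
        assert compare_mechanisms(curve) == compare_mechanisms(curve)

    def test_comparison_needs_four_concentrations(self):
        curve = RateCurve("x", np.array([1e19, 2e19, 4e19]), np.array([1e-4, 2e-4, 3e-4]))
        with pytest.raises(ValueError, match="4 distinct"):
            compare_mechanisms(curve)


class TestValidationAndIO:
    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            RateCurve("x", np.array([1e19, 1e19]), np.array([1e-4, 1e-4]))

    def test_negative_prediction_concentration_rejected(self, lab_concentrations_m3):
        fit = fit_lh_no2(
            generate_rate_curve("LH_NO2", K_MAX, K_LH, lab_concentrations_m3)
        )
        with pytest.raises(ValueError):
            predict_k_obs(fit, -1.0)

    def test_rate_curve_csv_round_trip(self, tmp_path, lab_concentrations_m3):
        curves = [
            generate_rate_curve(
                "LH_NO2", K_MAX, K_LH, lab_concentrations_m3, noise_cv=0.05, seed=1,
                substrate="dustA",
            )
        ]
        path = tmp_path / "rates.csv"
        write_rate_curve_csv(curves, path)
        back = read_rate_curve_csv(path)
        assert back[0].substrate == "dustA"
        np.testing.assert_allclose(
            back[0].concentrations, curves[0].concentrations, rtol=1e-12
        )
        np.testing.assert_allclose(back[0].k_obs, curves[0].k_obs, rtol=1e-12)
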
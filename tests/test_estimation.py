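from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from daphnia_ifd.estimation import (
    DataError,
    compare_response_types,
    estimate_perception_cost,
    fit_functional_response,
    fit_growth_model,
    fit_reaction_distance_model,
    scale_gamma_for_age,
    to_per_capita_risk,
)
from daphnia_ifd.generate import (
    default_consumption_spec,
    default_growth_spec,
    default_rd_spec,
    gen_consumption,
    gen_growth,
    gen_rd,
)
from daphnia_ifd.rates import FunctionalResponseParams, consumption_rate


def _noiseless(spec):
    return replace(spec, noise_sd=0.0)


class TestFunctionalResponse:
    @pytest.mark.parametrize("rtype", ["II", "III"])
    def test_noiseless_recovery(self, rtype):
        spec = _noiseless(default_consumption_spec(0, rtype))
        fit = fit_functional_response(gen_consumption(spec), rtype)
        true = spec.true_params
        expected = {"attack": true.attack, "handling": true.handling,
                    "gamma": true.gamma, "n": true.n}
        for name, est in zip(fit.param_names, fit.estimates):
            assert est == pytest.approx(expected[name], rel=1e-6, abs=1e-9)

    def test_nesting_type_ii_sse_at_least_type_iii(self):
        data = gen_consumption(default_consumption_spec(4, "III"))
        f2 = fit_functional_response(data, "II")
        f3 = fit_functional_response(data, "III")
        assert f2.sse >= f3.sse - 1e-9

    def test_misfit_type_ii_on_threshold_data(self):
        spec = _noiseless(default_consumption_spec(0, "III"))
        data = gen_consumption(spec)
        f2 = fit_functional_response(data, "II")
        f3 = fit_functional_response(data, "III")
        assert f3.sse < 1e-12
        assert f2.sse > 1e3 * max(f3.sse, 1e-12)

    def test_zero_consumption_below_cutoff_forces_positive_gamma(self):
        N = np.array([1, 2, 3, 4, 6, 8, 12, 20, 30, 50], dtype=float)
        true = FunctionalResponseParams(attack=24, handling=0.005, gamma=3.4158,
                                        n=2, type="III")
        data = pd.DataFrame({"prey_density": N,
                             "consumption": consumption_rate(N, true)})
        fit = fit_functional_response(data, "III")
        assert fit.estimates[fit.param_names.index("gamma")] > 0

    def test_insufficient_data_rejected(self):
        small = pd.DataFrame({"prey_density": [1, 2, 3], "consumption": [1, 2, 3]})
        with pytest.raises(DataError):
            fit_functional_response(small, "II")

    def test_equal_fits_select_simpler_type(self):
        # noiseless type II data: both models fit at machine error, so
        # parsimony keeps type II
        data = gen_consumption(_noiseless(default_consumption_spec(0, "II")))
        sel = compare_response_types(
            fit_functional_response(data, "II"),
            fit_functional_response(data, "III"),
            len(data),
        )
        assert sel.selected == "II"
        assert sel.F == 0.0

    def test_threshold_data_select_type_iii(self):
        data = gen_consumption(default_consumption_spec(8, "III"))
        sel = compare_response_types(
            fit_functional_response(data, "II"),
            fit_functional_response(data, "III"),
            len(data),
        )
        assert sel.selected == "III"
        assert sel.p < 0.05
        assert sel.aic_III < sel.aic_II


class TestPerCapitaRisk:
    def test_elementwise_division_and_zero_drop(self):
        data = pd.DataFrame({"prey_density": [0.0, 10.0], "consumption": [1.0, 5.0]})
        with pytest.warns(UserWarning):
            out = to_per_capita_risk(data)
        assert len(out) == 1
        assert out["per_capita_risk"].iloc[0] == pytest.approx(0.5)

    def test_fitted_curve_shapes(self):
        N = np.linspace(0.5, 60, 200)
        ii = FunctionalResponseParams(attack=24, handling=0.005)
        risk_ii = consumption_rate(N, ii) / N
        assert np.all(np.diff(risk_ii) < 0)
        iii = FunctionalResponseParams(attack=24, handling=0.005, gamma=3.4158,
                                       n=2, type="III")
        risk_iii = consumption_rate(N, iii) / N
        assert np.all(risk_iii[N <= 3.4158] == 0)
        peak = int(np.argmax(risk_iii))
        assert 0 < peak < len(N) - 1


class TestGammaScaling:
    @pytest.mark.parametrize(
        "gamma,orders,expected",
        [(3.4158, 2, 0.0342), (5.0, 0, 5.0), (0.0, 3, 0.0)],
    )
    def test_examples(self, gamma, orders, expected):
        assert scale_gamma_for_age(gamma, orders) == expected


class TestGrowthFit:
    def test_noiseless_recovery(self):
        spec = _noiseless(default_growth_spec(0))
        fit = fit_growth_model(gen_growth(spec))
        true = spec.true_params
        for name, est in zip(fit.param_names, fit.estimates):
            assert est == pytest.approx(getattr(true, name), rel=1e-6)

    def test_single_food_level_design_unidentifiable(self):
        spec = replace(default_growth_spec(0),
                       design={"food": [0.8], "replicates": 4})
        with pytest.raises(DataError):
            fit_growth_model(gen_growth(spec))

    def test_food_only_design_drops_other_terms(self):
        spec = replace(
            default_growth_spec(0),
            design={"food": [0.05, 0.1, 0.2, 0.4, 0.8, 1.6], "replicates": 3},
        )
        fit = fit_growth_model(gen_growth(spec))
        assert set(fit.param_names) == {"g0", "a1", "a2"}
        assert set(fit.extras["dropped_terms"]) == {"b", "c", "u", "kappa"}
        with pytest.raises(DataError):
            fit_growth_model(gen_growth(spec), require_full=True)

    def test_planted_interaction_detected(self):
        fit = fit_growth_model(gen_growth(default_growth_spec(42)))
        assert fit.wald_p("u") < 0.05


class TestReactionDistanceFit:
    def test_noiseless_recovery(self):
        spec = _noiseless(default_rd_spec(0))
        fit = fit_reaction_distance_model(gen_rd(spec))
        true = spec.true_params
        for name, est in zip(fit.param_names, fit.estimates):
            assert est == pytest.approx(getattr(true, name), rel=1e-6, abs=1e-8)

    def test_band_contrasts(self):
        fit = fit_reaction_distance_model(gen_rd(default_rd_spec(7)))
        assert fit.extras["p_red_vs_green"] < 0.05  # alpha = 0.6 planted
        assert fit.extras["p_blue_vs_green"] > 0.05  # phi = 1 (no effect)

    def test_flat_light_slope_ci_covers_zero(self):
        from daphnia_ifd.rates import RDParams

        spec = replace(default_rd_spec(3), true_params=RDParams(r0=2.0, k=0.0),
                       noise_sd=0.2)
        fit = fit_reaction_distance_model(gen_rd(spec))
        assert fit.wald_p("k") > 0.05


class TestPerceptionCost:
    def test_identical_arms_zero_slowdown(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0.3, 0.01, 40)
        data = pd.DataFrame({
            "arrangement": ["homogeneous"] * 20 + ["gradient"] * 20,
            "growth_rate": np.concatenate([g[:20], g[:20]]),
        })
        res = estimate_perception_cost(data)
        assert res.percent_slowdown == pytest.approx(0.0, abs=1e-9)

    def test_planted_deficit_recovered(self):
        from daphnia_ifd.generate import (
            default_paired_growth_spec,
            gen_paired_growth,
        )

        res = estimate_perception_cost(
            gen_paired_growth(default_paired_growth_spec(5))
        )
        assert res.ci_low < 9.2 < res.ci_high
        assert res.p < 0.05
        assert res.sd_gradient > res.sd_homogeneous
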
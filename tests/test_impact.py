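import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import landcarbon as lc
from landcarbon.io import ValidationError


def brute_force_flows(areas, eff, matrix):
    """Independent oracle: loop over ordered pairs, ledger both endpoints."""
    order = list(matrix.class_order)
    zr = {c: 0.0 for c in order}
    zc = {c: 0.0 for c in order}
    for i, src in enumerate(order):
        for q, dst in enumerate(order):
            if i == q:
                continue
            delta = eff[dst] - eff[src]
            flow = areas[src] * delta * matrix.probs[i, q]
            zr[dst] += flow      # inbound ledger of the destination
            zc[src] += flow      # outbound ledger of the source
    return pd.Series(zr), pd.Series(zc)


def random_instance(rng, n):
    probs = rng.dirichlet(np.ones(n), size=n)
    order = tuple(f"c{i}" for i in range(n))
    matrix = lc.TransitionMatrix(probs, class_order=order)
    areas = pd.Series(rng.uniform(10, 1e5, n), index=order)
    eff = pd.Series(rng.uniform(0, 600, n), index=order)
    return areas, eff, matrix


class TestTransferEquations:
    def test_identity_matrix_gives_zero_everywhere(self, two_class_impact_toy):
        areas, eff, _ = two_class_impact_toy
        ident = lc.TransitionMatrix(np.eye(2), class_order=("A", "B"))
        bd = lc.total_impact(areas, eff, ident)
        np.testing.assert_allclose(bd.subtotal, 0.0)
        assert bd.gtyx == 0.0

    def test_two_class_hand_arithmetic(self, two_class_impact_toy):
        areas, eff, matrix = two_class_impact_toy
        # ZR_A = S_B x (e_A - e_B) x a(B,A) = 200 x 250 x 0.05
        assert lc.transfer_in("A", areas, eff, matrix) == pytest.approx(2500.0)
        # ZC_A = S_A x (e_B - e_A) x a(A,B) = 100 x (-250) x 0.1
        assert lc.transfer_out("A", areas, eff, matrix) == pytest.approx(-2500.0)

    def test_symmetric_toy_totals_cancel(self, two_class_impact_toy):
        # ZR_A=2500, ZC_A=-2500, ZR_B=-2500, ZC_B=2500: pairwise cancellation
        areas, eff, matrix = two_class_impact_toy
        bd = lc.total_impact(areas, eff, matrix)
        assert bd.gtyx == pytest.approx(0.0, abs=1e-9)

    def test_equal_effective_densities_force_zero(self, two_class_impact_toy):
        areas, _, matrix = two_class_impact_toy
        eff = pd.Series({"A": 321.0, "B": 321.0})
        assert lc.total_impact(areas, eff, matrix).gtyx == pytest.approx(0.0)

    def test_missing_density_for_inbound_class_errors(self, two_class_impact_toy):
        areas, _, matrix = two_class_impact_toy
        eff = pd.Series({"A": 500.0, "B": np.nan})
        with pytest.raises(ValidationError, match="density"):
            lc.transfer_in("A", areas, eff, matrix)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_vectorized_equals_brute_force_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            areas, eff, matrix = random_instance(rng, n)
            zr_o, zc_o = brute_force_flows(areas, eff, matrix)
            bd = lc.total_impact(areas, eff, matrix)
            np.testing.assert_allclose(bd.zr, zr_o, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(bd.zc, zc_o, rtol=1e-9, atol=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_sum_zr_equals_sum_zc_on_any_input(self, seed):
        rng = np.random.default_rng(seed)
        areas, eff, matrix = random_instance(rng, 3)
        bd = lc.total_impact(areas, eff, matrix)
        assert bd.zr.sum() == pytest.approx(bd.zc.sum(), rel=1e-9, abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100))
    def test_gtyx_linear_in_uniform_area_scaling(self, scale):
        rng = np.random.default_rng(7)
        areas, eff, matrix = random_instance(rng, 4)
        base = lc.total_impact(areas, eff, matrix).gtyx
        scaled = lc.total_impact(areas * scale, eff, matrix).gtyx
        assert scaled == pytest.approx(base * scale, rel=1e-9)

    def test_gtyx_equals_sum_of_subtotals(self):
        rng = np.random.default_rng(3)
        areas, eff, matrix = random_instance(rng, 4)
        bd = lc.total_impact(areas, eff, matrix)
        assert bd.gtyx == pytest.approx(bd.subtotal.sum(), rel=1e-12)


class TestEffectiveDensity:
    def test_effective_is_rho_times_one_plus_beta(self):
        e = lc.EffectiveDensity("forest", rho=500.0, beta=0.04)
        assert e.effective == pytest.approx(520.0)

    def test_negative_rho_rejected(self):
        with pytest.raises(ValidationError):
            lc.EffectiveDensity("forest", rho=-1.0)

    def test_series_fills_unlisted_classes_with_defaults(self):
        eff = lc.effective_density_series(
            {"a": 100.0}, {"a": 0.1}, class_order=("a", "b"),
        )
        assert eff["a"] == pytest.approx(110.0)
        assert eff["b"] == 0.0


class TestFixtureMode:
    @pytest.mark.parametrize(
        "fixture,year,total,tol",
        [
            ("table9_impacts", 2025, -20753.69, 1.0),
            ("table9_impacts", 2030, -30837.03, 1.0),
            ("table11_impacts", 2021, -82226.0, 1.0),
            ("table11_impacts", 2022, -45892.0, 0.5),
        ],
    )
    def test_aggregating_printed_components_reproduces_totals(
        self, fixture, year, total, tol
    ):
        df = lc.load_fixture(fixture)
        sub = df[df["year"] == year].set_index("class")
        bd = lc.ImpactBreakdown.from_components(
            sub["zr_t"], sub["zc_t"], subtotals=sub["subtotal_t"]
        )
        assert bd.gtyx == pytest.approx(total, abs=tol)

    def test_mismatched_component_class_sets_error(self):
        with pytest.raises(ValidationError, match="differ"):
            lc.ImpactBreakdown.from_components({"a": 1.0}, {"b": 1.0})


class TestTotalWithImpact:
    def test_zero_impact_is_pure_standing_stock(self):
        areas = {"a": 100.0}
        dens = {"a": 500.0}
        assert lc.total_with_impact(areas, dens, 0.0) == pytest.approx(5.0)

    def test_impact_term_added_in_1e4t(self):
        areas = {"a": 1000.0}
        dens = {"a": 500.0}
        assert lc.total_with_impact(areas, dens, -20000.0) == pytest.approx(48.0)

    def test_suspiciously_small_impact_warns(self):
        with pytest.warns(UserWarning, match="tons"):
            lc.total_with_impact({"a": 1e5}, {"a": 500.0}, -2.0)


@pytest.fixture(scope="module")
def synthetic_history():
    spec = {
        "high": {"area": (1000.0, -5.0, 0.0), "density": (500.0, 2.0, 0.0)},
        "low": {"area": (2000.0, 5.0, 0.0), "density": (100.0, 1.0, 0.0)},
    }
    scenario = lc.SyntheticScenario(
        true_matrix=np.eye(9), class_shares=np.full(9, 1 / 9), seed=1,
        trend_spec=spec,
    )
    return lc.generate_account_series(scenario, 21, start_year=2000)


class TestScenario:
    def test_identity_matrix_scenario_is_pure_standing_stock(
        self, synthetic_history
    ):
        matrix = lc.TransitionMatrix(np.eye(2), class_order=("high", "low"))
        cfg = lc.ScenarioConfig(
            override_spec=(),
            arima_orders={(c, q): (0, 1, 0) for c in ("high", "low")
                          for q in ("area", "density")},
        )
        res = lc.run_scenario(synthetic_history, matrix, 2025, cfg)
        assert res.breakdown.gtyx == pytest.approx(0.0, abs=1e-9)
        areas = res.forecasts.per_class("area", 2025)
        dens = res.forecasts.per_class("density", 2025)
        assert res.total_1e4t == pytest.approx(
            lc.total_standing_stock(areas, dens)
        )

    def test_dominant_flow_direction_sets_gtyx_sign(self, synthetic_history):
        # all movement is high-density -> low-density, so the impact is negative
        matrix = lc.TransitionMatrix(
            np.array([[0.8, 0.2], [0.0, 1.0]]), class_order=("high", "low")
        )
        cfg = lc.ScenarioConfig(
            override_spec=(),
            arima_orders={(c, q): (0, 1, 0) for c in ("high", "low")
                          for q in ("area", "density")},
        )
        res = lc.run_scenario(synthetic_history, matrix, 2025, cfg)
        assert res.breakdown.gtyx < 0
        # and the reverse flow is favourable
        rev = lc.TransitionMatrix(
            np.array([[1.0, 0.0], [0.2, 0.8]]), class_order=("high", "low")
        )
        res_rev = lc.run_scenario(synthetic_history, rev, 2025, cfg)
        assert res_rev.breakdown.gtyx > 0

    def test_fitted_betas_match_noiseless_trends(self, synthetic_history):
        matrix = lc.TransitionMatrix(np.eye(2), class_order=("high", "low"))
        cfg = lc.ScenarioConfig(
            override_spec=(),
            arima_orders={(c, q): (0, 1, 0) for c in ("high", "low")
                          for q in ("area", "density")},
        )
        res = lc.run_scenario(synthetic_history, matrix, 2025, cfg)
        # density(2020) = 500 + 2x20 = 540; beta = 2x5/540
        assert res.betas["high"] == pytest.approx(10 / 540, rel=1e-9)
        assert res.betas["low"] == pytest.approx(5 / 120, rel=1e-9)

    def test_model_facade_matches_run_scenario(self, synthetic_history):
        matrix = lc.TransitionMatrix(
            np.array([[0.9, 0.1], [0.1, 0.9]]), class_order=("high", "low")
        )
        orders = {(c, q): (0, 1, 0) for c in ("high", "low")
                  for q in ("area", "density")}
        model = lc.CarbonImpactModel(
            override_spec=(), arima_orders=orders
        ).fit(synthetic_history, matrix)
        total = model.predict(2025)
        res = lc.run_scenario(
            synthetic_history, matrix, 2025,
            lc.ScenarioConfig(override_spec=(), arima_orders=orders),
        )
        assert total == pytest.approx(res.total_1e4t, rel=1e-12)

    def test_explicit_beta_source(self, synthetic_history):
        matrix = lc.TransitionMatrix(
            np.array([[0.9, 0.1], [0.1, 0.9]]), class_order=("high", "low")
        )
        cfg = lc.ScenarioConfig(
            beta_source="explicit", betas={"high": 0.0, "low": 0.0},
            override_spec=(),
            arima_orders={(c, q): (0, 1, 0) for c in ("high", "low")
                          for q in ("area", "density")},
        )
        res = lc.run_scenario(synthetic_history, matrix, 2025, cfg)
        np.testing.assert_allclose(res.betas.to_numpy(), 0.0)
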
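"""Four-state gap-junction model tests: series conductances, voltage
division, kinetics against analytic equilibria, stationary curves and the
two-sided Boltzmann fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from fmgap.gapjunction import (
    CX43,
    CX45,
    GapJunctionModel,
    GJPopulationState,
    HemichannelParams,
    StaticGapJunction,
    SteadyStateCurve,
    channel_state_conductance,
    dynamic_conductance,
    fit_modified_boltzmann,
    gate_rates,
    half_inactivation_voltage,
    hemichannel_voltages,
    population_rhs,
    steady_state_curve,
    _two_sided_boltzmann,
)


class TestStateConductances:
    def test_series_of_equal_open_hemichannels(self):
        hc = HemichannelParams(100.0, 25.0, 0.01, 0.1, 0.1, 1, 30.0)
        assert channel_state_conductance("HH", hc, hc) == pytest.approx(50.0)

    def test_mixed_series(self):
        a = HemichannelParams(100.0, 25.0, 0.01, 0.1, 0.1, 1, 30.0)
        b = HemichannelParams(100.0, 25.0, 0.01, 0.1, 0.1, 1, 30.0)
        # gA = 100 (H), gB = 25 (L) -> 20 pS
        assert channel_state_conductance("HL", a, b) == pytest.approx(20.0)

    def test_state_ordering(self):
        g = {s: channel_state_conductance(s, CX43, CX45)
             for s in ("HH", "HL", "LH", "LL")}
        assert g["HH"] > g["HL"] > g["LL"]
        assert g["HH"] > g["LH"] > g["LL"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            channel_state_conductance("XX", CX43, CX43)


class TestVoltageDivision:
    def test_symmetric_state_splits_evenly(self):
        vA, vB = hemichannel_voltages(60.0, "HH", CX43, CX43)
        assert vA == pytest.approx(30.0)
        assert vB == pytest.approx(30.0)

    def test_zero_vj(self):
        assert hemichannel_voltages(0.0, "HL", CX43, CX45) == (0.0, 0.0)

    @given(st.floats(min_value=-120, max_value=120),
           st.sampled_from(["HH", "HL", "LH", "LL"]))
    @settings(max_examples=50, deadline=None)
    def test_kirchhoff_sum(self, V_j, state):
        vA, vB = hemichannel_voltages(V_j, state, CX43, CX45)
        assert vA + vB == pytest.approx(V_j, abs=1e-12)
        # more voltage drops across the lower-conductance hemichannel
        gA = CX43.g_H if state[0] == "H" else CX43.g_L
        gB = CX45.g_H if state[1] == "H" else CX45.g_L
        if V_j > 0 and gA < gB:
            assert vA > vB


class TestGateKinetics:
    @pytest.mark.parametrize("hc", [CX43, CX45])
    def test_rates_positive_and_finite(self, hc):
        v = np.linspace(-120, 120, 241)
        r_close, r_open = gate_rates(v, hc)
        assert np.all(r_close > 0) and np.all(np.isfinite(r_close))
        assert np.all(r_open > 0) and np.all(np.isfinite(r_open))

    @pytest.mark.parametrize("hc", [CX43, CX45])
    def test_open_at_zero_voltage(self, hc):
        r_close, r_open = gate_rates(0.0, hc)
        assert r_open / (r_open + r_close) > 0.5

    def test_two_state_equilibrium_matches_integrated_kinetics(self):
        """Analytic open fraction r_open/(r_open+r_close) equals the
        long-time limit of the integrated two-state kinetics."""
        for v in (-60.0, -20.0, 15.0, 40.0):
            r_close, r_open = gate_rates(v, CX45)
            eq = r_open / (r_open + r_close)
            sol = solve_ivp(
                lambda t, y: [r_open * (1 - y[0]) - r_close * y[0]],
                (0, 50.0 / (r_open + r_close)), [0.5], method="LSODA",
                rtol=1e-10, atol=1e-12)
            assert sol.y[0, -1] == pytest.approx(eq, abs=1e-7)


class TestPopulationKinetics:
    @given(st.lists(st.floats(min_value=0.01, max_value=1.0),
                    min_size=4, max_size=4),
           st.floats(min_value=-110, max_value=110))
    @settings(max_examples=50, deadline=None)
    def test_fraction_derivatives_sum_to_zero(self, raw, V_j):
        f = np.asarray(raw) / np.sum(raw)
        pop = GJPopulationState(*f, phenotype="Cx43", N_C=10)
        df = population_rhs(pop, V_j, CX43, CX43)
        # conservation to roundoff, scaled to the derivative magnitude
        assert abs(df.sum()) < 1e-14 * max(1.0, np.abs(df).max())

    def test_stationary_distribution_is_null_vector(self):
        model = GapJunctionModel(CX43, CX45, N_C=1)
        for V_j in (-80.0, -30.0, 0.0, 30.0, 80.0):
            f = model.stationary_distribution(V_j)
            df = model.population_rhs(f, V_j)
            np.testing.assert_allclose(df, 0.0, atol=1e-12)

    def test_stationary_equals_long_time_integration(self):
        """Null-space solve agrees with integrating the master equation to
        its long-time limit for 100 voltages (oracle equivalence)."""
        rng = np.random.default_rng(7)
        model = GapJunctionModel(CX45, CX45, N_C=1)
        for V_j in rng.uniform(-100, 100, size=100):
            f_direct = model.stationary_distribution(V_j)
            Q = model.rate_matrix(float(V_j))
            # horizon set by the slowest relaxation mode of the chain
            lam = np.linalg.eigvals(Q)
            slow = np.min(np.abs(lam.real[np.abs(lam.real) > 1e-12]))
            sol = solve_ivp(lambda t, y: Q @ y, (0, 40.0 / slow),
                            [1.0, 0, 0, 0], method="LSODA",
                            rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(sol.y[:, -1], f_direct, atol=5e-6)

    def test_open_cluster_dominates_at_zero_voltage(self):
        f = GapJunctionModel(CX43, CX43).stationary_distribution(0.0)
        assert f[0] > 0.95

    def test_fraction_conservation_under_ap_shaped_clamp(self):
        """Sum of fractions stays 1 to 1e-9 while V_j(t) sweeps an
        AP-shaped waveform."""
        model = GapJunctionModel(CX43, CX45, N_C=60)

        def vj(t):  # fast negative spike, slow plateau recovery
            return -100.0 * np.exp(-t / 5.0) + 20.0 * (1 - np.exp(-t / 50.0))

        sol = solve_ivp(lambda t, y: model.population_rhs(y, vj(t)),
                        (0, 400.0), model.initial_fractions(),
                        method="LSODA", rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(sol.y.sum(axis=0) - 1.0)) < 1e-9


class TestConductance:
    def test_full_open_population(self):
        hc = HemichannelParams(100.0, 25.0, 0.01, 0.1, 0.1, 1, 30.0)
        pop = GJPopulationState(1.0, 0.0, 0.0, 0.0, N_C=60)
        assert dynamic_conductance(pop, hc, hc) == pytest.approx(3.0)

    def test_residual_floor_and_convex_bounds(self):
        model = GapJunctionModel(CX45, CX45, N_C=100)
        lo = model.conductance([0, 0, 0, 1.0])
        hi = model.conductance([1.0, 0, 0, 0])
        assert lo == pytest.approx(model.N_C * model.state_g[3] * 1e-3)
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = rng.dirichlet(np.ones(4))
            assert lo - 1e-12 <= model.conductance(f) <= hi + 1e-12

    def test_static_equals_frozen_open_dynamic(self):
        model = GapJunctionModel(CX43, CX43, N_C=60)
        static = StaticGapJunction(model.G_max)
        assert static.conductance() == model.conductance([1.0, 0, 0, 0])


class TestSteadyStateCurves:
    @pytest.mark.parametrize("pheno", ["Cx43", "Cx45"])
    def test_homotypic_symmetry(self, pheno):
        c = steady_state_curve(pheno)
        flipped = np.interp(-c.V_j, c.V_j, c.G_norm)
        assert np.max(np.abs(c.G_norm - flipped)) < 1e-3

    def test_maximal_at_zero(self):
        for pheno in ("Cx43", "Cx45"):
            c = steady_state_curve(pheno)
            assert abs(c.V_j[np.argmax(c.G_norm)]) <= 1.0

    def test_values_in_unit_interval_with_nonzero_residual(self):
        for pheno in ("Cx43", "Cx45", "Cx43/Cx45"):
            c = steady_state_curve(pheno)
            assert np.all(c.G_norm > 0.0)
            assert np.all(c.G_norm <= 1.0 + 1e-12)

    def test_cx45_more_voltage_sensitive_than_cx43(self):
        c43 = steady_state_curve("Cx43")
        c45 = steady_state_curve("Cx45")
        sel = (np.abs(c43.V_j) > 0) & (np.abs(c43.V_j) <= 80)
        assert np.all(c45.G_norm[sel] < c43.G_norm[sel] + 1e-12)

    def test_heterotypic_asymmetric_lower_at_negative(self):
        het = steady_state_curve("Cx43/Cx45")
        g = lambda v: float(np.interp(v, het.V_j, het.G_norm))
        assert g(-60.0) < g(60.0)

    def test_narrow_grid_rejected(self):
        with pytest.raises(ValueError):
            steady_state_curve("Cx43", np.linspace(-50, 50, 11))


class TestHalfInactivation:
    def test_cx45_within_measured_range(self):
        v = half_inactivation_voltage(steady_state_curve("Cx45"))
        assert 23.0 <= v <= 30.0

    def test_cx43_within_measured_range(self):
        v = half_inactivation_voltage(steady_state_curve("Cx43"))
        assert 55.0 <= v <= 60.0

    def test_synthetic_boltzmann_recovered(self):
        V = np.arange(-120.0, 120.5, 0.5)
        res = 0.3
        G = res + (1 - res) / (1 + np.exp((np.abs(V) - 40.0) / 6.0))
        curve = SteadyStateCurve(V, G / G.max())
        assert half_inactivation_voltage(curve) == pytest.approx(40.0, abs=0.5)

    def test_no_crossing_raises(self):
        V = np.arange(-120.0, 120.5, 0.5)
        curve = SteadyStateCurve(V, np.full_like(V, 0.99))
        with pytest.raises(ValueError):
            half_inactivation_voltage(curve)


class TestModifiedBoltzmannFit:
    def test_self_consistency_on_generated_data(self):
        V = np.arange(-100.0, 100.5, 0.5)
        p = (1.0, 0.35, 0.25, 45.0, -30.0, 7.0, 5.0)
        curve = SteadyStateCurve(V, _two_sided_boltzmann(V, *p))
        fit = fit_modified_boltzmann(curve)
        got = [fit[k] for k in ("G_max", "G_res_pos", "G_res_neg",
                                "V_half_pos", "V_half_neg", "k_pos", "k_neg")]
        np.testing.assert_allclose(got, p, rtol=1e-6, atol=1e-6)
        assert fit["rms_residual"] < 1e-8

    def test_homotypic_fit_symmetric(self):
        fit = fit_modified_boltzmann(steady_state_curve("Cx43"))
        assert abs(fit["V_half_pos"]) == pytest.approx(abs(fit["V_half_neg"]),
                                                       abs=1.0)

    def test_fit_agrees_with_midpoint_method(self):
        curve = steady_state_curve("Cx45")
        v_mid = half_inactivation_voltage(curve)
        fit = fit_modified_boltzmann(curve)
        assert fit["V_half_pos"] == pytest.approx(v_mid, abs=2.0)

    def test_single_polarity_curve_rejected(self):
        V = np.arange(1.0, 100.0, 0.5)
        with pytest.raises(ValueError):
            fit_modified_boltzmann(SteadyStateCurve(V, np.linspace(1, 0.4, len(V))))


class TestInvariantsOfTypes:
    def test_population_state_validation(self):
        with pytest.raises(ValueError):
            GJPopulationState(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            GJPopulationState(1.0, 0.0, 0.0, 0.0, N_C=0)

    def test_hemichannel_validation(self):
        with pytest.raises(ValueError):
            HemichannelParams(10.0, 20.0, 0.01, 0.1, 0.1, 1, 30.0)
        with pytest.raises(ValueError):
            HemichannelParams(100.0, 25.0, 0.0, 0.1, 0.1, 1, 30.0)
        with pytest.raises(ValueError):
            HemichannelParams(100.0, 25.0, 0.01, 0.1, 0.1, 2, 30.0)
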
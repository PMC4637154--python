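"""Coupled-system tests: sign conventions, charge conservation, the
decoupling limit, frozen-gate equivalence and the documented effects of
fibroblast loading on the myocyte action potential."""

import numpy as np
import pytest

from fmgap import gapjunction as gj
from fmgap.coupling import (
    CouplingConfig,
    CoupledSystem,
    gap_current,
    transjunctional_voltage,
)
from fmgap.membrane import PassiveFibroblastParams, StimulusProtocol
from fmgap.metrics import ap_metrics

ONE_BEAT = StimulusProtocol(amplitude=6000.0, duration=1.0, n_beats=1,
                            onset=10.0)


class TestElementaryRelations:
    def test_transjunctional_voltage_convention(self):
        assert transjunctional_voltage(-49.6, -49.6) == 0.0
        # resting fibroblast above resting myocyte -> positive V_j
        assert transjunctional_voltage(-49.6, -84.0) == pytest.approx(34.4)

    def test_gap_current_ohmic(self):
        assert gap_current(10.0, 3.0) == pytest.approx(30.0)
        assert gap_current(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            gap_current(10.0, -1.0)

    def test_resting_vj_of_the_two_models(self, uncoupled_trace,
                                          fibroblast_rest_30s):
        v_j = transjunctional_voltage(fibroblast_rest_30s[0],
                                      uncoupled_trace.V_myo[0])
        assert v_j == pytest.approx(34.4, abs=1.5)

    def test_vj_swings_negative_during_upstroke(self, matched_pair_traces):
        tr_d, _ = matched_pair_traces["Cx43"]
        assert tr_d.V_j.min() < -80.0
        assert tr_d.V_j[0, 0] > 0  # positive at rest


class TestChargeConservation:
    def test_junction_currents_balance_exactly(self):
        """The current the myocyte receives equals what the fibroblasts
        lose, state by state, at machine precision."""
        cfg = CouplingConfig(N=3, fibroblast="active", gj_model="Cx45",
                             G_j_max=3.0, stimulus=ONE_BEAT)
        sys = CoupledSystem(cfg)
        rng = np.random.default_rng(0)
        y = sys.initial_state()
        y[0] += 20 * rng.random()  # depolarize to create nonzero V_j
        _, _, I_gap = sys.junction_state(y)
        dy = sys.rhs(50.0, y)
        I_myo = sys.myocyte.total_current(y[: sys.n_myo])
        # myocyte: C dV/dt + I_myo - I_stim == sum I_gap
        got = sys.myocyte.C_m * dy[0] + I_myo
        assert got == pytest.approx(I_gap.sum(), rel=1e-12)
        for k in range(3):
            sl = sys._fib_slice(k)
            I_fib = sys.fibroblast.currents(y[sl])["I_fib"]
            got_f = sys.fibroblast.C_f * dy[sl][0] + I_fib
            assert got_f == pytest.approx(-I_gap[k], rel=1e-12)


class TestDecouplingLimit:
    def test_n0_identical_to_uncoupled_myocyte(self):
        """With N = 0 the coupled system is bitwise the bare myocyte on a
        fixed-step integration."""
        cfg = CouplingConfig(N=0, gj_model="static", G_j_max=1.0,
                             stimulus=ONE_BEAT)
        sys0 = CoupledSystem(cfg)
        tr = sys0.simulate(80.0, 0.5, method="fixed", dt=0.02)
        # reference: same stepper on the raw myocyte equations
        myo = sys0.myocyte
        y = myo.initial_state()
        t = 0.0
        for i in range(int(80.0 / 0.02)):
            y = sys0._fixed_step(t, y, 0.02, myo, 0)
            t += 0.02
        ref_cfg = CouplingConfig(N=0, gj_model="static", G_j_max=1.0,
                                 stimulus=ONE_BEAT)
        tr2 = CoupledSystem(ref_cfg).simulate(80.0, 0.5, method="fixed",
                                              dt=0.02)
        np.testing.assert_array_equal(tr.V_myo, tr2.V_myo)
        assert tr.V_myo[-1] == y[0]


class TestFrozenGateEquivalence:
    @pytest.mark.parametrize("pheno", ["Cx43", "Cx45", "Cx43/Cx45"])
    def test_frozen_open_dynamic_equals_static(self, pheno):
        """Dynamic model with (numerically) frozen gates and all channels
        open reproduces the static trace to machine precision."""
        cfg = CouplingConfig(N=1, fibroblast="active", gj_model=pheno,
                             G_j_max=3.0, stimulus=ONE_BEAT)
        sys_d = CoupledSystem(cfg)
        sys_d.gj.hcA = gj.rescaled(sys_d.gj.hcA, lam=1e-300)
        sys_d.gj.hcB = gj.rescaled(sys_d.gj.hcB, lam=1e-300)
        tr_d = sys_d.simulate(120.0, 0.5, method="fixed", dt=0.02)
        tr_s = CoupledSystem(cfg.static_counterpart()).simulate(
            120.0, 0.5, method="fixed", dt=0.02)
        np.testing.assert_allclose(tr_d.V_myo, tr_s.V_myo, rtol=0, atol=1e-9)
        np.testing.assert_allclose(tr_d.G_j, tr_s.G_j, rtol=1e-12)


class TestCouplingEffectsOnAP:
    def test_static_coupling_reshapes_the_ap(self, uncoupled_trace,
                                             coupled_static_trace):
        """Coupling hyperpolarizes the plateau, shortens APD and
        depolarizes the resting potential."""
        m_un = ap_metrics(uncoupled_trace)
        m_cp = ap_metrics(coupled_static_trace)
        assert m_cp.APD90 < m_un.APD90
        assert m_cp.plateau_potential < m_un.plateau_potential
        assert m_cp.resting_potential > m_un.resting_potential

    def test_apd_shortens_monotonically_with_fibroblast_count(self):
        """At fixed conductance, more fibroblasts load the myocyte harder:
        APD90 falls monotonically with N."""
        apds = []
        for N in (0, 2, 4, 8):
            cfg = CouplingConfig(N=N, fibroblast="active", gj_model="static",
                                 phenotype_for_static="Cx43", G_j_max=3.0,
                                 stimulus=ONE_BEAT)
            tr = CoupledSystem(cfg).simulate(450.0, 0.2)
            apds.append(ap_metrics(tr).APD90)
        assert all(a > b for a, b in zip(apds, apds[1:]))

    def test_hyperpolarized_passive_fibroblast_leaves_rest_untouched(
            self, uncoupled_trace):
        """A passive fibroblast with E_f = -80 mV does not move the coupled
        resting potential by more than 1 mV."""
        cfg = CouplingConfig(
            N=2, fibroblast="passive", gj_model="static",
            phenotype_for_static="Cx43", G_j_max=3.0,
            passive_params=PassiveFibroblastParams(C_f=6.3, G_f=1.0,
                                                   E_f=-80.0),
            stimulus=ONE_BEAT)
        tr = CoupledSystem(cfg).simulate(450.0, 0.2)
        d_rest = abs(ap_metrics(tr).resting_potential
                     - ap_metrics(uncoupled_trace).resting_potential)
        assert d_rest < 1.0


class TestSimulateContract:
    def test_output_sampling_independence(self):
        """Doubling output_dt leaves shared samples unchanged (sampling does
        not influence the integration)."""
        cfg = CouplingConfig(N=1, fibroblast="active", gj_model="Cx45",
                             G_j_max=3.0, stimulus=ONE_BEAT)
        tr1 = CoupledSystem(cfg).simulate(100.0, 0.2)
        tr2 = CoupledSystem(cfg).simulate(100.0, 0.4)
        shared = np.isin(np.round(tr1.t, 9), np.round(tr2.t, 9))
        np.testing.assert_allclose(tr1.V_myo[shared], tr2.V_myo,
                                   rtol=0, atol=1e-9)

    def test_t_end_must_cover_protocol(self):
        cfg = CouplingConfig(N=0, gj_model="static", G_j_max=1.0,
                             stimulus=StimulusProtocol(n_beats=3))
        with pytest.raises(ValueError):
            CoupledSystem(cfg).simulate(1500.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CouplingConfig(N=-1)
        with pytest.raises(ValueError):
            CouplingConfig(N=1, G_j_max=0.0)
        with pytest.raises(ValueError):
            CouplingConfig(gj_model="Cx40")
        assert CouplingConfig(N=2).classification == "normal"
        assert CouplingConfig(N=3).classification == "diseased"

    def test_nc_quantization(self):
        cfg = CouplingConfig(N=1, gj_model="Cx43", G_j_max=3.0)
        assert cfg.N_C() == 60  # g_HH = 50 pS
        assert cfg.realized_G_max() == pytest.approx(3.0)
        assert cfg.static_counterpart().N_C() == 60

    def test_state_labels_match_vector(self):
        cfg = CouplingConfig(N=2, fibroblast="active", gj_model="Cx45",
                             G_j_max=3.0, stimulus=ONE_BEAT)
        sys = CoupledSystem(cfg)
        assert len(sys.state_labels()) == sys.n_states == len(sys.initial_state())
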
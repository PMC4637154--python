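"""Shared fixtures: a handful of session-scoped simulation runs reused by
several tests, so each expensive integration happens once."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fmgap.coupling import CouplingConfig, CoupledSystem
from fmgap.membrane import ActiveFibroblast, LR1Myocyte, StimulusProtocol

ONE_BEAT = StimulusProtocol(amplitude=6000.0, duration=1.0,
                            cycle_length=1000.0, n_beats=1, onset=10.0)


@pytest.fixture(scope="session")
def lr1():
    return LR1Myocyte()


@pytest.fixture(scope="session")
def myocyte_rest(lr1):
    """Quiescent LR1 state after a 2 s unstimulated settle."""
    sol = solve_ivp(lambda t, y: lr1.rhs(y), (0, 2000), lr1.initial_state(),
                    method="LSODA", rtol=1e-8, atol=1e-10)
    return sol.y[:, -1]


@pytest.fixture(scope="session")
def fibroblast_rest_30s():
    """Final state of a 30 s unstimulated MacCannell fibroblast run."""
    fib = ActiveFibroblast()
    sol = solve_ivp(lambda t, y: fib.rhs(y), (0, 30_000), fib.initial_state(),
                    method="LSODA", rtol=1e-8,
                    atol=[1e-8, 1e-10, 1e-10, 1e-8, 1e-8])
    assert sol.success
    return sol.y[:, -1]


@pytest.fixture(scope="session")
def uncoupled_trace():
    cfg = CouplingConfig(N=0, gj_model="static", G_j_max=1.0, stimulus=ONE_BEAT)
    return CoupledSystem(cfg).simulate(450.0, output_dt=0.1)


@pytest.fixture(scope="session")
def coupled_static_trace():
    """Static coupling, two active fibroblasts at 3 nS, one beat."""
    cfg = CouplingConfig(N=2, fibroblast="active", gj_model="static",
                         phenotype_for_static="Cx43", G_j_max=3.0,
                         stimulus=ONE_BEAT)
    return CoupledSystem(cfg).simulate(450.0, output_dt=0.1)


@pytest.fixture(scope="session")
def matched_pair_traces():
    """(dynamic, static) traces per phenotype at N=2, 3 nS (first beat)."""
    from fmgap.metrics import run_matched_pair

    out = {}
    for pheno in ("Cx43", "Cx45", "Cx43/Cx45"):
        cfg = CouplingConfig(N=2, fibroblast="active", gj_model=pheno,
                             G_j_max=3.0, stimulus=ONE_BEAT)
        out[pheno] = run_matched_pair(cfg, t_end=350.0)
    return out
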
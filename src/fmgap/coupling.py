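"""Coupled myocyte + N fibroblasts + gap-junction integration.

One ventricular myocyte is coupled to N identical fibroblasts in a star
topology, each through its own gap junction.  With V_j = V_fib - V_myo and
an ohmic junction current I_gap = G_j * V_j (positive = depolarizing current
into the myocyte), the system is

    C_myo dV_myo/dt = -I_myo + sum_k I_gap,k + I_stim
    C_fib dV_fib/dt = -I_fib - I_gap            (per fibroblast)

plus the ionic state of each cell and, for dynamic junctions, the four-state
occupancy fractions of each channel population.  In the static model G_j is
a constant equal to the maximum (all channels in HH) conductance of the
matched dynamic model.

The full system is one flat state vector
``[myocyte | fibroblast_1..N | fractions_1..N]`` advanced by a single
integrator call: adaptive LSODA by default, or a fixed-step scheme with
Rush-Larsen gate updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .gapjunction import PHENOTYPES, GapJunctionModel, StaticGapJunction
from .membrane import (
    ActiveFibroblast,
    LR1Myocyte,
    PassiveFibroblast,
    PassiveFibroblastParams,
    StimulusProtocol,
)

__all__ = [
    "CouplingConfig",
    "CoupledSystem",
    "Trace",
    "transjunctional_voltage",
    "gap_current",
    "simulate",
]

GJ_CHOICES = ("static", "Cx43", "Cx45", "Cx43/Cx45")


def transjunctional_voltage(V_fib, V_myo):
    """V_j = V_fib - V_myo (fibroblast minus myocyte).

    During the AP upstroke the myocyte depolarizes ahead of the fibroblast,
    so V_j swings strongly negative.
    """
    return V_fib - V_myo


def gap_current(V_j, G_j):
    """Ohmic junction current I_gap = G_j * V_j (pA).

    Positive I_gap depolarizes the myocyte; the same current leaves the
    fibroblast, so the junction conserves charge exactly.
    """
    G_j = np.asarray(G_j, dtype=float)
    if np.any(G_j < 0):
        raise ValueError("G_j must be non-negative")
    return G_j * V_j


@dataclass(frozen=True)
class CouplingConfig:
    """Configuration of one myocyte-fibroblast coupling unit.

    N          : fibroblasts per myocyte (0 = uncoupled); ratios <= 2 are the
                 normal range, > 2 diseased fibrosis.
    fibroblast : "passive" or "active" (MacCannell).
    gj_model   : "static" or a dynamic phenotype ("Cx43", "Cx45", "Cx43/Cx45").
    G_j_max    : target maximal conductance per F-M connection, nS.  The
                 channel count is N_C = round(G_j_max / g_HH) (>= 1), so the
                 realized maximum is N_C * g_HH — identical between a dynamic
                 run and its static counterpart.
    phenotype_for_static : phenotype whose g_HH quantizes N_C when
                 gj_model == "static" (set by `static_counterpart`).
    contingent : contingent (True) vs independent gate-voltage division.
    passive_params : parameters of the passive fibroblast.
    """

    N: int = 1
    fibroblast: str = "active"
    gj_model: str = "Cx43"
    G_j_max: float = 3.0
    phenotype_for_static: str = "Cx43"
    contingent: bool = True
    passive_params: PassiveFibroblastParams = field(
        default_factory=PassiveFibroblastParams
    )
    stimulus: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.N > 0 and not self.G_j_max > 0:
            raise ValueError("G_j_max must be positive when N > 0")
        if self.gj_model not in GJ_CHOICES:
            raise ValueError(f"gj_model must be one of {GJ_CHOICES}")
        if self.fibroblast not in ("passive", "active"):
            raise ValueError("fibroblast must be 'passive' or 'active'")

    @property
    def is_dynamic(self) -> bool:
        return self.gj_model != "static"

    @property
    def phenotype(self) -> str:
        return self.gj_model if self.is_dynamic else self.phenotype_for_static

    @property
    def classification(self) -> str:
        return "normal" if self.N <= 2 else "diseased"

    def N_C(self) -> int:
        g_HH = GapJunctionModel.from_phenotype(self.phenotype).g_HH  # pS
        return max(1, round(self.G_j_max / (g_HH * 1e-3)))

    def realized_G_max(self) -> float:
        """Maximal junction conductance after channel-count quantization, nS."""
        g_HH = GapJunctionModel.from_phenotype(self.phenotype).g_HH
        return self.N_C() * g_HH * 1e-3

    def static_counterpart(self) -> "CouplingConfig":
        """Same configuration with the GJ replaced by its static maximum."""
        return replace(self, gj_model="static",
                       phenotype_for_static=self.phenotype)


@dataclass
class Trace:
    """Uniformly sampled time series of one coupled run.

    Per-fibroblast series (V_fib, V_j, I_gap, G_j) have shape (N, n_t); the
    stimulus marker is 1.0 while the pulse is on.
    """

    t: np.ndarray
    V_myo: np.ndarray
    V_fib: np.ndarray
    V_j: np.ndarray
    I_gap: np.ndarray
    G_j: np.ndarray
    stim: np.ndarray
    config: CouplingConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("V_myo", "stim"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time grid")
        for name in ("V_fib", "V_j", "I_gap", "G_j"):
            a = getattr(self, name)
            if a.shape[-1] != n:
                raise ValueError(f"{name} length does not match time grid")

    @property
    def N(self) -> int:
        return self.V_fib.shape[0]

    def total_I_gap(self) -> np.ndarray:
        """Summed junction current into the myocyte (pA)."""
        return self.I_gap.sum(axis=0) if self.N else np.zeros_like(self.t)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "V_myo": self.V_myo}
        for k in range(self.N):
            sfx = f"_{k + 1}" if self.N > 1 else ""
            cols[f"V_fib{sfx}"] = self.V_fib[k]
            cols[f"V_j{sfx}"] = self.V_j[k]
            cols[f"I_gap{sfx}"] = self.I_gap[k]
            cols[f"G_j{sfx}"] = self.G_j[k]
        cols["stim"] = self.stim
        return pd.DataFrame(cols)


class CoupledSystem:
    """The integrable unit: myocyte, N fibroblasts, N junctions, stimulus."""

    def __init__(self, config: CouplingConfig,
                 myocyte: LR1Myocyte | None = None):
        self.config = config
        self.myocyte = myocyte or LR1Myocyte()
        if config.fibroblast == "active":
            self.fibroblast = ActiveFibroblast()
        else:
            self.fibroblast = PassiveFibroblast(config.passive_params)
        self.stimulus = config.stimulus

        N_C = config.N_C() if config.N > 0 else 1
        if config.is_dynamic:
            hcA, hcB = PHENOTYPES[config.gj_model]
            # side A faces the myocyte, side B the fibroblast; V_j = V_fib - V_myo
            self.gj = GapJunctionModel(hcA, hcB, N_C=N_C,
                                       contingent=config.contingent)
        else:
            g_HH = GapJunctionModel.from_phenotype(config.phenotype).g_HH
            self.gj = StaticGapJunction(N_C * g_HH * 1e-3)

        self.n_myo = self.myocyte.n_states
        self.n_fib = self.fibroblast.n_states
        self.n_frac = 4 if config.is_dynamic else 0
        self.n_states = (self.n_myo + config.N * self.n_fib
                         + config.N * self.n_frac)

    # ---- state vector layout ----
    def _fib_slice(self, k: int) -> slice:
        a = self.n_myo + k * self.n_fib
        return slice(a, a + self.n_fib)

    def _frac_slice(self, k: int) -> slice:
        a = self.n_myo + self.config.N * self.n_fib + k * self.n_frac
        return slice(a, a + self.n_frac)

    def initial_state(self) -> np.ndarray:
        parts = [self.myocyte.initial_state()]
        parts += [self.fibroblast.initial_state()] * self.config.N
        if self.config.is_dynamic:
            parts += [self.gj.initial_fractions()] * self.config.N
        return np.concatenate(parts) if parts else np.array([])

    def state_labels(self) -> list[str]:
        """Column labels of the flat state vector (for text snapshots)."""
        labels = [f"myo.{n}" for n in self.myocyte.state_names]
        for k in range(self.config.N):
            labels += [f"fib{k + 1}.{n}" for n in self.fibroblast.state_names]
        if self.config.is_dynamic:
            for k in range(self.config.N):
                labels += [f"gj{k + 1}.f_{s}" for s in
                           ("HH", "HL", "LH", "LL")]
        return labels

    def junction_state(self, y: np.ndarray):
        """(V_j, G_j, I_gap) arrays of length N for a state vector."""
        N = self.config.N
        V_myo = y[0]
        V_j = np.empty(N)
        G_j = np.empty(N)
        for k in range(N):
            V_fib = y[self._fib_slice(k)][0]
            V_j[k] = transjunctional_voltage(V_fib, V_myo)
            if self.config.is_dynamic:
                G_j[k] = self.gj.conductance(y[self._frac_slice(k)])
            else:
                G_j[k] = self.gj.G_j
        return V_j, G_j, gap_current(V_j, G_j)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        N = self.config.N
        V_j, G_j, I_gap = self.junction_state(y) if N else (0, 0, np.zeros(0))
        I_stim = self.stimulus.current(t)
        dy[: self.n_myo] = self.myocyte.rhs(
            y[: self.n_myo], I_inj=I_gap.sum() + I_stim
        )
        for k in range(N):
            sl = self._fib_slice(k)
            dy[sl] = self.fibroblast.rhs(y[sl], I_inj=-I_gap[k])
            if self.config.is_dynamic:
                fl = self._frac_slice(k)
                dy[fl] = self.gj.population_rhs(y[fl], V_j[k])
        if not np.all(np.isfinite(dy)):
            raise FloatingPointError(
                f"non-finite derivative at t={t:.3f} ms; state={y!r}"
            )
        return dy

    def _atol(self) -> np.ndarray:
        atol = np.empty(self.n_states)
        atol[: self.n_myo] = 1e-8
        atol[0] = 1e-6
        atol[self.n_myo - 1] = 1e-10  # Ca_i
        for k in range(self.config.N):
            atol[self._fib_slice(k)] = 1e-8
            atol[self._fib_slice(k).start] = 1e-6
            if self.config.is_dynamic:
                atol[self._frac_slice(k)] = 1e-9
        return atol

    # ---- integration ----
    def simulate(self, t_end: float, output_dt: float = 0.1,
                 y0: np.ndarray | None = None, method: str = "lsoda",
                 rtol: float = 1e-6, dt: float = 0.01) -> Trace:
        """Integrate to ``t_end`` and sample on a uniform grid.

        method="lsoda" integrates piecewise between stimulus edges with an
        adaptive stiff solver; method="fixed" uses a fixed step ``dt`` with
        Rush-Larsen gate updates (deterministic step sequence, useful for
        exact model-equivalence comparisons).
        """
        if self.stimulus.n_beats > 0:
            last_on = self.stimulus.onset + (
                self.stimulus.n_beats - 1) * self.stimulus.cycle_length
            if t_end < last_on:
                raise ValueError("t_end does not cover the stimulus protocol")
        y0 = self.initial_state() if y0 is None else np.asarray(y0, dtype=float)
        t_grid = np.round(np.arange(0.0, t_end + output_dt / 2, output_dt), 9)
        if method == "fixed":
            Y = self._integrate_fixed(t_grid, y0, dt)
        elif method == "lsoda":
            Y = self._integrate_adaptive(t_grid, y0, t_end, rtol)
        else:
            raise ValueError(f"unknown method {method!r}")
        return self._trace_from_samples(t_grid, Y)

    def _integrate_adaptive(self, t_grid, y0, t_end, rtol) -> np.ndarray:
        edges = np.concatenate(
            [[0.0], self.stimulus.switch_times(t_end), [t_end]]
        )
        edges = np.unique(np.clip(edges, 0.0, t_end))
        Y = np.empty((len(t_grid), len(y0)))
        Y[0] = y0
        atol = self._atol()
        y = y0
        for a, b in zip(edges[:-1], edges[1:]):
            sel = (t_grid > a + 1e-12) & (t_grid <= b + 1e-12)
            t_eval = np.unique(np.concatenate([t_grid[sel], [b]]))
            sol = solve_ivp(self.rhs, (a, b), y, method="LSODA",
                            t_eval=t_eval, rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(
                    f"solver failed in [{a}, {b}] ms: {sol.message}"
                )
            idx = np.searchsorted(sol.t, t_grid[sel])
            Y[sel] = sol.y[:, idx].T
            y = sol.y[:, -1]
        return Y

    def _integrate_fixed(self, t_grid, y0, dt) -> np.ndarray:
        stride = max(1, int(round(t_grid[1] / dt))) if len(t_grid) > 1 else 1
        dt = t_grid[1] / stride if len(t_grid) > 1 else dt
        myo = self.myocyte
        N = self.config.N
        Y = np.empty((len(t_grid), len(y0)))
        Y[0] = y0
        y = y0.copy()
        t = 0.0
        for i in range(1, len(t_grid)):
            for _ in range(stride):
                y = self._fixed_step(t, y, dt, myo, N)
                t += dt
            Y[i] = y
        return Y

    def _fixed_step(self, t, y, dt, myo, N):
        out = y.copy()
        V_j, G_j, I_gap = self.junction_state(y) if N else (0, 0, np.zeros(0))
        I_stim = self.stimulus.current(t)
        # myocyte: forward Euler on V and Ca, Rush-Larsen on the gates
        V = y[0]
        cur = myo.current_densities(y[: self.n_myo])
        out[0] = V + dt * (-cur["I_ion"] + (I_gap.sum() + I_stim) / myo.C_m)
        for i, (a, b) in enumerate(myo.all_rates(V), start=1):
            tau = 1.0 / (a + b)
            ginf = a * tau
            out[i] = ginf + (y[i] - ginf) * np.exp(-dt / tau)
        out[7] = y[7] + dt * (-1e-4 * cur["I_si"] + 0.07 * (1e-4 - y[7]))
        for k in range(N):
            sl = self._fib_slice(k)
            if isinstance(self.fibroblast, ActiveFibroblast):
                fib = self.fibroblast
                yf = y[sl]
                dyf = fib.rhs(yf, I_inj=-I_gap[k])
                out[sl] = yf + dt * dyf
                # Rush-Larsen for the two delayed-rectifier gates
                Vf = yf[0]
                for j, (inf, tau) in enumerate(
                    ((fib.r_inf(Vf), fib.tau_r(Vf)),
                     (fib.s_inf(Vf), fib.tau_s(Vf))), start=1):
                    out[sl.start + j] = inf + (yf[j] - inf) * np.exp(-dt / tau)
            else:
                out[sl] = y[sl] + dt * self.fibroblast.rhs(y[sl], I_inj=-I_gap[k])
            if self.config.is_dynamic:
                fl = self._frac_slice(k)
                out[fl] = y[fl] + dt * self.gj.population_rhs(y[fl], V_j[k])
        return out

    def _trace_from_samples(self, t_grid, Y) -> Trace:
        N = self.config.N
        V_j = np.empty((N, len(t_grid)))
        G_j = np.empty((N, len(t_grid)))
        I_g = np.empty((N, len(t_grid)))
        V_f = np.empty((N, len(t_grid)))
        for i, y in enumerate(Y):
            if N:
                vj, gj_, ig = self.junction_state(y)
                V_j[:, i], G_j[:, i], I_g[:, i] = vj, gj_, ig
                for k in range(N):
                    V_f[k, i] = y[self._fib_slice(k)][0]
        stim = np.array([1.0 if self.stimulus.current(t) != 0.0 else 0.0
                         for t in t_grid])
        return Trace(t=t_grid, V_myo=Y[:, 0], V_fib=V_f, V_j=V_j,
                     I_gap=I_g, G_j=G_j, stim=stim, config=self.config)


def simulate(config: CouplingConfig, t_end: float, output_dt: float = 0.1,
             **kwargs) -> Trace:
    """Build a :class:`CoupledSystem` from ``config`` and integrate it."""
    return CoupledSystem(config).simulate(t_end, output_dt, **kwargs)
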
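"""Single-cell membrane models.

Three cell models are provided:

* :class:`LR1Myocyte` — the Luo–Rudy 1991 guinea-pig ventricular action
  potential model (fast Na current, slow inward Ca current, time-dependent
  and time-independent K currents, plateau K and background currents).
* :class:`PassiveFibroblast` — an RC membrane: capacitance in parallel with
  an ohmic leak to a fixed reversal potential.
* :class:`ActiveFibroblast` — the MacCannell ventricular fibroblast with an
  inward-rectifier K current, a delayed-rectifier K current, an Na/K pump
  and a background Na current, plus bulk intracellular Na and K.

Units everywhere: mV, ms, pA, pF, nS, mM.  Currents at module boundaries are
cell-total pA (density formulations are scaled by the cell capacitance, with
the usual 1 µF/cm² identity making pA/pF equal to µA/µF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MyocyteState",
    "PassiveFibroblastParams",
    "PassiveFibroblast",
    "ActiveFibroblastState",
    "ActiveFibroblast",
    "LR1Myocyte",
    "StimulusProtocol",
    "passive_fibroblast_rhs",
    "maccannell_currents",
    "myocyte_rhs",
]

FARADAY = 96485.0  # C/mol
RTF = 26.71  # mV at 37 °C

LR1_GATE_NAMES = ("m", "h", "j", "d", "f", "x")


# --------------------------------------------------------------------------
# stimulus protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic square-pulse current injection.

    amplitude : pA (positive depolarizes the myocyte)
    duration  : ms, pulse width; must be shorter than the cycle length
    cycle_length : ms, basic cycle length (1 Hz pacing = 1000 ms)
    n_beats   : number of pulses delivered (0 = unstimulated)
    onset     : ms, time of the first pulse
    """

    amplitude: float = 6000.0
    duration: float = 1.0
    cycle_length: float = 1000.0
    n_beats: int = 1
    onset: float = 10.0

    def __post_init__(self) -> None:
        if self.n_beats < 0:
            raise ValueError("n_beats must be >= 0")
        if self.n_beats > 0 and not self.duration < self.cycle_length:
            raise ValueError("stimulus duration must be < cycle length")

    def current(self, t: float) -> float:
        """Injected current (pA) at time t."""
        if self.n_beats == 0:
            return 0.0
        k = np.floor((t - self.onset) / self.cycle_length)
        k = min(max(k, 0), self.n_beats - 1)
        t0 = self.onset + k * self.cycle_length
        return self.amplitude if (t0 <= t < t0 + self.duration) else 0.0

    def switch_times(self, t_end: float) -> np.ndarray:
        """Times where the stimulus turns on or off, within [0, t_end]."""
        times = []
        for k in range(self.n_beats):
            on = self.onset + k * self.cycle_length
            if on > t_end:
                break
            times.append(on)
            if on + self.duration <= t_end:
                times.append(on + self.duration)
        return np.asarray(times)

    def stim_onsets(self, t_end: float) -> np.ndarray:
        return np.asarray(
            [self.onset + k * self.cycle_length
             for k in range(self.n_beats)
             if self.onset + k * self.cycle_length <= t_end]
        )


# --------------------------------------------------------------------------
# passive fibroblast
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveFibroblastParams:
    """RC fibroblast: C_f dV/dt = -G_f (V - E_f) + I_inj.

    C_f : membrane capacitance, pF (> 0)
    G_f : membrane conductance, nS (>= 0)
    E_f : reversal (resting) potential, mV
    """

    C_f: float = 6.3
    G_f: float = 1.0
    E_f: float = -25.0

    def __post_init__(self) -> None:
        if not self.C_f > 0:
            raise ValueError("C_f must be positive")
        if self.G_f < 0:
            raise ValueError("G_f must be non-negative")


def passive_fibroblast_rhs(V_f, params: PassiveFibroblastParams, I_inj=0.0):
    """dV_f/dt (mV/ms) of the passive RC fibroblast.

    nS·mV = pA and pA/pF = mV/ms, so the expression is dimensionally closed.
    """
    return (-params.G_f * (V_f - params.E_f) + I_inj) / params.C_f


class PassiveFibroblast:
    """Passive fibroblast wrapped in the common cell-model interface."""

    n_states = 1
    state_names = ("V_f",)

    def __init__(self, params: PassiveFibroblastParams | None = None):
        self.params = params or PassiveFibroblastParams()

    @property
    def capacitance(self) -> float:
        return self.params.C_f

    def initial_state(self) -> np.ndarray:
        return np.array([self.params.E_f], dtype=float)

    def rhs(self, y: np.ndarray, I_inj: float = 0.0) -> np.ndarray:
        dv = passive_fibroblast_rhs(y[..., 0], self.params, I_inj)
        return np.asarray(dv, dtype=float)[..., None]

    def relaxation(self, V0: float, t) -> np.ndarray:
        """Closed-form free relaxation V(t) = E + (V0-E) exp(-G t / C)."""
        p = self.params
        return p.E_f + (V0 - p.E_f) * np.exp(-p.G_f * np.asarray(t) / p.C_f)


# --------------------------------------------------------------------------
# MacCannell active fibroblast
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ActiveFibroblastState:
    V_f: float
    r: float
    s: float
    K_i: float
    Na_i: float

    def __post_init__(self) -> None:
        for g in (self.r, self.s):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gates must lie in [0,1]")
        if self.K_i <= 0 or self.Na_i <= 0:
            raise ValueError("intracellular concentrations must be positive")

    def to_vector(self) -> np.ndarray:
        return np.array([self.V_f, self.r, self.s, self.K_i, self.Na_i])

    @classmethod
    def from_vector(cls, y) -> "ActiveFibroblastState":
        return cls(*(float(v) for v in y))


class ActiveFibroblast:
    """MacCannell adult ventricular fibroblast.

    Four membrane currents: inward-rectifying K (time independent, using the
    ten Tusscher rectification function), delayed-rectifier K gated by an
    activation gate r and inactivation gate s, an electrogenic Na/K pump and
    a linear background Na conductance.  The pump and background current give
    the model Na and K homeostasis; the uncoupled cell rests near −49.6 mV.

    Conductances/currents are formulated per pF and scaled by C_f = 6.3 pF.
    """

    n_states = 5
    state_names = ("V_f", "r", "s", "K_i", "Na_i")

    C_f = 6.3          # pF
    volume = 1137.7e-15  # L, cytosolic volume (~1138 µm³)
    K_o = 5.4          # mM
    Na_o = 130.0       # mM

    G_K1 = 0.4822      # nS/pF
    G_Kv = 0.25        # nS/pF
    # background Na conductance; tuned so the uncoupled rest sits at -49.6 mV
    G_bNa = 0.008821   # nS/pF
    I_NaK_max = 2.002  # pA/pF
    K_mK = 1.0         # mM
    K_mNa = 11.0       # mM
    V_rev = -150.0     # mV

    def __init__(self, g_bna_scale: float = 1.0):
        self.g_bna_scale = g_bna_scale

    @property
    def capacitance(self) -> float:
        return self.C_f

    def initial_state(self) -> np.ndarray:
        V = -49.6
        return np.array(
            [V, self.r_inf(V), self.s_inf(V), 129.4, 8.5]
        )

    # gate kinetics (delayed rectifier)
    @staticmethod
    def r_inf(V):
        return 1.0 / (1.0 + np.exp(-(V + 20.0) / 11.0))

    @staticmethod
    def tau_r(V):
        return 20.3 + 138.0 * np.exp(-(((V + 20.0) / 25.9) ** 2))

    @staticmethod
    def s_inf(V):
        return 1.0 / (1.0 + np.exp((V + 23.0) / 7.0))

    @staticmethod
    def tau_s(V):
        return 1574.0 + 5268.0 * np.exp(-(((V + 23.0) / 22.7) ** 2))

    def E_K(self, K_i):
        return RTF * np.log(self.K_o / K_i)

    def E_Na(self, Na_i):
        return RTF * np.log(self.Na_o / Na_i)

    def currents(self, y) -> dict:
        """Per-current values (cell-total pA) and their sum ``I_fib``."""
        V, r, s, K_i, Na_i = (y[..., i] for i in range(5))
        E_K = self.E_K(K_i)
        dv = V - E_K
        # inward rectifier (ten Tusscher rectification profile)
        a = 0.1 / (1.0 + np.exp(0.06 * (dv - 200.0)))
        b = (3.0 * np.exp(0.0002 * (dv + 100.0)) + np.exp(0.1 * (dv - 10.0))) / (
            1.0 + np.exp(-0.5 * dv)
        )
        I_K1 = self.G_K1 * (a / (a + b)) * dv
        I_Kv = self.G_Kv * r * s * dv
        I_NaK = (
            self.I_NaK_max
            * (self.K_o / (self.K_o + self.K_mK))
            * (Na_i**1.5 / (Na_i**1.5 + self.K_mNa**1.5))
            * (V - self.V_rev)
            / (V + 200.0)
        )
        I_bNa = self.g_bna_scale * self.G_bNa * (V - self.E_Na(Na_i))
        out = {
            "I_K1": I_K1 * self.C_f,
            "I_Kv": I_Kv * self.C_f,
            "I_NaK": I_NaK * self.C_f,
            "I_bNa": I_bNa * self.C_f,
        }
        out["I_fib"] = out["I_K1"] + out["I_Kv"] + out["I_NaK"] + out["I_bNa"]
        return out

    def rhs(self, y, I_inj: float = 0.0) -> np.ndarray:
        V, r, s, K_i, Na_i = (y[..., i] for i in range(5))
        cur = self.currents(y)
        dV = (-cur["I_fib"] + I_inj) / self.C_f
        dr = (self.r_inf(V) - r) / self.tau_r(V)
        ds = (self.s_inf(V) - s) / self.tau_s(V)
        # pA -> mM/ms: 1 pA = 1e-15 C/ms; /F -> mol/ms; /vol(L) -> M/ms; ×1e3 -> mM/ms
        scale = 1e-12 / (self.volume * FARADAY)
        dK = -(cur["I_K1"] + cur["I_Kv"] - 2.0 * cur["I_NaK"]) * scale
        dNa = -(cur["I_bNa"] + 3.0 * cur["I_NaK"]) * scale
        return np.stack(
            [np.asarray(x, dtype=float) for x in (dV, dr, ds, dK, dNa)], axis=-1
        )


def maccannell_currents(state: ActiveFibroblastState, model: ActiveFibroblast | None = None) -> dict:
    """The four MacCannell membrane currents and their sum (cell-total pA)."""
    model = model or ActiveFibroblast()
    return model.currents(state.to_vector())


# --------------------------------------------------------------------------
# Luo-Rudy 1991 ventricular myocyte
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MyocyteState:
    """LR1 state: voltage, six Hodgkin-Huxley gates and intracellular Ca."""

    V_m: float
    gates: tuple = field(default=None)  # (m, h, j, d, f, x)
    Ca_i: float = 2e-4

    def __post_init__(self) -> None:
        if self.gates is None or len(self.gates) != 6:
            raise ValueError("gates must be the 6-tuple (m, h, j, d, f, x)")
        if any(not (0.0 <= g <= 1.0) for g in self.gates):
            raise ValueError("gates must lie in [0,1]")
        if not self.Ca_i > 0:
            raise ValueError("Ca_i must be positive")
        if not np.isfinite(self.V_m):
            raise ValueError("V_m must be finite")

    def to_vector(self) -> np.ndarray:
        return np.array([self.V_m, *self.gates, self.Ca_i])

    @classmethod
    def from_vector(cls, y) -> "MyocyteState":
        return cls(float(y[0]), tuple(float(g) for g in y[1:7]), float(y[7]))


def _safe_ratio(num, den, limit):
    """num/den with the removable singularity at den=0 replaced by `limit`."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-9
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


class LR1Myocyte:
    """Luo–Rudy 1991 guinea-pig ventricular action potential model.

    Six ionic currents: fast Na (m³hj), slow inward Ca (df) with a
    Ca-dependent reversal, time-dependent K (x with inward rectification
    factor xi), time-independent K1, plateau K, and a linear background
    current.  Intracellular Ca follows the original single-pool update.

    Current densities are µA/µF (≡ pA/pF); cell-total currents scale by the
    cell capacitance (default 153.4 pF, the standard 100 µm × 11 µm cell).
    All rate functions accept numpy arrays so cable models can evaluate a
    whole strand at once.
    """

    n_states = 8
    state_names = ("V_m", "m", "h", "j", "d", "f", "x", "Ca_i")

    C_m = 153.4  # pF
    K_o, K_i = 5.4, 145.0
    Na_o, Na_i = 140.0, 18.0
    G_Na = 23.0      # mS/cm² == nS/pF
    G_si = 0.09
    E_Na = 54.4

    def __init__(self, C_m: float | None = None, G_si: float | None = None,
                 G_K1_scale: float = 1.0):
        if C_m is not None:
            self.C_m = float(C_m)
        if G_si is not None:
            self.G_si = float(G_si)
        PR_NaK = 0.01833
        self.E_K = RTF * np.log(
            (self.K_o + PR_NaK * self.Na_o) / (self.K_i + PR_NaK * self.Na_i)
        )
        self.E_K1 = RTF * np.log(self.K_o / self.K_i)
        self.G_K = 0.282 * np.sqrt(self.K_o / 5.4)
        self.G_K1 = G_K1_scale * 0.6047 * np.sqrt(self.K_o / 5.4)

    @property
    def capacitance(self) -> float:
        return self.C_m

    # ---- gate rate functions (1/ms); array-safe ----
    @staticmethod
    def rates_m(V):
        x = V + 47.13
        am = 0.32 * _safe_ratio(x, 1.0 - np.exp(-0.1 * x), 10.0)
        bm = 0.08 * np.exp(-V / 11.0)
        return am, bm

    @staticmethod
    def rates_h(V):
        V = np.asarray(V, dtype=float)
        low = V < -40.0
        ah = np.where(low, 0.135 * np.exp(-(80.0 + V) / 6.8), 0.0)
        bh_low = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * np.minimum(V, 0.0))
        bh_high = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        return ah, np.where(low, bh_low, bh_high)

    @staticmethod
    def rates_j(V):
        V = np.asarray(V, dtype=float)
        low = V < -40.0
        Vc = np.minimum(V, 0.0)  # overflow guard for the exp(0.2444 V) term
        aj_low = (
            (-1.2714e5 * np.exp(0.2444 * Vc) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        aj = np.where(low, aj_low, 0.0)
        bj_low = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
        bj_high = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
        return aj, np.where(low, bj_low, bj_high)

    @staticmethod
    def rates_d(V):
        ad = 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
        bd = 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
        return ad, bd

    @staticmethod
    def rates_f(V):
        af = 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
        bf = 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))
        return af, bf

    @staticmethod
    def rates_x(V):
        ax = 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
        bx = 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))
        return ax, bx

    def all_rates(self, V):
        return (
            self.rates_m(V), self.rates_h(V), self.rates_j(V),
            self.rates_d(V), self.rates_f(V), self.rates_x(V),
        )

    def gate_steady_state(self, V) -> np.ndarray:
        """Steady-state values of (m, h, j, d, f, x) at fixed voltage."""
        vals = [a / (a + b) for a, b in self.all_rates(V)]
        return np.stack([np.asarray(v, dtype=float) for v in vals], axis=-1)

    @staticmethod
    def xi(V):
        """Inward-rectification factor of the time-dependent K current."""
        V = np.asarray(V, dtype=float)
        num = 2.837 * (np.exp(0.04 * (V + 77.0)) - 1.0)
        den = (V + 77.0) * np.exp(0.04 * (V + 35.0))
        lim = 2.837 * 0.04 / np.exp(0.04 * (V + 35.0))  # limit V -> -77
        out = np.where(V > -100.0, _safe_ratio(num, den, lim), 1.0)
        return out

    def current_densities(self, y) -> dict:
        """Ionic current densities (µA/µF) from a state vector/array."""
        V = y[..., 0]
        m, h, jj, d, f, x = (y[..., i] for i in range(1, 7))
        Ca = y[..., 7]
        I_Na = self.G_Na * m**3 * h * jj * (V - self.E_Na)
        E_si = 7.7 - 13.0287 * np.log(np.maximum(Ca, 1e-10))
        I_si = self.G_si * d * f * (V - E_si)
        I_K = self.G_K * x * self.xi(V) * (V - self.E_K)
        aK1 = 1.02 / (1.0 + np.exp(0.2385 * (V - self.E_K1 - 59.215)))
        bK1 = (
            0.49124 * np.exp(0.08032 * (V - self.E_K1 + 5.476))
            + np.exp(0.06175 * (V - self.E_K1 - 594.31))
        ) / (1.0 + np.exp(-0.5143 * (V - self.E_K1 + 4.753)))
        I_K1 = self.G_K1 * (aK1 / (aK1 + bK1)) * (V - self.E_K1)
        Kp = 1.0 / (1.0 + np.exp((7.488 - V) / 5.98))
        I_Kp = 0.0183 * Kp * (V - self.E_K1)
        I_b = 0.03921 * (V + 59.87)
        return {
            "I_Na": I_Na, "I_si": I_si, "I_K": I_K,
            "I_K1": I_K1, "I_Kp": I_Kp, "I_b": I_b,
            "I_ion": I_Na + I_si + I_K + I_K1 + I_Kp + I_b,
        }

    def total_current(self, y):
        """Cell-total ionic current I_myo (pA)."""
        return self.current_densities(y)["I_ion"] * self.C_m

    def rhs(self, y, I_inj=0.0) -> np.ndarray:
        """Full state derivative; I_inj is cell-total pA into the cell."""
        V = y[..., 0]
        cur = self.current_densities(y)
        dV = (-cur["I_ion"] * self.C_m + I_inj) / self.C_m
        if not np.all(np.isfinite(np.atleast_1d(dV))):
            raise FloatingPointError(
                f"non-finite myocyte dV/dt at V={V!r}; last currents: "
                + ", ".join(f"{k}={v!r}" for k, v in cur.items())
            )
        dgates = []
        for i, (a, b) in enumerate(self.all_rates(V), start=1):
            g = y[..., i]
            dgates.append(a * (1.0 - g) - b * g)
        dCa = -1e-4 * cur["I_si"] + 0.07 * (1e-4 - y[..., 7])
        return np.stack(
            [np.asarray(v, dtype=float) for v in (dV, *dgates, dCa)], axis=-1
        )

    def initial_state(self) -> np.ndarray:
        """Quiescent state near the resting potential."""
        V = -84.38
        return np.array([V, *self.gate_steady_state(V), 2e-4])


def myocyte_rhs(state: MyocyteState, I_inj: float = 0.0,
                model: LR1Myocyte | None = None) -> np.ndarray:
    model = model or LR1Myocyte()
    return model.rhs(state.to_vector(), I_inj)
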
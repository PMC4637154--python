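"""Gap-junction conductance models.

A gap-junction channel is two hemichannels (connexons) in series.  Each
hemichannel carries one voltage gate that switches between a high (H) and a
nonzero residual low (L) conductance state, driven by the part of the
transjunctional voltage V_j that drops across that hemichannel.  The two
gates acting independently give four channel conformations HH, HL, LH, LL;
a population of N_C channels is described by the occupancy fractions of the
four states (mean-field master equation), and the junction conductance is

    G_j = N_C * sum_state f_state * g_state.

Gating is *contingent* by default: the voltage sensed by each gate follows
the resistive divider of the current conformation, so a closed (residual)
hemichannel takes most of V_j and reinforces its own closure.  An
independent-gating variant (each gate always senses half of V_j, as in a
fixed divider) is available for comparison.

Voltage/orientation conventions.  For a junction between cell X (side A)
and cell Y (side B), V_j = V_Y - V_X.  The drop across hcA is
v_A = V_j * gB/(gA+gB) and across hcB is v_B = V_j * gA/(gA+gB).  Each gate
senses its own cytoplasmic side relative to the junction interior
(s_A = -v_A, s_B = +v_B) multiplied by the isoform's gating polarity.

The shipped Cx43 and Cx45 parameter sets reproduce the standard steady-state
calibration: homotypic conductance maximal at V_j = 0, symmetric decline to
a nonzero residual, half-inactivation near 57 mV (Cx43) and 26 mV (Cx45),
and the heterotypic Cx43/Cx45 junction losing conductance preferentially at
negative V_j (Cx45 side negative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HemichannelParams",
    "GJPopulationState",
    "SteadyStateCurve",
    "CX43",
    "CX45",
    "PHENOTYPES",
    "GapJunctionModel",
    "StaticGapJunction",
    "channel_state_conductance",
    "hemichannel_voltages",
    "gate_rates",
    "population_rhs",
    "dynamic_conductance",
    "steady_state_curve",
    "half_inactivation_voltage",
    "fit_modified_boltzmann",
]

STATE_LABELS = ("HH", "HL", "LH", "LL")
_EXP_CLAMP = 50.0


@dataclass(frozen=True)
class HemichannelParams:
    """One connexon's conductances and gate kinetics.

    g_H, g_L  : open / residual conductance, pS (g_H > g_L > 0)
    lam       : base transition rate at the gate midpoint, 1/ms
    A_open    : voltage sensitivity of the opening (L->H) rate, 1/mV
    A_close   : voltage sensitivity of the closing (H->L) rate, 1/mV
    polarity  : +1 or -1; sign of the sensed cytoplasmic-side voltage that
                promotes closure
    V_0       : half-gating offset of the single gate, mV (sensed voltage at
                which open and closed are equally likely)
    """

    g_H: float
    g_L: float
    lam: float
    A_open: float
    A_close: float
    polarity: int
    V_0: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.g_H > self.g_L > 0):
            raise ValueError("require g_H > g_L > 0")
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


# Default isoform parameter sets.  The unitary conductances follow the
# single-channel literature scale (Cx43 main state ~100 pS, Cx45 ~40 pS,
# residual about a quarter of the main state); V_0 was calibrated once
# against the stationary curve so the junction half-inactivation voltages
# land inside the measured ranges (Cx43 55-60 mV, Cx45 23-30 mV).
CX43 = HemichannelParams(
    g_H=100.0, g_L=25.0, lam=0.0025, A_open=0.075, A_close=0.075,
    polarity=+1, V_0=37.5, name="Cx43",
)
CX45 = HemichannelParams(
    g_H=40.0, g_L=10.0, lam=0.008, A_open=0.10, A_close=0.10,
    polarity=-1, V_0=16.5, name="Cx45",
)

PHENOTYPES: dict[str, tuple[HemichannelParams, HemichannelParams]] = {
    "Cx43": (CX43, CX43),
    "Cx45": (CX45, CX45),
    "Cx43/Cx45": (CX43, CX45),
}


@dataclass
class GJPopulationState:
    """Occupancy fractions of the four channel conformations."""

    f_HH: float
    f_HL: float
    f_LH: float
    f_LL: float
    phenotype: str = "Cx43"
    N_C: int = 1

    def __post_init__(self) -> None:
        f = self.fractions
        if np.any(f < -1e-12):
            raise ValueError("fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 (within 1e-9)")
        if self.N_C < 1:
            raise ValueError("N_C must be >= 1")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_HH, self.f_HL, self.f_LH, self.f_LL])


# --------------------------------------------------------------------------
# elementary pieces
# --------------------------------------------------------------------------

def _state_g_pair(state_label: str, hcA: HemichannelParams, hcB: HemichannelParams):
    if state_label not in STATE_LABELS:
        raise ValueError(f"unknown state label {state_label!r}")
    gA = hcA.g_H if state_label[0] == "H" else hcA.g_L
    gB = hcB.g_H if state_label[1] == "H" else hcB.g_L
    return gA, gB


def channel_state_conductance(state_label: str, hcA: HemichannelParams,
                              hcB: HemichannelParams) -> float:
    """Series conductance (pS) of the channel in one conformation."""
    gA, gB = _state_g_pair(state_label, hcA, hcB)
    return gA * gB / (gA + gB)


def hemichannel_voltages(V_j, state_label: str, hcA: HemichannelParams,
                         hcB: HemichannelParams):
    """Voltage drops (v_A, v_B) across the two series hemichannels.

    Division is proportional to resistance, so v_A + v_B = V_j exactly.
    """
    gA, gB = _state_g_pair(state_label, hcA, hcB)
    v_A = V_j * gB / (gA + gB)
    return v_A, V_j - v_A


def gate_rates(v, params: HemichannelParams):
    """(closing H->L, opening L->H) rates (1/ms) at sensed voltage ``v``.

    Exponential voltage dependence on the polarity-signed sensed voltage u:
    both rates equal ``lam`` at u = V_0; the equilibrium open fraction is a
    Boltzmann 1/(1+exp((A_open+A_close)(u - V_0))), >1/2 at u = 0.
    """
    u = params.polarity * np.asarray(v, dtype=float)
    z = u - params.V_0
    r_close = params.lam * np.exp(np.clip(params.A_close * z, -_EXP_CLAMP, _EXP_CLAMP))
    r_open = params.lam * np.exp(np.clip(-params.A_open * z, -_EXP_CLAMP, _EXP_CLAMP))
    return r_close, r_open


# --------------------------------------------------------------------------
# four-state population kinetics
# --------------------------------------------------------------------------

class GapJunctionModel:
    """Four-state voltage-gated channel population for one F-M (or any
    cell-cell) junction.

    Parameters
    ----------
    hcA, hcB : hemichannel parameter sets for side A (cell X) and side B
        (cell Y); V_j = V_Y - V_X.
    N_C : number of channels in the junction.
    contingent : if True (default) gate voltages follow the conformation-
        dependent resistive divider; if False both gates sense the fixed
        HH-state divider.
    """

    n_states = 4

    def __init__(self, hcA: HemichannelParams, hcB: HemichannelParams,
                 N_C: int = 1, contingent: bool = True):
        self.hcA = hcA
        self.hcB = hcB
        self.N_C = int(N_C)
        self.contingent = contingent
        self.state_g = np.array(
            [channel_state_conductance(s, hcA, hcB) for s in STATE_LABELS]
        )  # pS, order HH HL LH LL

    @classmethod
    def from_phenotype(cls, phenotype: str, N_C: int = 1,
                       contingent: bool = True, flip: bool = False) -> "GapJunctionModel":
        try:
            hcA, hcB = PHENOTYPES[phenotype]
        except KeyError:
            raise ValueError(f"unknown phenotype {phenotype!r}") from None
        if flip:
            hcA, hcB = hcB, hcA
        return cls(hcA, hcB, N_C=N_C, contingent=contingent)

    @property
    def g_HH(self) -> float:
        return self.state_g[0]

    def initial_fractions(self) -> np.ndarray:
        return np.array([1.0, 0.0, 0.0, 0.0])

    def _sensed_voltages(self, V_j):
        """Sensed gate voltages (s_A, s_B) per conformation; arrays (..., 4)."""
        V_j = np.asarray(V_j, dtype=float)[..., None]
        if self.contingent:
            labels = STATE_LABELS
        else:
            labels = ("HH",) * 4
        vA = np.stack(
            [hemichannel_voltages(np.squeeze(V_j, -1), s, self.hcA, self.hcB)[0]
             for s in labels], axis=-1,
        )
        vB = V_j - vA
        return -vA, vB

    def rate_matrix(self, V_j) -> np.ndarray:
        """Master-equation rate matrix Q (4x4, units 1/ms) at fixed V_j.

        Q[i, j] is the rate from state j to state i (columns sum to 0), with
        each transition evaluated at the sensed voltage of the *origin*
        conformation (contingent gating).
        """
        s_A, s_B = self._sensed_voltages(V_j)  # (..., 4)
        cA, oA = gate_rates(s_A, self.hcA)
        cB, oB = gate_rates(s_B, self.hcB)
        shape = np.shape(V_j)
        Q = np.zeros(shape + (4, 4))
        # state order: 0=HH 1=HL 2=LH 3=LL; first letter gate A, second gate B
        moves = [
            (0, 2, cA), (2, 0, oA),  # A gate: HH<->LH
            (1, 3, cA), (3, 1, oA),  # A gate: HL<->LL
            (0, 1, cB), (1, 0, oB),  # B gate: HH<->HL
            (2, 3, cB), (3, 2, oB),  # B gate: LH<->LL
        ]
        for src, dst, r in moves:
            Q[..., dst, src] += r[..., src]
            Q[..., src, src] -= r[..., src]
        return Q

    def population_rhs(self, fractions, V_j) -> np.ndarray:
        """d(fractions)/dt of the four-state master equation."""
        Q = self.rate_matrix(V_j)
        return np.einsum("...ij,...j->...i", Q, np.asarray(fractions, dtype=float))

    def stationary_distribution(self, V_j) -> np.ndarray:
        """Stationary fractions at fixed V_j (null space of the rate matrix)."""
        Q = self.rate_matrix(np.asarray(V_j, dtype=float))
        A = Q.copy()
        A[..., 3, :] = 1.0  # replace one balance row by the normalization
        b = np.zeros(A.shape[:-1])
        b[..., 3] = 1.0
        f = np.linalg.solve(A, b[..., None])[..., 0]
        return np.clip(f, 0.0, None) / np.clip(f, 0.0, None).sum(-1, keepdims=True)

    def conductance(self, fractions) -> np.ndarray:
        """Junction conductance G_j (nS) from state fractions."""
        f = np.asarray(fractions, dtype=float)
        return self.N_C * (f @ self.state_g) * 1e-3  # pS -> nS

    @property
    def G_max(self) -> float:
        """Maximal (all channels HH) conductance, nS."""
        return self.N_C * self.g_HH * 1e-3


class StaticGapJunction:
    """Constant-conductance junction: G_j fixed at the dynamic model's maximum."""

    n_states = 0

    def __init__(self, G_j: float):
        if G_j < 0:
            raise ValueError("G_j must be non-negative")
        self.G_j = float(G_j)

    def conductance(self, fractions=None) -> float:
        return self.G_j

    @property
    def G_max(self) -> float:
        return self.G_j


def population_rhs(pop: GJPopulationState, V_j, hcA: HemichannelParams,
                   hcB: HemichannelParams, contingent: bool = True) -> np.ndarray:
    model = GapJunctionModel(hcA, hcB, N_C=pop.N_C, contingent=contingent)
    return model.population_rhs(pop.fractions, V_j)


def dynamic_conductance(pop: GJPopulationState, hcA: HemichannelParams,
                        hcB: HemichannelParams) -> float:
    model = GapJunctionModel(hcA, hcB, N_C=pop.N_C)
    return float(model.conductance(pop.fractions))


# --------------------------------------------------------------------------
# steady-state characterization
# --------------------------------------------------------------------------

@dataclass
class SteadyStateCurve:
    """Normalized stationary conductance versus transjunctional voltage."""

    V_j: np.ndarray
    G_norm: np.ndarray
    phenotype: str = ""

    def __post_init__(self) -> None:
        self.V_j = np.asarray(self.V_j, dtype=float)
        self.G_norm = np.asarray(self.G_norm, dtype=float)
        if self.V_j.ndim != 1 or self.V_j.shape != self.G_norm.shape:
            raise ValueError("V_j and G_norm must be matching 1-D arrays")
        if np.any(np.diff(self.V_j) <= 0):
            raise ValueError("V_j grid must be strictly increasing")
        if np.any(self.G_norm <= 0) or np.any(self.G_norm > 1 + 1e-9):
            raise ValueError("normalized conductance must lie in (0, 1]")


def steady_state_curve(phenotype: str, V_j=None, contingent: bool = True,
                       model: GapJunctionModel | None = None) -> SteadyStateCurve:
    """Stationary G_j/G_j,max over a V_j grid (default ±100 mV, 0.5 mV step)."""
    if V_j is None:
        V_j = np.arange(-100.0, 100.0 + 0.25, 0.5)
    V_j = np.asarray(V_j, dtype=float)
    if V_j.min() > -100.0 or V_j.max() < 100.0:
        raise ValueError("grid must span at least ±100 mV")
    if model is None:
        model = GapJunctionModel.from_phenotype(phenotype, contingent=contingent)
    f = model.stationary_distribution(V_j)
    G = model.conductance(f)
    return SteadyStateCurve(V_j, G / G.max(), phenotype=phenotype)


def half_inactivation_voltage(curve: SteadyStateCurve) -> float:
    """|V_j| where the symmetric curve crosses midway between its maximum
    and its large-|V_j| residual plateau (linear interpolation).

    Defined for homotypic (symmetric, monotone-on-the-positive-branch)
    curves; the positive and negative branch estimates are averaged.
    """
    vals = []
    for sign in (+1, -1):
        sel = sign * curve.V_j >= 0
        v = np.abs(curve.V_j[sel])
        g = curve.G_norm[sel]
        order = np.argsort(v)
        v, g = v[order], g[order]
        target = 0.5 * (g.max() + g[-1])  # midpoint max <-> residual plateau
        below = np.nonzero(g <= target)[0]
        if len(below) == 0 or below[0] == 0:
            raise ValueError("curve does not cross its midpoint within the grid")
        i = below[0]
        frac = (g[i - 1] - target) / (g[i - 1] - g[i])
        vals.append(v[i - 1] + frac * (v[i] - v[i - 1]))
    return float(np.mean(vals))


def _two_sided_boltzmann(V, G_max, G_res_pos, G_res_neg, V_half_pos,
                         V_half_neg, k_pos, k_neg):
    pos = G_res_pos + (G_max - G_res_pos) / (1.0 + np.exp((V - V_half_pos) / k_pos))
    neg = G_res_neg + (G_max - G_res_neg) / (1.0 + np.exp(-(V - V_half_neg) / k_neg))
    return np.where(V >= 0, pos, neg)


def fit_modified_boltzmann(curve: SteadyStateCurve) -> dict:
    """Least-squares fit of a two-sided Boltzmann with residual conductances.

    The positive and negative V_j polarities are fitted simultaneously, each
    with its own half-inactivation voltage, slope factor and residual, under
    a shared maximum.  Returns the parameters plus the fit RMS residual.
    """
    if curve.V_j.min() >= 0 or curve.V_j.max() <= 0:
        raise ValueError("curve must cover both V_j polarities")
    V, G = curve.V_j, curve.G_norm
    gmax = G.max()
    gres_p = G[V >= 0].min()
    gres_n = G[V <= 0].min()
    p0 = np.array([gmax, gres_p, gres_n, 40.0, -40.0, 8.0, 8.0])

    def resid(p):
        return _two_sided_boltzmann(V, *p) - G

    lb = [0.0, 0.0, 0.0, 1.0, -150.0, 0.5, 0.5]
    ub = [2.0, 1.0, 1.0, 150.0, -1.0, 60.0, 60.0]
    res = least_squares(resid, p0, bounds=(lb, ub))
    if not res.success and res.status <= 0:
        raise RuntimeError(f"Boltzmann fit failed: {res.message}")
    G_max, G_res_pos, G_res_neg, Vh_pos, Vh_neg, k_pos, k_neg = res.x
    return {
        "G_max": G_max,
        "G_res_pos": G_res_pos, "G_res_neg": G_res_neg,
        "V_half_pos": Vh_pos, "V_half_neg": Vh_neg,
        "k_pos": k_pos, "k_neg": k_neg,
        "rms_residual": float(np.sqrt(np.mean(res.fun**2))),
    }


def rescaled(params: HemichannelParams, **changes) -> HemichannelParams:
    """Convenience wrapper over dataclasses.replace for parameter overrides."""
    return replace(params, **changes)
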
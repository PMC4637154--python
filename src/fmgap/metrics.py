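"""Derived quantities from simulated traces.

AP morphology metrics (resting potential, upstroke velocity, amplitude,
plateau, APD50/APD90), the early/late decomposition of the gap junctional
current, the dynamic-vs-static peak difference ΔI_gap,peak, the
(F-M ratio × conductance) sweep, and spontaneous-activity detection.

The early component of I_gap is the transient-outward-like surge during
phase 1 of the AP (default window: 10 ms after the upstroke); the late
component is the background-like current read at the APD50 time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coupling import CouplingConfig, CoupledSystem, Trace

__all__ = [
    "APMetrics",
    "GapCurrentComponents",
    "SweepResult",
    "ap_metrics",
    "igap_components",
    "delta_igap_peak",
    "sweep_delta_igap",
    "detect_spontaneous",
    "run_matched_pair",
]

AP_AMPLITUDE_MIN = 40.0  # mV; smaller excursions are not counted as APs
EARLY_WINDOW = 10.0      # ms after the upstroke
DVDT_THRESHOLD = 10.0    # mV/ms for AP detection


@dataclass(frozen=True)
class APMetrics:
    resting_potential: float  # mV
    dVdt_max: float           # mV/ms
    amplitude: float          # mV
    plateau_potential: float  # mV (mean over [APD20, APD50] window)
    APD50: float              # ms
    APD90: float              # ms
    t_upstroke: float         # ms (time of dV/dt max)
    detected: bool = True

    def __post_init__(self) -> None:
        # APDs are nan when the trace truncates before full repolarization
        if (self.detected and np.isfinite(self.APD50)
                and np.isfinite(self.APD90) and self.APD50 > self.APD90):
            raise ValueError("APD50 must not exceed APD90")


@dataclass(frozen=True)
class GapCurrentComponents:
    early_peak: float       # pA, max |I_gap| in the early window
    early_peak_time: float  # ms
    late_component: float   # pA, signed I_gap at the APD50 time


def _dvdt(t, V):
    return np.gradient(V, t)


def _beat_upstrokes(t, V, min_separation=100.0):
    """Indices of dV/dt maxima of each detected AP."""
    dv = _dvdt(t, V)
    cand = np.nonzero(dv > DVDT_THRESHOLD)[0]
    ups = []
    for i in cand:
        if ups and t[i] - t[ups[-1]] < min_separation:
            if dv[i] > dv[ups[-1]]:
                ups[-1] = i
            continue
        ups.append(i)
    return ups


def _crossing_time(t, V, level, i_start, direction):
    """Linear-interpolated time where V crosses `level` after index i_start."""
    V = V[i_start:]
    t = t[i_start:]
    if direction < 0:
        hit = np.nonzero(V <= level)[0]
    else:
        hit = np.nonzero(V >= level)[0]
    if len(hit) == 0 or hit[0] == 0:
        return np.nan
    i = hit[0]
    frac = (level - V[i - 1]) / (V[i] - V[i - 1])
    return t[i - 1] + frac * (t[i] - t[i - 1])


def ap_metrics(trace: Trace, beat_index: int = 0) -> APMetrics:
    """AP morphology metrics of one beat of the myocyte voltage.

    The resting potential is the minimum voltage over the diastolic interval
    preceding the upstroke; APD values run from the dV/dt maximum to the
    stated repolarization fraction toward that resting value; the plateau is
    the mean voltage between the APD20 and APD50 times.
    """
    t, V = trace.t, trace.V_myo
    ups = _beat_upstrokes(t, V)
    if beat_index >= len(ups):
        raise IndexError(f"beat {beat_index} not found ({len(ups)} beats detected)")
    i_up = ups[beat_index]
    i_prev = ups[beat_index - 1] if beat_index > 0 else 0
    rest = V[i_prev:i_up + 1].min() if i_up > i_prev else V[0]
    i_end = ups[beat_index + 1] if beat_index + 1 < len(ups) else len(t)
    seg_t, seg_V = t[i_up:i_end], V[i_up:i_end]
    peak = seg_V.max()
    amp = peak - rest
    if amp < AP_AMPLITUDE_MIN:
        return APMetrics(rest, float(_dvdt(t, V)[i_up]), amp, np.nan,
                         np.nan, np.nan, t[i_up], detected=False)
    levels = {p: peak - p / 100.0 * amp for p in (20, 50, 90)}
    t_cross = {p: _crossing_time(seg_t, seg_V, lv, np.argmax(seg_V), -1)
               for p, lv in levels.items()}
    t_up = t[i_up]
    apd50 = t_cross[50] - t_up
    apd90 = t_cross[90] - t_up
    plateau_sel = (seg_t >= t_cross[20]) & (seg_t <= t_cross[50])
    plateau = float(seg_V[plateau_sel].mean()) if plateau_sel.any() else np.nan
    return APMetrics(
        resting_potential=float(rest),
        dVdt_max=float(_dvdt(t, V)[i_up]),
        amplitude=float(amp),
        plateau_potential=plateau,
        APD50=float(apd50),
        APD90=float(apd90),
        t_upstroke=float(t_up),
    )


def igap_components(trace: Trace, beat_index: int = 0,
                    early_window: float = EARLY_WINDOW) -> GapCurrentComponents:
    """Early/late decomposition of the summed gap junctional current."""
    I = trace.total_I_gap()
    if trace.N == 0:
        return GapCurrentComponents(0.0, 0.0, 0.0)
    m = ap_metrics(trace, beat_index)
    if not m.detected:
        raise ValueError("no AP upstroke detected in trace")
    t = trace.t
    sel = (t >= m.t_upstroke) & (t <= m.t_upstroke + early_window)
    i_peak = np.argmax(np.abs(I[sel]))
    t_apd50 = m.t_upstroke + m.APD50
    late = float(np.interp(t_apd50, t, I))
    return GapCurrentComponents(
        early_peak=float(np.abs(I[sel])[i_peak]),
        early_peak_time=float(t[sel][i_peak]),
        late_component=late,
    )


def delta_igap_peak(dynamic: Trace, static: Trace, beat_index: int = 0) -> float:
    """|early peak| dynamic minus |early peak| static (pA, expected <= 0).

    Both traces must come from matched configurations differing only in the
    gap-junction model.
    """
    cd, cs = dynamic.config, static.config
    if cd is not None and cs is not None:
        if not (cd.is_dynamic and not cs.is_dynamic):
            raise ValueError("expected one dynamic and one static trace")
        if cd.static_counterpart() != cs:
            raise ValueError("traces come from mismatched configurations")
    e_d = igap_components(dynamic, beat_index).early_peak
    e_s = igap_components(static, beat_index).early_peak
    return e_d - e_s


def run_matched_pair(config: CouplingConfig, t_end: float = 350.0,
                     output_dt: float = 0.1, **kwargs) -> tuple[Trace, Trace]:
    """Simulate a dynamic configuration and its static counterpart."""
    if not config.is_dynamic:
        raise ValueError("config must specify a dynamic phenotype")
    tr_d = CoupledSystem(config).simulate(t_end, output_dt, **kwargs)
    tr_s = CoupledSystem(config.static_counterpart()).simulate(
        t_end, output_dt, **kwargs)
    return tr_d, tr_s


@dataclass
class SweepResult:
    """ΔI_gap,peak over the (F-M ratio × conductance) grid."""

    ratios: np.ndarray        # F-M ratio axis
    conductances: np.ndarray  # nS axis
    delta: np.ndarray         # pA, shape (n_ratios, n_conductances)
    early_static: np.ndarray
    early_dynamic: np.ndarray
    phenotype: str = ""

    def __post_init__(self) -> None:
        shape = (len(self.ratios), len(self.conductances))
        for name in ("delta", "early_static", "early_dynamic"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match the axes")

    def argmax_conductance(self, ratio_index: int = -1) -> float:
        """Conductance (nS) maximizing |ΔI_gap,peak| at one ratio."""
        row = np.abs(self.delta[ratio_index])
        if np.all(np.isnan(row)):
            raise ValueError("all sweep cells failed at this ratio")
        return float(self.conductances[np.nanargmax(row)])

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, r in enumerate(self.ratios):
            for j, g in enumerate(self.conductances):
                recs.append(
                    {"ratio": r, "G_j_max": g, "delta_igap_peak": self.delta[i, j],
                     "early_static": self.early_static[i, j],
                     "early_dynamic": self.early_dynamic[i, j]}
                )
        return pd.DataFrame(recs)


DEFAULT_RATIOS = (1, 2, 4, 6, 8)
DEFAULT_CONDUCTANCES = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


def sweep_delta_igap(ratios=DEFAULT_RATIOS, conductances=DEFAULT_CONDUCTANCES,
                     phenotype: str = "Cx45", base: CouplingConfig | None = None,
                     t_end: float = 350.0, **kwargs) -> SweepResult:
    """Paired static/dynamic first-beat runs over the full grid.

    A failed run flags its cell as NaN and the sweep continues.
    """
    base = base or CouplingConfig()
    ratios = np.asarray(ratios, dtype=int)
    conductances = np.asarray(conductances, dtype=float)
    shape = (len(ratios), len(conductances))
    delta = np.full(shape, np.nan)
    e_s = np.full(shape, np.nan)
    e_d = np.full(shape, np.nan)
    for i, N in enumerate(ratios):
        for j, G in enumerate(conductances):
            cfg = replace(base, N=int(N), gj_model=phenotype, G_j_max=float(G))
            try:
                tr_d, tr_s = run_matched_pair(cfg, t_end=t_end, **kwargs)
                e_d[i, j] = igap_components(tr_d).early_peak
                e_s[i, j] = igap_components(tr_s).early_peak
                delta[i, j] = e_d[i, j] - e_s[i, j]
            except (RuntimeError, FloatingPointError, ValueError):
                continue
    return SweepResult(ratios, conductances, delta, e_s, e_d,
                       phenotype=phenotype)


def detect_spontaneous(trace: Trace, stimulus_times=None,
                       margin: float = 50.0, dvdt_threshold: float = 0.25,
                       t_min: float = 0.0, refractory: float = 250.0,
                       lookback: float = 1500.0) -> list[float]:
    """Upstroke times of APs not attributable to a stimulus.

    An AP (dV/dt max above ``dvdt_threshold``, amplitude above 40 mV
    relative to the minimum over the preceding ``lookback`` ms) whose
    upstroke lies more than ``margin`` ms from every stimulus onset and
    after ``t_min`` is reported as spontaneous.  Fibroblast-driven
    automaticity rises from a depolarized diastolic potential where the Na
    current is largely inactivated, so its upstrokes are slow Ca-carried
    ramps — hence the gentle default dV/dt threshold and the long
    ``refractory`` gap (ms) merging one detection per cycle.
    """
    t, V = trace.t, trace.V_myo
    if stimulus_times is None:
        if trace.config is not None:
            stimulus_times = trace.config.stimulus.stim_onsets(t[-1])
        else:
            stimulus_times = t[np.nonzero(np.diff(trace.stim) > 0)[0]]
    stimulus_times = np.asarray(stimulus_times, dtype=float)
    dt_sample = t[1] - t[0] if len(t) > 1 else 1.0
    n_back = max(1, int(round(lookback / dt_sample)))
    n_fwd = int(round(500.0 / dt_sample))
    dv = _dvdt(t, V)
    cand = np.nonzero(dv > dvdt_threshold)[0]
    out = []
    for i in cand:
        if t[i] < t_min:
            continue
        if out and t[i] - out[-1] < refractory:
            continue
        rest = V[max(0, i - n_back):i + 1].min()
        peak = V[i:min(len(V), i + n_fwd)].max()
        if peak - rest < AP_AMPLITUDE_MIN:
            continue
        if stimulus_times.size == 0 or np.abs(stimulus_times - t[i]).min() > margin:
            out.append(float(t[i]))
    return out
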
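# fmgap — fibroblast–myocyte coupling with voltage-gated gap junctions

Cardiac fibrosis surrounds working myocytes with electrically coupled
fibroblasts.  Most simulation studies treat the fibroblast–myocyte (F-M) gap
junction as a fixed resistor, yet connexin channels gate with the
transjunctional voltage: each hemichannel flips between a high- and a
nonzero low-conductance state, so the junctional conductance G<sub>j</sub>
inactivates transiently whenever the two cells' voltages diverge — most of
all during the myocyte upstroke.  `fmgap` is a small simulator for asking
when that gating matters.  It targets computational electrophysiologists
who want a desk-scale, fully scriptable model of F-M coupling rather than a
tissue-scale solver.

## The model

A guinea-pig ventricular myocyte (Luo–Rudy 1991) is coupled to N identical
fibroblasts (passive RC, or the MacCannell active model resting at
−49.6 mV) in a star topology.  With V<sub>j</sub> = V<sub>fib</sub> −
V<sub>myo</sub>:

```
C_myo dV_myo/dt = −I_myo + Σ_k G_j,k·V_j,k + I_stim
C_fib dV_fib/dt = −I_fib − G_j·V_j
```

**Static junction** — G<sub>j</sub> constant, equal to the maximum of the
matched dynamic model.

**Dynamic junction** — two hemichannels in series, each carrying one
voltage gate (high H / residual L state), giving four channel conformations
HH, HL, LH, LL.  A channel population is described by occupancy fractions
f<sub>s</sub> obeying a master equation whose rates depend on the voltage
across each hemichannel (contingent gating via the resistive divider), and

```
G_j = N_C · Σ_s f_s · g_s ,       N_C = round(G_j,max / g_HH).
```

Shipped parameter sets reproduce the standard calibration of homotypic
Cx43 and Cx45 and heterotypic Cx43/Cx45 junctions: symmetric bell-shaped
steady-state G<sub>j</sub>(V<sub>j</sub>) with half-inactivation at
57.5 mV (Cx43, measured range 55–60) and 26.5 mV (Cx45, range 23–30), and
asymmetric gating of Cx43/Cx45 with enhanced sensitivity at negative
V<sub>j</sub>.  A 1D strand module (myocytes chained by static ohmic
junctions, fibroblasts attached per cell or randomly inserted into the
chain) measures conduction velocity versus fibrosis density.

## Worked example

One myocyte, one MacCannell fibroblast, 3 nS maximal coupling, Cx45
junction, a single paced beat:

```python
from fmgap import CouplingConfig, StimulusProtocol
from fmgap.metrics import run_matched_pair, ap_metrics, igap_components, delta_igap_peak

stim = StimulusProtocol(amplitude=6000, duration=1, n_beats=1, onset=10)
cfg = CouplingConfig(N=1, fibroblast="active", gj_model="Cx45",
                     G_j_max=3.0, stimulus=stim)
dyn, stat = run_matched_pair(cfg, t_end=450.0)
print(ap_metrics(dyn).APD90)              # 351.0  (uncoupled: 366.8)
print(igap_components(stat).early_peak)   # 298.2
print(igap_components(dyn).early_peak)    # 290.4
print(delta_igap_peak(dyn, stat))         # -7.8
```

The numbers (ms and pA) say: coupling shortens the action potential
duration (APD90 366.8 → 351.0 ms); the early, transient-outward-like surge
of gap current reaches 298.2 pA with a static junction but only 290.4 pA
with the voltage-gated Cx45 junction, because G<sub>j</sub> partially
inactivates while V<sub>j</sub> swings to ≈ −110 mV during the upstroke.
ΔI<sub>gap,peak</sub> = −7.8 pA is that reduction.  Sweeping F-M ratio ×
conductance (`fmgap.metrics.sweep_delta_igap`) shows the reduction is
largest at high fibrosis and intermediate (≤ 4 nS) coupling.

The same scenarios run from the shell:

```bash
fmgap gj-curve --phenotype Cx45 -o out      # steady-state G_j(V_j) table
fmgap run-pair -N 1 --phenotype Cx45 --gj-max 3 -o out
fmgap run-sweep --ratios 1,2,4,6,8 --conductances 0.5,1,2,3,4,6,8 -o out
fmgap run-cable --ratios 0,0.5,1,2 --replicates 3 -o out
```

All outputs are plain CSV with a provenance header; every run echoes its
full configuration to a sidecar YAML file and is bit-reproducible.

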
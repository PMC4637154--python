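# Methods

## Scope and units

`fmgap` simulates electrotonic coupling between one ventricular myocyte and
N fibroblasts through static or transjunctional-voltage-gated gap
junctions, plus a 1D strand for conduction-velocity (CV) studies.  Units
throughout: mV, ms, pA, pF, nS, mM; conductance·voltage is pA and
current/capacitance is mV/ms, so no hidden conversion factors exist.
Currents at module boundaries are cell-total pA; ionic models formulated
per capacitance use the 1 µF/cm² identity (pA/pF ≡ µA/µF).

## Membrane models

**Myocyte.**  The Luo–Rudy 1991 (LR1) guinea-pig ventricular model: fast Na
(m³hj), slow inward Ca with Ca-dependent reversal, time-dependent K with
inward rectification, time-independent K1, plateau K and a linear
background current, with the original single-pool Ca update.  Cell
capacitance 153.4 pF (the standard 100 µm × 11 µm cell); rest −84.4 mV,
paced amplitude ≈ 126 mV, APD90 ≈ 367 ms at 1 Hz.  The myocyte sits behind
a small interface (`rhs`, `current_densities`, `gate_steady_state`) so a
different ventricular model can be substituted; constructor hooks expose
the Ca conductance and a K1 scale for variant studies.  All rate functions
are array-safe, which is what lets the strand integrate every cell in one
vectorized call.

**Passive fibroblast.**  C_f dV/dt = −G_f (V − E_f) + I_inj.  Pair-level
defaults C_f = 6.3 pF, G_f = 1 nS, E_f = −25 mV: a small cell with the
MacCannell capacitance, unit-order membrane conductance and a depolarized
reversal in the range reported for cultured (myo)fibroblasts.  The closed
form V(t) = E_f + (V₀ − E_f)·exp(−G_f t/C_f) is shipped alongside and is
the oracle for the integrator tests.

**Active fibroblast (MacCannell).**  Four currents: an inward-rectifier K
current (ten Tusscher rectification profile, G = 0.4822 nS/pF), a
delayed-rectifier K current (activation r, inactivation s; G =
0.25 nS/pF), the electrogenic Na/K pump (linear-in-V form, maximum
2.002 pA/pF, reversal −150 mV) and a background Na conductance, with bulk
intracellular Na and K.  C_f = 6.3 pF.  Two quantities are not fixed by the
published formulation as we ship it: the cytosolic volume (set to
1137.7 µm³, a plausible small-cell value; it only scales the slow
concentration drift) and the background-Na conductance, which is the
model's free knob for the resting potential.  G_bNa = 0.008821 nS/pF was
calibrated once by root-finding so the uncoupled cell rests at −49.6 mV
after 30 s — the potential the model is defined to rest at — and is frozen.
Na/K homeostasis is slow (minutes), so 30-s runs drift by < 0.4 mV and the
resting check starts concentrations at their nominal values.

## Gap-junction model

A channel is two hemichannels (connexons) in series; each carries one
voltage gate switching between a high (H) and a nonzero residual (L)
conductance.  Channel conformations HH/HL/LH/LL have series conductances
g_s = g_A g_B/(g_A+g_B).  A population of N_C channels is mean-field: state
fractions f_s follow the master equation df/dt = Q(V_j) f, and G_j =
N_C Σ f_s g_s.  Deterministic fractions (not stochastic channels) match the
population-conductance formulation of the coupled system; single-channel
noise is out of scope.

**Gating rates.**  Each gate senses the part of V_j dropping across its own
hemichannel, from its cytoplasmic side, times an isoform polarity P:
u = P·s.  Rates are exponential in voltage,

    closing = λ·exp(A_close (u − V₀)),   opening = λ·exp(−A_open (u − V₀)),

so the single-gate equilibrium open fraction is a Boltzmann with midpoint
V₀ and steepness A_open + A_close, and the H state dominates at V_j = 0.
By default gating is *contingent*: the divider uses the conformation's own
conductances, so a closed (low-conductance) hemichannel absorbs most of
V_j and self-stabilizes; an independent-gating switch fixes the divider at
the HH conformation for comparison.

**Parameter sets.**  Published four-state fits for these phenotypes are
not tabulated in a reusable form, so the shipped sets were chosen against
the standard experimental calibration and then frozen:

| | g_H (pS) | g_L (pS) | λ (1/ms) | A_open = A_close (1/mV) | P | V₀ (mV) |
|---|---|---|---|---|---|---|
| Cx43 | 100 | 25 | 0.0025 | 0.075 | +1 | 37.5 |
| Cx45 | 40 | 10 | 0.008 | 0.10 | −1 | 16.5 |

Unitary conductances follow the single-channel literature scale (Cx43 main
state ≈ 100 pS, Cx45 ≈ 40 pS, residuals ≈ a quarter of the main state, so
the homotypic normalized residual plateau is g_HL/g_HH = 0.4).  V₀ was
calibrated once, by root-finding on the junction's stationary curve, so the
half-inactivation voltage (midpoint between maximum and residual plateau —
the appropriate definition when residuals are nonzero) lands mid-range of
the measured windows: 57.5 mV for Cx43 (range 55–60) and 26.5 mV for Cx45
(23–30).  λ and the steepnesses set the kinetics: at the gate midpoint
transitions are slow (τ ≈ 1/2λ: 200 ms for Cx43, 63 ms for Cx45) and
accelerate exponentially with voltage, reaching millisecond-scale closing
at upstroke-sized |V_j| — which is what lets the junction inactivate
partially within the 10-ms early window while barely moving at plateau
voltages.  The polarity convention (+1 for Cx43, −1 for Cx45 in our sensed-
voltage sign frame) is what makes both gates of the heterotypic Cx43/Cx45
junction close for negative V_j (fibroblast side negative), producing its
one-sided voltage sensitivity; homotypic junctions are symmetric under
V_j → −V_j for either polarity.

**Stationary curves** are computed by a direct null-space solve of Q(V_j)
per grid point (no pseudo-time integration), normalized to the maximum; a
two-sided Boltzmann with per-polarity midpoints, slopes and residuals is
fitted by bounded least squares as an independent cross-check of the
midpoint-based half-inactivation estimate (the two agree within 1 mV for
the shipped sets).

## Coupled system and integration

State layout is one flat vector [myocyte | fibroblast₁..N | fractions₁..N]
advanced by a single integrator call.  Junction current I_gap = G_j·V_j
(V_j = V_fib − V_myo) enters the myocyte with + and the fibroblast with −,
so the junction conserves charge identically per evaluation.  The static
model uses G_j = N_C·g_HH with N_C = round(G_j,max/g_HH) (≥ 1), making the
static conductance *exactly* the dynamic model's maximum — the paired
comparison is free of quantization mismatch, and a dynamic run with gates
frozen open reproduces the static run to machine precision (tested).

Two integration modes:

* **Adaptive (default):** LSODA, rtol 1e-6, absolute tolerances scaled per
  state class (1e-6 mV voltages, 1e-8 gates, 1e-10 Ca, 1e-9 fractions).
  The timeline is split at stimulus edges so the square pulse is exact and
  the solver never steps over it; output is sampled on a uniform grid via
  t_eval, which leaves the step sequence — and hence the solution —
  independent of the output density.
* **Fixed-step:** Rush–Larsen exponential updates for Hodgkin–Huxley
  gates, forward Euler for voltages, Ca and fractions (dt = 0.01–0.02 ms).
  Used where bitwise determinism across runs matters (equivalence tests,
  regression fixtures) and by the strand.

Default stimulus: 1 Hz, 1-ms, 6000 pA pulses (≈ 1.5× diastolic threshold;
threshold by bisection is ≈ 4 nA for 1 ms).  First-beat analyses start the
myocyte and fibroblast at their respective uncoupled resting states with
all channels in HH — the experiment the sweep emulates is the first paced
beat after coupling is established.

## Derived metrics

APD50/APD90 run from the dV/dt-maximum to 50/90 % repolarization toward
the resting potential (minimum of the preceding diastolic interval);
plateau potential is the mean voltage between the APD20 and APD50 times.
The early gap-current component is the largest |I_gap| within 10 ms of the
upstroke (bracketing phase 1 in this model class; configurable); the late
component is I_gap at the APD50 time.  ΔI_gap,peak is signed (dynamic −
static early-peak magnitude).  The default sweep grid spans F-M ratios
{1, 2, 4, 6, 8} (≤ 2 normal, > 2 diseased fibrosis) × conductances
{0.5, 1, 2, 3, 4, 6, 8} nS (the experimentally measured coupling range in
cultured pairs).  Under these conditions the reduction of the early peak
is largest at high ratio and intermediate conductance (3 nS at ratio 8):
at small G_j the current itself is small, while at large G_j the
fibroblast charges so fast (τ = C_f/G_j < 1 ms) that V_j collapses before
the gates can act.

The spontaneous-activity detector reports upstrokes > 50 ms away from any
stimulus with amplitude > 40 mV relative to the preceding 1.5 s minimum
and dV/dt above 0.25 mV/ms.  The gentle slope threshold is deliberate:
fibroblast-driven automaticity in this myocyte rises from a depolarized
diastolic potential with Na largely inactivated, so its upstrokes are slow
Ca-carried ramps (≲ 0.5 mV/ms; sustained ~0.85 Hz oscillations appear,
e.g., at N = 2, G_j = 8 nS, E_f = 0, with the Ca conductance reduced to
0.04 mS/µF); stimulated-AP metrics use a conventional 10 mV/ms threshold.
A 250-ms refractory merges one detection per cycle.  At very high coupling
density the cell is held depolarized and nothing is detected
(depolarization block).

## 1D strand

A discrete chain of LR1 cells joined by static ohmic junctions (default
1500 nS, giving 63.6 cm/s at 100 µm cell length — normal ventricular
range; dynamic gating between well-coupled myocytes changes CV negligibly
and is omitted).  CV is the regression slope of activation time (−20 mV
upstroke crossing, linearly interpolated) on position over the central 50 %
of the myocytes; any unactivated myocyte in the window flags block.
Stimulus: 2-ms, 20 nA pulses into the five left-most myocytes (a
single-cell pulse cannot source a 1500-nS-coupled chain).

Fibroblasts enter in one of two geometries, and the distinction is
physical, not cosmetic:

* **Attached (star) placement.**  Each myocyte keeps its place in the
  excitable chain and carries parallel fibroblast attachments.  Every cell
  starts at the quiescent point of the myocyte-plus-load system (solved by
  root-finding with gates at steady state), so the wave enters equilibrated
  tissue.  In this geometry a depolarized fibroblast load *raises* CV over
  the whole parameter range we explored (G_f up to 30 nS, G_j up to 8 nS,
  E_f up to 0 mV, tissue coupling 150–2500 nS): the achievable stable rest
  depolarization (bounded near −75 mV by the N-shaped steady-state I-V)
  stays inside this myocyte's supernormal window, and the junctional shunt
  is orders of magnitude below the Na current.  This reproduces the
  biphasic/supernormal CV-versus-density behavior of fibroblast-coated
  strand experiments, and we report it as a genuine property of
  star-attached loading on this myocyte — not a tunable defect.
* **Inline (random insertion) placement.**  Fibroblast nodes are inserted
  into the chain (interspersed coculture / diffuse fibrosis), so
  conduction must cross inexcitable tissue through a weaker interface
  coupling (g_fm_inline, default 500 nS — set so a single insert costs
  ≈ 0.5 ms against 0.16 ms per myocyte).  Mean CV then falls monotonically
  with the F-M ratio (63.6 → 28.9 → 21.7 cm/s at ratios 0/1/2, three seeds)
  and long fibroblast runs produce conduction block; with E_f = −80 mV the
  myocyte resting potential is untouched and the decline is purely
  architectural and near-linear.  Inline default fibroblast node:
  C_f = 100 pF (a tissue-scale fibrotic insert, not a single 6.3-pF cell),
  G_f = 1 nS, E_f = −50 mV.  Inline strands are settled for 150 ms without
  stimulus before pacing so the network starts at its coupled rest.

Random placement draws per-cell counts floor(r) + Bernoulli(frac(r)) from
a recorded seed; density sweeps run ≥ 3 seeds per ratio and report mean CV
and block fraction.  Step sizes are bounded by the fastest RC time constant
in the network (explicit-Euler stability), dt = 0.01 ms by default.

## Problem sizes and determinism

The test suite and the acceptance script use first-beat pair runs
(350–450 ms), 60–90-cell strands with ratios ≤ 2–3, a ±100 mV / 0.5 mV
stationary-curve grid, and a single-ratio (8) × 7-conductance sweep for
the peak-location check; these sizes keep the full suite in a few minutes
on one core while leaving every qualitative conclusion unchanged at finer
settings (doubling grids or halving dt moves the reported quantities well
within their stated tolerances).  Everything is deterministic given the
configuration; the only randomness is the seeded attachment map and the
seeded initial state of the acceptance script's fibroblast run.  Regression
fixtures are coarse fixed-step runs stored as CSV with a hash of every
shipped model parameter; a parameter change fails the comparison until the
fixtures are regenerated deliberately.

## Limitations

* The mean-field fraction description ignores channel-count fluctuations,
  which matter for junctions of a few channels (N_C < ~10).
* Unitary conductances do not rectify; slow gating, facilitation and
  recovery kinetics beyond the single fast gate per hemichannel are not
  modeled.
* The LR1 myocyte lacks modern Ca handling; absolute APD and plateau
  values are model-class specific even though the coupling-induced
  *changes* are robust.
* The strand is a discrete resistive chain, not a monodomain/bidomain
  continuum; extracellular potentials, 2D/3D geometry and
  fibroblast-fibroblast network conduction are out of scope.
* Fibroblast parameters for tissue-scale inline nodes are effective lumped
  values, not single-cell measurements.
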
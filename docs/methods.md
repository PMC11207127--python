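# Model and methods

## Overview

`tcsleep` simulates the NREM-sleep thalamocortical circuit as four
one-dimensional layers of conductance-based neurons: 200 cortical pyramidal
cells (PY), 40 cortical interneurons (IN), 40 thalamocortical relay cells
(TC) and 40 thalamic reticular cells (RE).  The cortical sub-network
generates the slow oscillation (SO, < 1 Hz alternation of silent Down
states and depolarized Up states); the thalamic sub-network generates
spindle-band (~10 Hz) oscillations through the TC–RE loop.  A sensory
neuron (SN) can deliver 20 ms cues onto the TC layer through AMPA
receptors, timed by an online SO detector under three closed-loop
protocols (CLS, sCLS, DSt).

## Cell models

Cortical cells are reduced two-compartment models.  The dendrite carries
the full capacitive equation

    C_m dV_D/dt = −g_L (V_D − E_L) − g_SD (V_D − V_S) − I_D^int − I^syn

with I_D^int = I_Na + I_Nap + I_KL + I_HVA + I_KCa + I_Km, while the
axosomatic compartment (tiny area, very large g_Na = 2000 and
g_K = 200 mS/cm²) is treated as quasi-stationary: each step V_S solves

    g_DS (V_D − V_S) = I_S^int(V_S),    I_S^int = I_Na + I_Nap + I_K

by damped fixed-point iteration.  With gating frozen within a step the
balance is linear in V_S; only the instantaneous persistent-Na activation
makes it mildly nonlinear, so three damped iterations converge far below
the integration error.  The dendrite/soma area ratio is ρ = 165 (PY) and
50 (IN); IN cells carry no persistent Na current and use g_Km = 0.03
instead of 0.014 mS/cm².  C_m = 0.75 µF/cm² and a 10 MΩ axial coupling
resistance (scaled by compartment areas) are standard reduced-model
values; the soma area 1.0×10⁻⁶ cm² reconciles density conductances with
point (µS) synaptic conductances.

Thalamic cells are single compartments, C_m = 1 µF/cm²:

    C_m dV/dt = −g_L (V − E_L) − I^int − I^syn

with I_TC^int = I_Na + I_K + I_KL + I_h + I_T and
I_RE^int = I_Na + I_K + I_KL + I_T.

All currents follow I = g·m^M·h^N·(V − E) with first-order gating
dx/dt = −(x − x_∞)/τ_x.  Cortical time constants are divided by the
temperature factor Q_T = 2.9529; the RE low-threshold current uses fixed
divisors 6.8986 (τ_m) and 3.7372 (τ_h).  Rates with removable
singularities (a·x/(1−e^(−x/q))) are evaluated through a guard at the
pole with the analytic limit a·q, making every rate continuous in V.

Parameter notes where the design was genuinely open:

* **Persistent Na activation.**  m_∞ = 0.02/(1 + exp(−(V+42)/5)).  An
  amplitude of 0.2 with g_Nap = 15/2.5 mS/cm² leaves the resting membrane
  with net inward current at every voltage near rest — no stable silent
  Down state can exist — so the lineage amplitude 0.02 is used
  (`channels.NAP_M_SCALE`).
* **TC low-threshold current.**  Relay-cell I_T kinetics are the canonical
  rat/guinea-pig sigmoids (m_∞ half-activation −57 mV, h_∞ −81 mV) with a
  3.7372 temperature divisor; the default conductance is 1.3 mS/cm²
  (a 1.1 mS/cm² relay cell sits just below the rebound-regeneration
  margin and never bursts).
* **I_h.**  Voltage gating relaxes the open fraction O toward
  h_∞ = 1/(1+exp((V+75)/5.5)) with the classical bell-shaped τ_s; a
  calcium-bound regulator P1 (P0 + 2Ca ⇌ P1, rate k1·[Ca]⁴ with
  k1 = 2.5×10⁷ mM⁻⁴ms⁻¹, k2 = 4×10⁻⁴ ms⁻¹) locks open channels
  (O + P1 → OL at k3 = 0.1 ms⁻¹, back at k4 = 0.001 ms⁻¹).  The current
  is g_h·(O + 2·OL)·(V − E_h); the locked-state factor 2 is exposed as
  `ih_ginc`.  This calcium-dependent upregulation is the spindle-waning
  mechanism: repeated TC bursts load the pool, lock channels open, and
  the standing depolarization removes the hyperpolarization needed for
  further rebounds.
* **Calcium pools.**  d[Ca]/dt = −k·I_Ca − ([Ca] − Ca_rest)/τ with
  Ca_rest = 2.4×10⁻⁴ mM; τ = 165 ms (cortical dendrite, fed by I_HVA)
  and 5 ms (TC, fed by I_T).  The cortical influx scale 0.02
  mM·cm²/(µA·ms) is a calibration constant: it sets the I_KCa build-up
  that terminates Up states after a few hundred milliseconds (too small
  and cells latch into a persistent-Na plateau; too large and Up states
  collapse into single spikes).
* **Reversals.**  E_Na = +50, E_K = −95 (matching the K-leak reversal),
  E_h = −40, E_Ca = +180 mV (Nernst-like; fixed, no per-step update).

## Synapses

AMPA, NMDA and GABA_A follow a first-order binding scheme driven by a
rectangular transmitter pulse T = A·θ(t−t0)·θ(t0+t_max−t) with A = 0.5
and t_max = 0.3 ms released at each presynaptic spike:

    dO/dt = α T (1 − O) − β O

with (α, β) = (1.1, 0.19) for AMPA, (1.0, 0.0067) for NMDA and
(10.5, 0.166) for GABA_A (ms⁻¹ scale).  A 0.03 ms pulse would open only
~1.6 % of receptors per spike and no pathway could drive its target at
the tabulated conductances, so the canonical 0.3 ms duration is the
default (configurable as `t_max`).  NMDA carries the voltage gate
f(V) = 1/(1+exp(−(V+25)/12.5)); AMPA and GABA_A have f = 1.

Intracortical AMPA and GABA_A conductances are scaled by a depression
resource updated per presynaptic spike,
D ← 1 − (1 − D(1−U))·exp(−Δt/700 ms), with U = 0.07 (AMPA) and 0.073
(GABA_A).  NMDA and all thalamic/thalamocortical projections are
undepressed.

GABA_B uses the G-protein cascade dR/dt = K1·T·(1−R) − K2·R,
dG/dt = K3·R − K4·G and I = g·G⁴/(G⁴+Kd)·(V−E_K), with K1 = 0.52
mM⁻¹ms⁻¹, K2 = 0.0013 ms⁻¹, K3 = 0.098 µM·ms⁻¹, K4 = 0.033 ms⁻¹ and
Kd = 100 µM⁴.  A tenfold smaller K1 leaves G below ~0.4 µM so the quartic
saturation term never exceeds ~10⁻⁴ and the receptor is numerically
inert; 0.52 is the canonical value of this kinetic scheme.

## Network

Connection radii are interpreted on the target layer's own index grid
(configurable to source-grid units); a source cell at fine index i maps
to the target grid through x = (i+0.5)·n_tgt/n_src − 0.5 and connects to
every target j with |x − j| ≤ radius, open boundaries, no
self-connections.  The intracortical PY→PY radius (11) is read on the
N = 40 grid (±55 PY neighbours); with the fine reading the recurrent
excitation cannot ignite network Up states at the tabulated conductances.

Conductances in the connection table are treated as per-synapse weights.
Because the aggregate normalization is an open choice, each projection
additionally carries an effective-scale factor (`engine.DEFAULT_G_SCALE`)
calibrated once for the Control regime: intra-thalamic projections are
scaled by ≈ 1/in-degree (so the tabulated value acts as a per-target
total — 33 convergent 0.1 µS inputs would otherwise make single relay
EPSPs three orders of magnitude too strong), and the corticothalamic
projections by 0.5.  The RE→TC GABA_A reversal is −94 mV (the deeply
hyperpolarized chloride reversal of relay cells in this model family);
with the cortical −70 mV value at a −77 mV relay resting potential,
"inhibition" would be non-hyperpolarizing and the I_h/I_T rebound loop
could not oscillate at all.  TC g_KL is 0.02 mS/cm² (0.03 pins the relay
cell below its rebound margin).

**Miniature-EPSP drive.**  Each SO cycle is seeded by Poisson miniature
AMPA events onto every PY and IN cell (rate 9 Hz per cell, 0.015 µS,
scaled on IN by the dendritic-area ratio), gated by the SO cycle: the
drive is removed when a cycle initiates (SO detection) and re-armed
100 ms after the cycle terminates (50 ms of network-wide PY silence).
Rate and amplitude are calibration constants tuned once so the Control
network cycles at roughly 30 SOs per minute; the ignition process is a
threshold phenomenon and these two numbers are the most sensitive in the
model.

## Stimulation

The online SO detector watches the pooled PY spike stream: after every
PY cell has been silent for more than 100 ms it arms and counts spikes;
the 75th spike marks the Down-to-Up transition.  Renewed silence while
counting resets the count; a detection disarms until a new silence.

Cues are 20 ms, 200 Hz activations of the sensory neuron (0.01 µS AMPA
onto every TC cell — calibrated so that a Point-1 cue measurably raises
the sigma-band envelope of the following two seconds).  Points 1–3 are
0/120/180 ms after detection; Point 4 is the falling 50 %-of-peak
crossing of the 20 ms-smoothed PY population rate (the Up-to-Down
transition; threshold and smoothing configurable).  Protocols: CLS cues
two successive detections then pauses detection 2.5 s; sCLS cues one;
DSt cues every detection while the preceding Down state is shorter than
0.5 s, a longer one triggering the 2.5 s pause (driving restarts with a
cue on the first detection after a pause).  Overlapping cue windows merge
(the transmitter pulse saturates rather than doubling).

## Numerics

Fixed-step integration, dt = 0.025 ms by default (voltages: explicit
Euler; gating: exact exponential relaxation; receptor states: exact
exponential updates with the transmitter pulse resolved sub-step).  The
network kernel (numba) interpolates gating steady states and per-step
decay factors from dense lookup tables on a 0.05 mV grid built from the
same rate functions as the reference single-cell classes, which are
cross-checked against the kernel in the test suite.  Synaptic state is
tracked per presynaptic cell (all connections from one source share
kinetics and pulse clocks) and per-target sums are windowed prefix sums,
which makes the cost linear in cells rather than connections.  A single
seeded generator drives all randomness in a fixed order, so a (config,
seed) pair reproduces bit-identically.  Voltage divergence (> 200 mV or
non-finite) aborts with the offending cell named.

## Analysis

The cortical LFP proxy is the summed AMPA + NMDA + GABA_A postsynaptic
current over all PY cells, sign-flipped so Up states are positive.  PSD:
Welch, 4 s windows, 50 % overlap, detrended; only relative comparisons
across conditions are meaningful.  Spectrogram: 1 s moving window, 0.1 s
hop, reported band 0.1–18 Hz.

Spindles have no unique operational definition; the detector band-passes
the LFP to the sigma band (10–16 Hz; 8–11 Hz for the slow-spindle
configuration), takes the analytic-signal envelope, and marks intervals
where the envelope exceeds k × median for at least `min_dur`, merging
gaps shorter than `merge_gap` (defaults k = 2, 0.3 s, 0.1 s).  Raising k
or `min_dur` lowers counts roughly monotonically; all parameters are
exposed and the constructed-burst fixtures in the test suite pin recall
and precision at 1.0 under the defaults.

## What the simulator does and does not emulate

The generator reproduces the *mechanistic skeleton* of NREM oscillations:
bistable cortical Up/Down dynamics seeded by stochastic minis, a
thalamic rebound loop producing waxing-and-waning sigma-band events
nested at Down-to-Up transitions, and phase-dependent sensitivity to
sensory cues.  It does not emulate: spatially realistic geometry (1-D
slabs), neuromodulatory state changes, synaptic plasticity, the auditory
periphery (cues enter as direct AMPA conductance), measurement noise or
volume conduction in the LFP, or inter-subject variability.  Passing
tests therefore demonstrate internal consistency of the implementation
and the stated emergent phenomenology, not quantitative agreement with
human EEG.

## Known limitations

* The Control regime produces spindle-band events on most SO cycles;
  detected spindle densities (roughly 10–25 per minute at the default
  detector settings) are well above typical experimental counts, and
  inter-spindle intervals correspondingly short.  The coupling between
  the cortical ignition process and thalamic feedback makes spindle
  sparsity and SO rate impossible to tune independently in this
  parameterization.
* Cue effects are modest relative to trajectory-level chaos: two runs
  differing only in a handful of cues decorrelate within seconds, so
  condition comparisons need several seeds (or paired, event-locked
  statistics, as used in the tests).
* The slow-spindle configuration (corticothalamic balance flipped toward
  RE) roughly doubles reticular activity and weakens/delays early relay
  firing, but does not reproduce a clean ~400 ms relay silence in this
  calibration.
* Simulation lengths in the tests and in the acceptance script are
  40–60 s per condition; all summary statistics are rates per minute or
  interval means, so run length scales out.  Stochastic run-to-run spread
  at this length is appreciable, which is why Control statistics are
  pooled over seeds.
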
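# tcsleep

A conductance-based thalamocortical network model of NREM sleep with
closed-loop stimulation, for computational neuroscientists studying how
sensory cues timed to slow-oscillation phases shape sleep spindles.

The network has four one-dimensional layers — 200 cortical pyramidal
cells (PY), 40 interneurons (IN), 40 thalamocortical relay cells (TC) and
40 reticular cells (RE) — all Hodgkin–Huxley type.  Cortical cells are
reduced two-compartment models,

    C_m dV_D/dt = −g_L(V_D−E_L) − g_SD(V_D−V_S) − I_D^int − I^syn,
    g_DS(V_D−V_S) = I_S^int(V_S)        (quasi-stationary axosoma)

with I_D^int = I_Na + I_Nap + I_KL + I_HVA + I_KCa + I_Km; thalamic cells
are single compartments with I_Na + I_K + I_KL + I_T (+ I_h for TC).
Synapses are kinetic receptor models (AMPA, NMDA, GABA_A first order;
GABA_B via a G-protein cascade with I = g·G⁴/(G⁴+K_d)·(V−E_K)) with
short-term depression D_{n+1} = 1 − (1−D_n(1−U))e^{−Δt/τ} on
intracortical AMPA/GABA_A.

Slow oscillations (~0.5 Hz) arise from cortical Up/Down bistability
seeded by miniature EPSPs during Down states; spindle-band (~10 Hz)
oscillations arise from the TC–RE rebound loop (I_T, I_h) and wane
through calcium-dependent I_h upregulation.  An online detector finds the
Down-to-Up transition (>100 ms of network silence, then the 75th PY
spike) and a sensory neuron delivers 20 ms AMPA cues to the TC layer
under three protocols: CLS (paired cues, then a 2.5 s detection pause),
sCLS (single cue + pause) and DSt (cue every cycle while Down states stay
short).  Cue timing points: 1 = at detection, 2/3 = +120/180 ms,
4 = the Up-to-Down transition.

See `docs/methods.md` for the full model description, parameter
rationale and known limitations.

## Worked example

Simulate 30 s of the Control regime and analyze the cortical LFP:

```
tcsleep run --protocol control --duration 30 --seed 1 --out run_ctrl
tcsleep analyze run_ctrl/lfp.tsv --events run_ctrl/events.tsv
```

which prints (seed 1):

```
duration_s	30.0
spindles	15
spindle_density_per_min	30.00
inter_spindle_mean_s	1.97
inter_spindle_sd_s	1.54
sigma_band_power	160.9
dominant_freq_5_20_hz	10.00
so_per_min	38.00
cues	0
```

Reading: the network cycles through ~38 slow oscillations per minute in
this 30 s window (SO_DETECT events in `events.tsv`); the LFP's dominant
rhythm between 5 and 20 Hz sits at 10 Hz (the thalamic spindle band),
and the envelope-threshold detector finds 15 sigma-band events whose
onsets are ~2 s apart.  A closed-loop run only differs by the protocol flags,
e.g. `--protocol cls --point 1 --pause 2.5`, and logs CUE/PAUSE events
alongside the detections.

The same operations are available as a library:

```python
from tcsleep import SimConfig, run_simulation, compute_lfp, detect_spindles

rec = run_simulation(SimConfig(duration=30.0, seed=1))
events = detect_spindles(compute_lfp(rec))
```

`tcsleep dump-params` prints the complete parameter ledger (intrinsic
currents, synaptic table, calibration constants); `tcsleep make-fixtures`
writes single-cell current-clamp traces (pyramidal step response, TC/RE
rebound bursts) as delimited text.

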
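# spinephys

Patch-clamp sweep analysis for spinal proprioceptive neurons, with a
conductance-model generator for synthetic recordings.

Clarke's column (CC) neurons relay hindlimb proprioception to the
cerebellum through the dorsal spinocerebellar tract; the neighboring
Atoh1-lineage medial and lateral neurons integrate proprioceptive input
into local spinal circuits. Whole-cell recordings distinguish these
groups by passive membrane properties, firing type under current steps,
a hyperpolarization-activated current (I_h) that is a CC signature, and
the organization of their evoked synaptic inputs. `spinephys`
implements that characterization pipeline as a tested, reusable
library:

* **intrinsic analysis** — spike detection, passive properties
  (V_m_rest, R_m, C_m, spontaneous rate), two-stage rheobase search,
  and the four-way firing-type classification: tonic (T), fading (F),
  single (S), undefined (U). A cell is F when the mean of the last
  three AP amplitudes in a step falls ≥ 25% below that step's first AP
  and a later step shows an even stronger reduction, or when firing
  fails mid-step with a rising baseline — the signature of
  depolarization block.
* **HCN analysis** — leak-subtracted I_h per voltage step
  (I_h = I_ss − I_inst), sag potentials (Δ = V_ss − V_trough),
  pharmacological block statistics including the signed sag change
  100·(Δ − Δ′)/Δ, and rebound firing after hyperpolarization.
* **synaptic analysis** — evoked-EPSC detection, the 3-of-5
  stimulation-threshold rule, the Si/Multi/Ba/Si+Ba/NR response
  taxonomy, latency jitter (SD of first latencies; low jitter with few
  failures ⇒ monosynaptic), and 20 Hz train failure/depression.
* **statistics** — mean ± SEM group summaries, Welch's t tests (raw or
  summary input), Pearson correlations, proportion tables and report
  assembly.
* **synthetic data** — a single-compartment Hodgkin–Huxley-style model
  (Na, K, low-threshold K, first-order HCN gate, slow Na inactivation
  for depolarization block) whose default archetypes are calibrated to
  the published group statistics, plus an evoked-input generator with
  Bernoulli release, resource-depletion short-term depression
  (R_{n+1} = 1 − (1 − R_n(1−U))e^{−Δt/τ_rec}), latency jitter and
  barrage structure. Every simulated sweep carries its ground truth.

See `docs/methods.md` for the model, calibration and measurement
conventions.

## Worked example

```python
import spinephys as sp

params = sp.make_archetype("CC")            # default Clarke's-column cell
cfg = sp.SimulationConfig(noise=False)
protocols = sp.standard_protocols()

battery = sp.simulate_current_clamp(params, protocols["firing_steps"], cfg)
print(sp.classify_firing_type(battery).label)

vc = sp.simulate_voltage_clamp(params, protocols["vc_hyperpol_steps"], cfg)
ih = sp.measure_ih(vc)
print({int(d): round(float(v), 1) for d, v in zip(ih.delta_mV, ih.i_h)
       if d in (-30, -60, -90)})
```

prints

```
T
{-30: -119.9, -60: -358.4, -90: -461.8}
```

The CC archetype is tonic-firing (T), and the leak-subtracted
hyperpolarization-activated current grows with step size — about
−120 pA at the Δ−30 mV step, approaching −460 pA at Δ−90 mV. Inward
currents are negative throughout. The narrative scripts in `examples/`
walk through each capability (population generation and bundle I/O,
intrinsic characterization, I_h/sag/rebound with HCN block, synaptic
input analysis, group reports) and print what the numbers mean.

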
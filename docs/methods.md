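# Methods

`spinephys` characterizes spinal proprioceptive neurons — Clarke's
column (CC) and the Atoh1-lineage medial and lateral groups — from
whole-cell patch-clamp sweep data, and ships a conductance-based
generator that produces synthetic recordings with the statistical
structure of those groups. This note documents the model, the
measurement procedures, the calibration, and the places where a design
choice was genuinely open.

## Conductance model

Each simulated cell is a single compartment:

```
C dV/dt = I_inj − g_L (V − E_L) − g_Na m∞(V)³ h s (V − E_Na)
          − g_K n⁴ (V − E_K) − g_KLT w (V − E_K) − g_h r (V − E_h) + ξ(t)
```

with Wang–Buzsáki-style Na/K kinetics shifted along the voltage axis so
spike threshold sits near −50 mV. Na activation `m` is instantaneous;
`h` and `n` follow first-order kinetics. Three additional gates carry
the phenomena of interest:

* **s — slow Na inactivation** (`s∞(V) = 1 − depth·σ((V−V_s)/k_s)`,
  fixed τ_s). This is the depolarization-block variable: sustained
  depolarization slowly removes Na availability, producing declining
  spike amplitudes, mid-step firing failure and a depolarized
  inter-spike baseline. The depth and speed of `s` are what distinguish
  the firing archetypes — tonic (negligible depth), fading
  (depth ≈ 0.9, τ_s ≈ 100–160 ms), single (very deep and fast, so
  firing stops after 1–2 APs), and undefined (parameters at the
  tonic/fading boundary; no mechanistic claim is made for the real
  switching cells).
* **w — low-threshold K conductance** (σ activation at −43 mV,
  τ = 5–15 ms). Its role is to place rheobase above the bare
  (V_thr − V_rest)/R_m prediction, as a subthreshold outward
  conductance does in real neurons. Without it the printed group means
  (e.g. medial R_m 1.81 GΩ, rest −53.75 mV, rheobase 32.6 pA) are
  mutually inconsistent in a passive-plus-spikes model.
* **r — HCN activation** (σ midpoint −100 mV, slope 10 mV; τ(V) falls
  from ≈ 480 ms at −100 mV to ≈ 60 ms at −160 mV, so activation speeds
  up with hyperpolarization). `g_h > 0` only for the CC group.
  E_h is set to −30 mV — within the physiological range for HCN
  channels — because rebound firing requires the residual HCN current
  to drive the membrane all the way to spike threshold; with a more
  negative reversal the driving force collapses a few mV short.

Membrane noise is an additive white current scaled so the stationary
voltage SD at rest equals the configured value (0.4 mV by default).
Voltage-clamp simulation uses an ideal clamp with a 0.2 ms settle;
the recorded current is ionic plus capacitive, so step responses show a
realistic brief transient.

## Integration

Strang splitting at dt = 12.5 µs: Rush–Larsen half-steps for the gates
around an exponential-Euler membrane update evaluated at a midpoint
voltage, decimated to the 10 kHz output rate. The scheme is stable
through the spike upstroke without adaptive stepping, and second-order
accurate: halving dt changes no spike count for the default archetypes
across the full step battery (this is a tested invariant). Fading cells
near the depolarization-block boundary are the sensitive case — their
last spikes straddle the spike criterion — and the archetype parameters
were chosen in the regime where counts are converged at the default
step.

## Archetype calibration

Defaults live in `src/spinephys/data/archetypes.yaml` (versioned).
Calibration targets are the published group statistics: capacitance,
input resistance, resting potential and rheobase per group; the
firing-type mixtures (CC 56/32/12% T/F/S; medial and lateral mostly
fading); leak-subtracted I_h of −118/−408/−616 pA at voltage steps of
−30/−60/−90 mV; a rebound-firing threshold in the deep-hyperpolarization
range (≈ −140 mV) abolished by HCN block; tonic CC cells reaching at
most 109 spikes during the 500 pA step with a near-linear f–I relation;
and the evoked-input latency/jitter/failure/depression values (below).

Two calibration trade-offs deserve a note:

* **Rheobase vs rebound in CC cells.** Both are set by the same
  voltage range (−60 to −50 mV): rheobase needs a subthreshold outward
  brake there, rebound needs the residual HCN current to overcome that
  brake. With the rebound threshold placed correctly (≈ −150 mV step
  trough) the CC rheobase equilibrates near 47 pA rather than the
  printed 81.8 pA group mean. The medial and lateral groups carry no
  HCN conductance, so their rheobase targets are met without
  compromise (≈ 34 and ≈ 70 pA).
* **Tonic amplitude stability in small cells.** Driven at 500 pA, a
  19 pF cell with fast-spiking K kinetics fires > 300 Hz, and the first
  AP (full Na availability) towers over the steady-state APs — which
  reads as fading. Tonic medial/lateral archetypes therefore use
  2× slower delayed-rectifier kinetics (`k_tau_scale`), which caps
  their rates and keeps the last-three/first amplitude ratio above the
  fading criterion.

Per-cell passive parameters are drawn from the documented group means
with dispersions of SEM·√n from the same source, with two guards: the
coefficient of variation is capped at 0.5 and draws are truncated at
±2 (log-)SD. Without the cap, the heavy lognormal tail produces cells
whose rheobase exceeds the 500 pA battery maximum — which would be
classified "single" regardless of archetype — taking the generator out
of the regime the published mixtures describe. Spike-conductance
densities scale with capacitance, so firing dynamics are preserved
across cell sizes.

## What the generator does and does not emulate

Emulated: the three groups' passive statistics and firing-type
mixtures; HCN currents, sag, rebound and their pharmacological block
(a `fraction` argument scales g_h, mirroring ZD-7288); junction-corrected
voltages; membrane and recording noise; evoked monosynaptic,
polysynaptic and barrage input structure with release failures and
short-term depression; optogenetic shutter latency.

Not emulated: spontaneous firing proportions at rest (model cells rest
below threshold unless their drawn resting potential is high);
electrode-access artifacts and series-resistance error; the ~6% of CC
cells without I_h (all synthetic CC cells carry g_h); temperature
effects; dendritic filtering; any mechanism for the "undefined" firing
class beyond boundary placement. Passing tests therefore validate the
measurement pipeline against a controlled ground truth — they do not
show that the pipeline is robust to every artifact of real recordings.

Measured R_m of conductance-bearing cells sits below the configured
leak value (e.g. 0.31 vs 0.41 GΩ for the CC default) because the
resting KLT and HCN conductances add to the leak — the same bias a real
−50 pA step measurement carries.

## Measurement procedures

* **Spike detection**: dV/dt ≥ 10 mV/ms marks the AP threshold time,
  the peak is the maximum within the following 5 ms, amplitude is
  peak − threshold voltage; minimum inter-event interval 1.5 ms,
  minimum amplitude 20 mV (rejects the decrementing spikelets emitted
  at the edge of depolarization block).
* **Passive properties**: V_m_rest is the median of spike-free rest
  samples; R_m the steady-state ΔV/ΔI of the −50 pA step; C_m = τ_m/R_m
  with τ_m from a single-exponential fit over the first 100 ms of the
  step onset. The 200 ms step leaves ≈ 3.5 τ_m of settling for a CC
  cell, so R_m carries a ≈ 4% underestimate — accepted, since the
  protocol is fixed.
* **Rheobase**: coarse 10–20 pA ladder to the first firing step, then a
  1–3 pA ladder starting below that estimate; the rheobase is the first
  fine step that fires with the next two steps also firing. A cell
  silent up to the protocol maximum is reported not-excitable, not an
  error.
* **Firing type**: single = fewer than 3 APs at every step; fading =
  a ≥ 25% last-three-vs-first amplitude reduction confirmed by a larger
  mean-amplitude reduction in a subsequent step, or mid-step failure
  without resumption plus a ≥ 5 mV baseline rise (inter-spike minima,
  last vs first 200 ms of the step); tonic = no fading evidence and a
  non-decreasing spike count (a dip below 80% of the running maximum
  minus one spike breaks monotonicity — the slack absorbs count noise);
  undefined = everything else, i.e. the rule outcome differs across
  intensities without the fading confirmation. Labels depend only on
  amplitudes, counts and within-step drift, so they are invariant to a
  uniform voltage offset.
* **I_h**: instantaneous current averaged over [onset+5, onset+15] ms
  (after the capacitive settle, before appreciable HCN activation),
  steady-state over the last 100 ms of the step; I_h is their
  difference, signed (inward negative). End-of-step mean is used rather
  than a fitted asymptote; for slowly activating steps this
  underestimates the true steady state slightly and is documented
  behavior.
* **Sag**: trough over [onset, onset+150] ms, steady state over the
  last 25 ms; Δ = V_ss − V_trough; sag present if Δ > 1 mV in ≥ 2
  steps. Steps whose trough falls below −120 mV are flagged (damage
  risk for small cells), never excluded. The block statistic
  100·(Δ − Δ')/Δ uses the signed drug Δ, so a blocked trace that keeps
  hyperpolarizing yields > 100%.
* **Rebound**: APs counted in the 200 ms after step offset; threshold =
  most depolarized step trough with ≥ 1 rebound AP; the
  afterdepolarization is quantified as the area (mV·ms) between V and
  the pre-step baseline over 50 ms from the first rebound AP's fast
  repolarization.
* **EPSC detection**: 1 ms stimulus-artifact blanking; events within
  (1, 500] ms; 0.5 ms boxcar smoothing for peak picking with a floor of
  max(3× raw baseline noise SD, 5 pA); amplitudes from a local pre-event
  baseline on the raw trace; latency is the interpolated time the event
  first reaches 20% of its own peak (amplitude-independent by
  construction). Under default noise the estimator recovers ≥ 95% of
  events above 3× noise SD with < 0.5 ms latency error.
* **Response taxonomy**: NR (no events), Si (one event), Multi (2–4
  events all peaking ≤ 10 ms), Si+Ba (one early event ≥ 2× the median
  amplitude of ≥ 3 later events), Ba (otherwise). The literal published
  categories leave gaps (two events spanning the 10 ms boundary; five
  early events); those route to Ba, the catch-all for prolonged
  volleys, making the taxonomy total and mutually exclusive — a tested
  property.
* **Jitter and connectivity**: jitter = sample SD of per-sweep first
  latencies (≥ 4 sweeps required). Monosynaptic calls require jitter ≤
  0.2 ms for electrical stimulation and ≤ 2 ms for optogenetic
  stimulation (shutter mechanics dominate the optical timing floor),
  plus ≤ 5% train failures when a train was recorded.
* **Stimulation threshold**: lowest tested intensity with ≥ 3 of 5
  responding sweeps; with fewer sweeps a proportional (≥ 60%) criterion
  applies, with a warning; silent up to the ladder maximum → NR.
* **Trains**: 45 ms per-stimulus windows (shorter if the next stimulus
  comes sooner; events attributed to the nearer stimulus); failure % =
  stimuli with no detected event; depression % compares the mean first-
  and last-stimulus amplitudes.

## Synaptic input model

Release per stimulus is Bernoulli (default 0.991 for the monosynaptic
dorsal-root input, giving the 0.9% failure rate). Amplitudes follow the
resource-depletion recursion
`R_{n+1} = 1 − (1 − R_n(1−U)) e^{−Δt/τ_rec}` with amplitude ∝ R_n
normalized so the first response equals the quantal amplitude
(415.3 pA distal). `U = 0.5`, `τ_rec = 0.247 s` were solved analytically
so the 20-stimulus, 20 Hz recursion gives 69% first-to-last depression.
Amplitude variability is lognormal and mean-preserving (CV 0.2–0.3);
a truncated-normal alternative occasionally produces near-floor events
whose latency estimates are meaningless. Latencies are Gaussian
(jitter = SD); optogenetic latencies are *apparent* latencies that
include the ≈ 6 ms shutter-opening lag. The polysynaptic preset adds a
latency offset and a 36.5 ms jitter; barrages are Poisson events over
(10, 500] ms with exponentially decaying rate. EPSC waveforms are
peak-normalized bi-exponentials (rise 0.5–0.8 ms, decay 6–8 ms) on a
−70 mV holding baseline.

## Statistics

Values are reported mean ± SEM. Welch's t test (two-sided, Satterthwaite
df) accepts raw samples or (n, mean, SEM) summaries; the two paths agree
to floating-point precision because the statistic depends on the data
only through (n, mean, SD). Zero variance on both sides with equal means
returns p = 1 by convention. No multiple-testing correction is applied;
raw p values are reported and the caller chooses a threshold. Proportion
tables include nonresponsive cells and sum to 100% within rounding.

## Problem sizes

The validation suite uses 200-cell cohorts for mixture recovery, a
500-cell labeled population for classifier agreement (≥ 90% for T/F/S),
100 replicate cells × 7 sweeps for jitter recovery, 8 cells × 50 trains
for failure rates, and single noise-free runs for the deterministic
calibration checks. These sizes put binomial/sampling tolerances well
inside the published precision while keeping the full suite fast on one
CPU.

## Known limitations

The model is a single compartment: no dendritic filtering, no
series-resistance artifact, no temperature dependence. The fading/single
mechanism is one biophysically plausible route to depolarization block,
not a fitted mechanism. The CC rheobase compromise and the slightly
shallow I_h growth at the deepest steps (−462 pA at Δ−90 vs −616
printed) are consequences of a first-order HCN gate sharing one
voltage range with the rheobase-setting conductance. Classification of
real recordings with different noise structure may need the detector
thresholds (all exposed as module constants) revisited.
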
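"""Passive properties, rheobase search, spike detection, and the
four-way firing-type classification (tonic / fading / single /
undefined).

The classifier follows the published criteria: a cell is **S** (single)
if it fires fewer than 3 APs at every step of the ten-step battery;
**F** (fading) if in some step the mean amplitude of the last three APs
is reduced by >= 25% relative to that step's first AP and a subsequent
step shows an even more pronounced mean-amplitude reduction, or if
firing fails mid-step without resumption together with a rising
baseline; **T** (tonic) if no step shows fading evidence and the spike
count is non-decreasing across steps; **U** (undefined) when the
outcome differs across stimulus intensities without satisfying the
fading confirmation clause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    CURRENT_CLAMP,
    CellRecording,
    ModeError,
    ProtocolError,
    Sweep,
)

# spike detector settings: dV/dt threshold defines AP threshold time;
# the peak is searched within the following window; a minimum
# inter-event interval prevents merging close doublets.
DVDT_THRESHOLD_MV_PER_MS = 10.0
PEAK_WINDOW_MS = 5.0
MIN_INTERVAL_MS = 1.5
MIN_SPIKE_AMPLITUDE_MV = 20.0

FADE_RATIO = 0.75          # last-three mean below 75% of first AP = fading
BASELINE_RISE_MV = 5.0     # within-step baseline depolarization for failure
TONIC_COUNT_SLACK = 0.8    # tolerated fractional count dip for "non-decreasing"


@dataclass
class SpikeEvent:
    """One detected action potential."""

    time: float         # s, threshold-crossing time
    peak: float         # mV
    threshold_V: float  # mV at the dV/dt criterion crossing
    amplitude: float    # mV, peak − threshold_V


@dataclass
class PassiveProps:
    Vm_rest: float      # mV
    spont_rate: float   # Hz
    Rm: float           # GΩ
    Cm: float           # pF
    tau_m: float = float("nan")  # ms


@dataclass
class RheobaseResult:
    coarse_estimate: float  # pA
    rheobase: float         # pA (nan when not excitable)
    fine_step: float        # pA
    excitable: bool = True


@dataclass
class StepEvidence:
    """Per-step evidence backing a firing-type label."""

    current_pA: float
    n_APs: int
    first_amp: float
    last3_mean: float
    mean_amp: float
    baseline_rise_mV: float
    failure: bool

    @property
    def fade(self) -> bool:
        """>=25% reduction of the last-three-AP mean vs the first AP."""
        return (self.n_APs >= 4 and np.isfinite(self.first_amp)
                and self.last3_mean <= FADE_RATIO * self.first_amp)

    @property
    def mean_reduction(self) -> float:
        if self.n_APs < 1 or not np.isfinite(self.first_amp) or self.first_amp <= 0:
            return 0.0
        return 1.0 - self.mean_amp / self.first_amp


@dataclass
class FiringTypeResult:
    label: str  # T | F | S | U
    evidence: list[StepEvidence] = field(default_factory=list)
    non_excitable: bool = False


def detect_spikes(sweep: Sweep) -> list[SpikeEvent]:
    """Detect action potentials in a current-clamp sweep.

    Threshold time is the upward crossing of the dV/dt criterion
    (10 mV/ms); the peak is the maximum within the following 5 ms;
    amplitude is peak minus threshold voltage. Events closer than
    1.5 ms to the previous threshold crossing are not re-triggered.
    """
    if sweep.mode != CURRENT_CLAMP:
        raise ModeError("spike detection requires a current-clamp sweep")
    v = sweep.response
    rate = sweep.sampling_rate
    dvdt = np.diff(v) * rate / 1000.0  # mV/ms
    above = dvdt >= DVDT_THRESHOLD_MV_PER_MS
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])

    peak_win = max(1, round(PEAK_WINDOW_MS / 1000.0 * rate))
    min_gap = MIN_INTERVAL_MS / 1000.0 * rate

    events: list[SpikeEvent] = []
    last_idx = -np.inf
    for idx in crossings:
        if idx - last_idx < min_gap:
            continue
        seg = v[idx: idx + peak_win + 1]
        pk_off = int(np.argmax(seg))
        peak = float(seg[pk_off])
        thr_v = float(v[idx])
        amp = peak - thr_v
        if amp < MIN_SPIKE_AMPLITUDE_MV:
            continue
        # require an actual downstroke within the window (reject ramps)
        if pk_off == seg.size - 1 and idx + peak_win + 1 < v.size:
            continue
        events.append(SpikeEvent(time=idx / rate, peak=peak,
                                 threshold_V=thr_v, amplitude=amp))
        last_idx = idx
    return events


def _spikes_in_window(sweep: Sweep, t0: float, t1: float) -> list[SpikeEvent]:
    return [s for s in detect_spikes(sweep) if t0 <= s.time < t1]


def _step_geometry(sweep: Sweep) -> tuple[float, float]:
    onset = sweep.meta.get("step_onset_s")
    dur = sweep.meta.get("step_duration_s")
    if onset is None or dur is None:
        if sweep.t0_events:
            onset = sweep.t0_events[0].time_s
        else:
            raise ProtocolError("sweep lacks step onset/duration metadata")
        dur = dur if dur is not None else sweep.duration - onset
    return float(onset), float(dur)


def measure_passive(rec: CellRecording) -> PassiveProps:
    """Resting potential, spontaneous rate, input resistance, capacitance.

    V_m_rest is the median of spike-free samples across the rest sweeps
    (recorded with no holding current); the spontaneous rate is total
    APs over total rest time. R_m is the steady-state ΔV/ΔI of the
    smallest (−50 pA) hyperpolarizing step; C_m = τ_m/R_m with τ_m from
    a single-exponential fit to the first 100 ms of the step onset.
    """
    rest = rec.get("rest")
    steps = rec.get("cc_hyperpol_steps")

    total_spikes = 0
    total_time = 0.0
    rest_samples = []
    for sw in rest:
        spikes = detect_spikes(sw)
        total_spikes += len(spikes)
        total_time += sw.duration
        mask = np.ones(sw.n_samples, dtype=bool)
        blank = round(0.020 * sw.sampling_rate)
        for s in spikes:
            i = round(s.time * sw.sampling_rate)
            mask[max(0, i - blank // 4): i + blank] = False
        rest_samples.append(sw.response[mask])
    vm_rest = float(np.median(np.concatenate(rest_samples)))
    spont = total_spikes / total_time

    # smallest-amplitude hyperpolarizing step
    sw = min(steps, key=lambda s: abs(s.meta.get("step_amplitude_pA", np.inf)))
    amp = sw.meta["step_amplitude_pA"]
    onset, dur = _step_geometry(sw)
    rate = sw.sampling_rate
    i_on = round(onset * rate)
    i_off = round((onset + dur) * rate)
    v = sw.response
    v_base = float(np.mean(v[max(0, i_on - round(0.05 * rate)): i_on]))
    v_ss = float(np.mean(v[i_off - round(0.025 * rate): i_off]))
    rm = (v_ss - v_base) / amp  # mV/pA = GΩ

    # membrane time constant from the step onset
    n_fit = min(round(0.100 * rate), i_off - i_on)
    t_ms = np.arange(n_fit) / rate * 1000.0
    seg = v[i_on: i_on + n_fit]

    def _expfit(t, v0, dv, tau):
        return v0 + dv * (1.0 - np.exp(-t / tau))

    tau0 = max(abs(rm) * 20.0, 1.0)
    with warnings.catch_warnings():
        # flat traces (e.g. zero-amplitude steps) give a singular fit
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            _expfit, t_ms, seg,
            p0=(v_base, v_ss - v_base, tau0),
            maxfev=10000,
        )
    tau_m = abs(popt[2])
    cm = tau_m / abs(rm) if rm != 0 else float("nan")  # ms / GΩ = pF
    return PassiveProps(Vm_rest=vm_rest, spont_rate=spont, Rm=abs(rm),
                        Cm=cm, tau_m=tau_m)


def _fires(sweep: Sweep) -> bool:
    onset, dur = _step_geometry(sweep)
    return len(_spikes_in_window(sweep, onset, onset + dur)) >= 1


def find_rheobase(
    stim: Callable[[float], Sweep],
    coarse_step: float = 15.0,
    fine_step: float = 2.0,
    i_max: float = 500.0,
) -> RheobaseResult:
    """Two-stage rheobase search against a ``current -> Sweep`` source.

    A coarse ladder (10–20 pA increments, 1 s steps) finds the first
    firing step; a fine ladder (1–3 pA increments) starting a few pA
    below that estimate finds the first current that fires and keeps
    firing on the following two steps. A cell silent up to ``i_max`` is
    reported as not excitable rather than raising.
    """
    if not 10.0 <= coarse_step <= 20.0:
        raise ProtocolError("coarse_step must be 10–20 pA")
    if not 1.0 <= fine_step <= 3.0:
        raise ProtocolError("fine_step must be 1–3 pA")

    coarse_estimate = np.nan
    i = coarse_step
    while i <= i_max + 1e-9:
        if _fires(stim(i)):
            coarse_estimate = i
            break
        i += coarse_step
    if not np.isfinite(coarse_estimate):
        return RheobaseResult(np.nan, np.nan, fine_step, excitable=False)

    start = max(coarse_estimate - coarse_step + fine_step, fine_step)
    fired: dict[float, bool] = {}

    def fires_at(cur: float) -> bool:
        if cur not in fired:
            fired[cur] = _fires(stim(cur))
        return fired[cur]

    cur = start
    while cur <= coarse_estimate + coarse_step:
        if (fires_at(cur) and fires_at(cur + fine_step)
                and fires_at(cur + 2 * fine_step)):
            return RheobaseResult(coarse_estimate, cur, fine_step)
        cur += fine_step
    # fell through: the coarse step itself is the best estimate
    return RheobaseResult(coarse_estimate, coarse_estimate, fine_step)


def find_rheobase_from_batteries(
    coarse_sweeps: Sequence[Sweep],
    fine_sweeps: Sequence[Sweep],
) -> RheobaseResult:
    """Rheobase from recorded coarse/fine step batteries.

    Sweeps must carry their step amplitude in metadata. The fine-step
    rule requires the two following fine sweeps to fire as well.
    """
    def by_amp(sweeps):
        pairs = sorted(
            (float(s.meta["step_amplitude_pA"]), s) for s in sweeps
        )
        return [a for a, _ in pairs], [s for _, s in pairs]

    c_amps, c_sw = by_amp(coarse_sweeps)
    coarse_estimate = np.nan
    for a, s in zip(c_amps, c_sw):
        if _fires(s):
            coarse_estimate = a
            break
    if not np.isfinite(coarse_estimate):
        return RheobaseResult(np.nan, np.nan, np.nan, excitable=False)

    f_amps, f_sw = by_amp(fine_sweeps)
    fine_step = float(np.median(np.diff(f_amps))) if len(f_amps) > 1 else np.nan
    firing = [_fires(s) for s in f_sw]
    for i in range(len(f_sw)):
        tail = firing[i:i + 3]
        if len(tail) == 3 and all(tail):
            return RheobaseResult(coarse_estimate, f_amps[i], fine_step)
        if len(tail) < 3 and all(tail) and firing[i]:
            # battery ends while still firing: accept first firing step
            return RheobaseResult(coarse_estimate, f_amps[i], fine_step)
    return RheobaseResult(coarse_estimate, coarse_estimate, fine_step)


def _battery_evidence(step_battery: Sequence[Sweep]) -> list[StepEvidence]:
    if len(step_battery) != 10:
        raise ProtocolError(
            f"firing-type battery must have 10 sweeps, got {len(step_battery)}"
        )
    evidence = []
    for sw in step_battery:
        if sw.mode != CURRENT_CLAMP:
            raise ProtocolError("firing-type battery must be current clamp")
        onset, dur = _step_geometry(sw)
        spikes = _spikes_in_window(sw, onset, onset + dur)
        amps = np.array([s.amplitude for s in spikes])
        n = len(spikes)
        first = amps[0] if n else np.nan
        last3 = float(np.mean(amps[-3:])) if n >= 3 else np.nan
        mean_amp = float(np.mean(amps)) if n else np.nan

        rate = sw.sampling_rate
        seg = lambda t0, t1: sw.response[round(t0 * rate): round(t1 * rate)]
        win = min(0.2, dur / 2)
        rise = float(np.min(seg(onset + dur - win, onset + dur))
                     - np.min(seg(onset, onset + win)))

        failure = False
        if n >= 2:
            isis = np.diff([s.time for s in spikes])
            remaining = onset + dur - spikes[-1].time
            failure = remaining > max(0.15 * dur, 4.0 * float(np.median(isis)))

        evidence.append(StepEvidence(
            current_pA=float(sw.meta.get("step_amplitude_pA", np.nan)),
            n_APs=n,
            first_amp=float(first),
            last3_mean=last3,
            mean_amp=mean_amp,
            baseline_rise_mV=rise,
            failure=failure,
        ))
    return evidence


def classify_firing_type(step_battery: Sequence[Sweep]) -> FiringTypeResult:
    """Label a ten-step (Δ+50 pA / 1 s) battery as T, F, S or U."""
    ev = _battery_evidence(step_battery)
    counts = [e.n_APs for e in ev]

    if all(c < 3 for c in counts):
        return FiringTypeResult("S", ev, non_excitable=(sum(counts) == 0))

    fade_idx = [i for i, e in enumerate(ev) if e.fade]
    fail_rise = [i for i, e in enumerate(ev)
                 if e.failure and e.baseline_rise_mV >= BASELINE_RISE_MV]

    confirmed_fade = any(
        ev[j].mean_reduction > ev[i].mean_reduction
        for i in fade_idx for j in range(i + 1, len(ev))
    )
    if confirmed_fade or fail_rise:
        return FiringTypeResult("F", ev)

    if not fade_idx and not any(e.failure for e in ev):
        # tonic candidate: spike count must not fall off at higher steps
        running_max = 0
        monotone = True
        for c in counts:
            if c < TONIC_COUNT_SLACK * running_max - 1:
                monotone = False
                break
            running_max = max(running_max, c)
        if monotone:
            return FiringTypeResult("T", ev)
    return FiringTypeResult("U", ev)


def build_fI_curve(step_battery: Sequence[Sweep]) -> list[tuple[float, int]]:
    """(injected current, spike count) for each step of the battery."""
    ev = _battery_evidence(step_battery)
    return [(e.current_pA, e.n_APs) for e in ev]
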
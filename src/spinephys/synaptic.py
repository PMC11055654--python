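"""Evoked-EPSC detection, stimulation thresholds, response taxonomy,
latency/jitter, and 20 Hz train statistics.

Event detection is derivative-free: the trace is lightly smoothed, a
baseline and noise floor are estimated from the pre-stimulus segment,
and inward peaks exceeding the detection floor (3× the baseline noise
SD, with an absolute minimum) are taken as events. Event latency is the
time the current first reaches 20% of the event's own peak, which makes
the onset estimate independent of event amplitude.

The response taxonomy follows the published four types plus
nonresponsive: Si (one event), Multi (2–4 discrete events peaking
within 10 ms of the stimulus), Ba (a barrage spanning beyond 10 ms,
within hundreds of ms), and Si+Ba (an early dominant event at least
twice the median amplitude of a later barrage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    VOLTAGE_CLAMP,
    InsufficientDataError,
    ModeError,
    Sweep,
)

ARTIFACT_BLANK_MS = 1.0       # stimulus-artifact blanking window
SEARCH_WINDOW_MS = 500.0      # events counted within (1, 500] ms
DETECTION_FLOOR_SD = 3.0      # multiples of baseline noise SD
MIN_EVENT_PA = 5.0            # absolute detection floor
SMOOTH_MS = 0.5               # boxcar smoothing before peak picking
MIN_EVENT_SEPARATION_MS = 2.0
EARLY_LATE_BOUNDARY_MS = 10.0  # Multi vs barrage boundary
SI_BA_DOMINANCE = 2.0         # early/late amplitude ratio for Si+Ba
MONO_JITTER_MS = {"electrical": 0.2, "optogenetic": 2.0}
MONO_MAX_FAILURE_PCT = 5.0
TRAIN_WINDOW_MS = 45.0        # per-stimulus detection window in trains


@dataclass
class EPSCEvent:
    """One detected evoked EPSC."""

    latency_ms: float      # onset latency from the stimulus
    amplitude_pA: float    # peak magnitude, baseline-subtracted
    rise_10_90_ms: float
    decay_tau_ms: float
    peak_time_s: float     # absolute time within the sweep


@dataclass
class EvokedResponse:
    stim_intensity: float | None
    events: list[EPSCEvent]
    type: str              # Si | Multi | Ba | Si+Ba | NR


@dataclass
class ThresholdResult:
    threshold_uA: float    # nan => nonresponsive up to the ladder maximum
    responsive: bool
    criterion: str
    ladder_uA: list[float] = field(default_factory=list)
    n_responses: dict = field(default_factory=dict)


@dataclass
class TrainResult:
    n_stimuli: int
    n_sweeps: int
    failure_pct: float
    depression_pct: float  # 100 × (A_first − A_last)/A_first
    first_amp_pA: float
    last_amp_pA: float


@dataclass
class JitterResult:
    mean_latency_ms: float
    jitter_ms: float       # sample SD of per-sweep first latencies
    n_sweeps: int
    connectivity_call: str  # mono | poly
    modality: str = "electrical"


def _smooth(x: np.ndarray, rate: float) -> np.ndarray:
    w = max(1, round(SMOOTH_MS / 1000.0 * rate))
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def detect_epscs(
    sweep: Sweep,
    stim_time_s: float,
    window_ms: float = SEARCH_WINDOW_MS,
    floor_sd: float = DETECTION_FLOOR_SD,
    min_amp_pA: float = MIN_EVENT_PA,
) -> list[EPSCEvent]:
    """Detect inward EPSC events following one stimulus.

    The first 1 ms after the stimulus is blanked (artifact window);
    events are accepted within (1, ``window_ms``] ms. Amplitudes are
    measured from a local pre-event baseline on the raw trace.
    """
    if sweep.mode != VOLTAGE_CLAMP:
        raise ModeError("EPSC detection requires a voltage-clamp sweep")
    from scipy.signal import find_peaks

    rate = sweep.sampling_rate
    i_stim = round(stim_time_s * rate)
    i0 = i_stim + round(ARTIFACT_BLANK_MS / 1000.0 * rate)
    i1 = min(sweep.n_samples, i_stim + round(window_ms / 1000.0 * rate))
    if i1 <= i0:
        return []

    raw = sweep.response
    # baseline and noise from the pre-stimulus segment (>= 5 ms)
    b0 = max(0, i_stim - round(0.020 * rate))
    base_seg = raw[b0:i_stim]
    if base_seg.size < round(0.005 * rate):
        base_seg = raw[: max(round(0.005 * rate), 2)]
    baseline = float(np.median(base_seg))
    # noise floor from the raw pre-stimulus segment: smoothing lowers the
    # noise but barely attenuates EPSC peaks, so a raw-SD floor applied
    # to the smoothed trace keeps false positives negligible
    noise_sd = 1.4826 * float(np.median(np.abs(base_seg - baseline))) \
        if i_stim - b0 >= 10 else 0.0
    floor = max(floor_sd * noise_sd, min_amp_pA)
    sm = _smooth(raw - baseline, rate)

    seg = -sm[i0:i1]  # inward events become positive
    dist = max(1, round(MIN_EVENT_SEPARATION_MS / 1000.0 * rate))
    peaks, props = find_peaks(seg, height=floor, distance=dist)

    events: list[EPSCEvent] = []
    for pk in peaks:
        ip = i0 + pk
        # rising-phase search window: far enough back to contain the
        # onset; local baseline estimated just before it
        lb1 = max(i0, ip - round(0.005 * rate))
        lb0 = max(b0, lb1 - round(0.0025 * rate))
        if lb0 >= lb1:
            lb0 = max(0, lb1 - 5)
        local_base = float(np.median(raw[lb0:lb1]))
        # refine the peak on the raw trace (±0.5 ms)
        r0 = max(i0, ip - round(0.0005 * rate))
        r1 = min(i1, ip + round(0.0005 * rate) + 1)
        ipk = r0 + int(np.argmin(raw[r0:r1]))
        amp = local_base - float(raw[ipk])
        if amp < floor:
            continue

        # onset: first 20% crossing of the event's own peak, interpolated
        mag = local_base - raw[lb1:ipk + 1]
        thr = 0.2 * amp
        above = np.flatnonzero(mag >= thr)
        if above.size == 0:
            onset_idx = float(ipk)
        else:
            j = int(above[0])
            if j == 0:
                onset_idx = float(lb1)
            else:
                y0, y1 = mag[j - 1], mag[j]
                fr = (thr - y0) / (y1 - y0) if y1 > y0 else 0.0
                onset_idx = lb1 + j - 1 + fr
        latency_ms = (onset_idx / rate - stim_time_s) * 1000.0
        if latency_ms <= ARTIFACT_BLANK_MS:
            continue

        # 10–90% rise time on the rising phase
        def _cross(frac):
            t = frac * amp
            idx = np.flatnonzero(mag >= t)
            if idx.size == 0:
                return float(ipk)
            j = int(idx[0])
            if j == 0:
                return float(lb1)
            y0, y1 = mag[j - 1], mag[j]
            fr = (t - y0) / (y1 - y0) if y1 > y0 else 0.0
            return lb1 + j - 1 + fr

        rise = (_cross(0.9) - _cross(0.1)) / rate * 1000.0

        # decay: time to fall to 1/e of the peak
        tail = local_base - raw[ipk:min(i1, ipk + round(0.050 * rate))]
        under = np.flatnonzero(tail <= amp / np.e)
        decay = (float(under[0]) / rate * 1000.0) if under.size else np.nan

        events.append(EPSCEvent(
            latency_ms=float(latency_ms),
            amplitude_pA=float(amp),
            rise_10_90_ms=float(rise),
            decay_tau_ms=float(decay),
            peak_time_s=float(ipk / rate),
        ))
    events.sort(key=lambda e: e.latency_ms)
    return events


def classify_evoked_response(events: Sequence[EPSCEvent]) -> str:
    """Assign the evoked-response type: Si, Multi, Ba, Si+Ba or NR.

    The decision tree is total and mutually exclusive over any finite
    event list: no events is NR; one event is Si; 2–4 events all
    peaking within 10 ms of the stimulus are Multi; one early event at
    least twice the median amplitude of >= 3 later events is Si+Ba;
    everything else with activity beyond 10 ms (or >= 5 early events —
    a dense volley) is Ba.
    """
    n = len(events)
    if n == 0:
        return "NR"
    if n == 1:
        return "Si"
    lat = np.array([e.latency_ms for e in events])
    amp = np.array([e.amplitude_pA for e in events])
    early = lat <= EARLY_LATE_BOUNDARY_MS
    if early.all():
        return "Multi" if n <= 4 else "Ba"
    n_late = int((~early).sum())
    if int(early.sum()) == 1 and n_late >= 3:
        if amp[early][0] >= SI_BA_DOMINANCE * float(np.median(amp[~early])):
            return "Si+Ba"
    return "Ba"


def determine_stim_threshold(
    responses: dict[float, Sequence[Sweep]],
    stim_time_s: float | None = None,
    max_intensity_uA: float = 5000.0,
) -> ThresholdResult:
    """Stimulation threshold by the 3-of-5 rule.

    ``responses`` maps stimulation intensity (µA) to the sweeps recorded
    at that intensity (nominally five). The threshold is the lowest
    tested intensity at which at least three of five attempts evoked a
    detectable response; a cell silent up to the ladder maximum is
    nonresponsive. With fewer than five sweeps a proportional criterion
    (>= 60%) is applied, with a warning.
    """
    ladder = sorted(responses)
    n_resp: dict[float, int] = {}
    threshold = np.nan
    for inten in ladder:
        sweeps = responses[inten]
        if len(sweeps) < 5:
            warnings.warn(
                f"{len(sweeps)} sweeps at {inten} µA; "
                "applying proportional 3-of-5 criterion",
                stacklevel=2,
            )
        hits = 0
        for sw in sweeps:
            t = stim_time_s
            if t is None:
                if not sw.t0_events:
                    raise InsufficientDataError("sweep lacks a stimulus event")
                t = sw.t0_events[0].time_s
            if detect_epscs(sw, t):
                hits += 1
        n_resp[inten] = hits
        if np.isnan(threshold) and hits / len(sweeps) >= 3.0 / 5.0:
            threshold = float(inten)
    return ThresholdResult(
        threshold_uA=threshold,
        responsive=bool(np.isfinite(threshold)),
        criterion=">=3 of 5 attempts with a response",
        ladder_uA=[float(x) for x in ladder],
        n_responses=n_resp,
    )


def compute_latency_jitter(
    sweeps: Sequence[Sweep],
    stim_time_s: float | None = None,
    modality: str = "electrical",
) -> JitterResult:
    """Per-cell latency statistics over repeated evoked sweeps.

    The first-event latency is taken per sweep; the jitter is the
    sample SD of those latencies. The connectivity call is mono when
    the jitter is at or below the modality's threshold (0.2 ms
    electrical, 2 ms optogenetic — shutter mechanics dominate the
    optogenetic timing floor).
    """
    latencies = []
    for sw in sweeps:
        t = stim_time_s
        if t is None:
            if not sw.t0_events:
                raise InsufficientDataError("sweep lacks a stimulus event")
            t = sw.t0_events[0].time_s
        ev = detect_epscs(sw, t)
        if ev:
            latencies.append(ev[0].latency_ms)
    if len(latencies) < 4:
        raise InsufficientDataError(
            f"need >=4 sweeps with a first-event latency, got {len(latencies)}"
        )
    lat = np.asarray(latencies)
    jitter = float(np.std(lat, ddof=1))
    call = "mono" if jitter <= MONO_JITTER_MS[modality] else "poly"
    return JitterResult(
        mean_latency_ms=float(np.mean(lat)),
        jitter_ms=jitter,
        n_sweeps=len(lat),
        connectivity_call=call,
        modality=modality,
    )


def analyze_train(
    train_sweeps: Sequence[Sweep],
    stim_times_s: Sequence[float] | None = None,
) -> TrainResult:
    """Failure and depression statistics for 20 Hz stimulus trains.

    Each stimulus owns a 45 ms detection window (shorter if the next
    stimulus comes sooner); a stimulus with no detected event is a
    failure. Depression compares the mean first-stimulus amplitude with
    the mean last-stimulus amplitude across sweeps.
    """
    n_stim = None
    failures = 0
    total = 0
    firsts, lasts = [], []
    for sw in train_sweeps:
        stims = (list(stim_times_s) if stim_times_s is not None
                 else [ev.time_s for ev in sw.t0_events])
        if not stims:
            raise InsufficientDataError("train sweep lacks stimulus events")
        if n_stim is None:
            n_stim = len(stims)
        amps = []
        for k, t in enumerate(stims):
            gap_ms = ((stims[k + 1] - t) * 1000.0 if k + 1 < len(stims)
                      else TRAIN_WINDOW_MS)
            win = min(TRAIN_WINDOW_MS, gap_ms)
            ev = detect_epscs(sw, t, window_ms=win)
            total += 1
            if not ev:
                failures += 1
                amps.append(np.nan)
            else:
                amps.append(ev[0].amplitude_pA)
        if np.isfinite(amps[0]):
            firsts.append(amps[0])
        if np.isfinite(amps[-1]):
            lasts.append(amps[-1])

    a_first = float(np.mean(firsts)) if firsts else np.nan
    a_last = float(np.mean(lasts)) if lasts else np.nan
    depression = 100.0 * (a_first - a_last) / a_first if firsts and lasts else np.nan
    return TrainResult(
        n_stimuli=int(n_stim or 0),
        n_sweeps=len(train_sweeps),
        failure_pct=100.0 * failures / total if total else np.nan,
        depression_pct=depression,
        first_amp_pA=a_first,
        last_amp_pA=a_last,
    )


def call_connectivity(jitter: JitterResult,
                      train: TrainResult | None = None) -> str:
    """Mono- vs polysynaptic call from jitter and (optionally) failures.

    Mono requires jitter at or below the modality threshold and, when a
    train was recorded, a failure rate of at most 5%.
    """
    if jitter.jitter_ms > MONO_JITTER_MS[jitter.modality]:
        return "poly"
    if train is not None and train.failure_pct > MONO_MAX_FAILURE_PCT:
        return "poly"
    return "mono"
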
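"""I_h quantification, sag potentials, HCN-block statistics, rebound firing.

I_h is measured in voltage clamp as the difference between the
steady-state current at the end of a hyperpolarizing step and the
instantaneous current just after the capacitive settle — the
"instantaneous leak subtraction". This makes the estimator invariant to
any added constant conductance, because a pure leak contributes equally
to both windows.

Sag is measured in current clamp as Δ = V_ss − V_trough during a
hyperpolarizing step. When HCN channels are blocked the membrane keeps
hyperpolarizing instead of rebounding, so the drug-condition Δ becomes
negative and the relative sag change (Δ − Δ')/Δ exceeds 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    ProtocolError,
    SpinephysError,
    Sweep,
)
from .intrinsic import detect_spikes

# measurement windows (s)
INST_WINDOW = (0.005, 0.015)   # after step onset, post capacitive settle
SS_WINDOW = 0.100              # last part of the step (voltage clamp)
SAG_TROUGH_WINDOW = 0.150      # from onset, search for the trough
SAG_SS_WINDOW = 0.025          # last part of the step (current clamp)
REBOUND_WINDOW = 0.200         # after step offset
SAG_PRESENT_MV = 1.0           # Δ threshold for sag presence
HYPERPOL_DAMAGE_MV = -120.0    # flag troughs below this for small cells


@dataclass
class IhResult:
    """Leak-subtracted I_h per hyperpolarizing voltage step."""

    delta_mV: np.ndarray   # command step sizes (negative)
    i_inst: np.ndarray     # pA, instantaneous current after settle
    i_ss: np.ndarray       # pA, end-of-step current
    i_h: np.ndarray        # pA, i_ss − i_inst (inward negative)


@dataclass
class SagResult:
    delta_mV_steps: np.ndarray   # command step amplitudes (pA, negative)
    v_trough: np.ndarray         # mV
    v_ss: np.ndarray             # mV
    sag_delta: np.ndarray        # mV, V_ss − V_trough (signed)
    sag_present: bool
    damage_flags: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class BlockResult:
    ih_block_fraction: float           # 0–1 (values >1 clipped at 1.2, flagged)
    over_block: bool = False
    step_mV: float = float("nan")      # step at which the fraction was read


@dataclass
class ReboundResult:
    step_pA: np.ndarray           # step amplitudes
    trough_mV: np.ndarray         # step trough voltages
    n_rebound_APs: np.ndarray     # counts in the post-offset window
    rebound_threshold_mV: float   # most depolarized trough with >=1 rebound AP
    adp_area_mV_ms: float         # afterdepolarization area after 1st rebound AP


def _geometry(sweep: Sweep) -> tuple[float, float, float]:
    onset = sweep.meta.get("step_onset_s")
    dur = sweep.meta.get("step_duration_s")
    if onset is None or dur is None:
        raise ProtocolError("sweep lacks step onset/duration metadata")
    return float(onset), float(dur), sweep.sampling_rate


def measure_ih(vc_sweeps: Sequence[Sweep]) -> IhResult:
    """Leak-subtracted I_h from a hyperpolarizing voltage-step battery.

    I_inst is the mean current over [onset+5 ms, onset+15 ms] (after the
    capacitive transient), I_ss the mean over the last 100 ms of the
    step; I_h = I_ss − I_inst, reported with sign (inward negative).
    """
    deltas, i_inst, i_ss = [], [], []
    for sw in vc_sweeps:
        if sw.mode != VOLTAGE_CLAMP:
            raise ProtocolError("I_h measurement requires voltage-clamp sweeps")
        onset, dur, rate = _geometry(sw)
        if dur < INST_WINDOW[1] + SS_WINDOW:
            raise ProtocolError(
                f"step of {dur * 1000:.0f} ms too short for the I_h windows"
            )
        i = sw.response
        a0 = round((onset + INST_WINDOW[0]) * rate)
        a1 = round((onset + INST_WINDOW[1]) * rate)
        b0 = round((onset + dur - SS_WINDOW) * rate)
        b1 = round((onset + dur) * rate)
        deltas.append(sw.meta.get("step_amplitude_mV", np.nan))
        i_inst.append(float(np.mean(i[a0:a1])))
        i_ss.append(float(np.mean(i[b0:b1])))

    order = np.argsort(deltas)[::-1]  # smallest |ΔV| first
    deltas = np.asarray(deltas)[order]
    i_inst = np.asarray(i_inst)[order]
    i_ss = np.asarray(i_ss)[order]
    return IhResult(deltas, i_inst, i_ss, i_ss - i_inst)


def measure_sag(cc_sweeps: Sequence[Sweep]) -> SagResult:
    """Sag potentials from hyperpolarizing current steps (200 ms).

    V_trough is the minimum over [onset, onset+150 ms], V_ss the mean of
    the last 25 ms of the step; Δ = V_ss − V_trough. Sag is present if
    Δ > 1 mV in at least two steps. Steps whose trough is below −120 mV
    are flagged (hyperpolarization-damage risk for small cells), never
    excluded.
    """
    amps, troughs, ss, deltas, flags = [], [], [], [], []
    for sw in cc_sweeps:
        if sw.mode != CURRENT_CLAMP:
            raise ProtocolError("sag measurement requires current-clamp sweeps")
        onset, dur, rate = _geometry(sw)
        if dur < SAG_SS_WINDOW * 2:
            raise ProtocolError("step too short for the sag windows")
        v = sw.response
        t0 = round(onset * rate)
        t1 = round((onset + min(SAG_TROUGH_WINDOW, dur)) * rate)
        b0 = round((onset + dur - SAG_SS_WINDOW) * rate)
        b1 = round((onset + dur) * rate)
        v_tr = float(np.min(v[t0:t1]))
        v_ss = float(np.mean(v[b0:b1]))
        amps.append(sw.meta.get("step_amplitude_pA", np.nan))
        troughs.append(v_tr)
        ss.append(v_ss)
        deltas.append(v_ss - v_tr)
        flags.append(v_tr < HYPERPOL_DAMAGE_MV)

    order = np.argsort(amps)[::-1]  # smallest |ΔI| first
    amps = np.asarray(amps)[order]
    deltas = np.asarray(deltas)[order]
    present = int(np.sum(deltas > SAG_PRESENT_MV)) >= 2
    return SagResult(
        delta_mV_steps=amps,
        v_trough=np.asarray(troughs)[order],
        v_ss=np.asarray(ss)[order],
        sag_delta=deltas,
        sag_present=present,
        damage_flags=np.asarray(flags)[order],
    )


def compute_block(control: IhResult, drug: IhResult,
                  min_control_pA: float = 10.0) -> BlockResult:
    """Fractional I_h block at the largest common voltage step.

    fraction = 1 − I_h(drug)/I_h(control); values above 1 (drug current
    overshooting zero) are clipped at 1.2 and flagged. A control I_h
    smaller than ``min_control_pA`` in magnitude is undefined.
    """
    common = np.intersect1d(control.delta_mV, drug.delta_mV)
    if common.size == 0:
        raise ProtocolError("no common voltage step between conditions")
    step = common[np.argmax(np.abs(common))]
    ih_c = float(control.i_h[control.delta_mV == step][0])
    ih_d = float(drug.i_h[drug.delta_mV == step][0])
    if abs(ih_c) < min_control_pA:
        raise SpinephysError(
            f"control I_h ({ih_c:.1f} pA) too small to define a block fraction"
        )
    frac = 1.0 - ih_d / ih_c
    over = frac > 1.0
    return BlockResult(float(np.clip(frac, 0.0, 1.2)), over_block=over,
                       step_mV=float(step))


def compute_sag_delta_change(control: SagResult, drug: SagResult,
                             step: float | None = None) -> float:
    """Relative sag change (%) between control and drug conditions.

    Computed as 100 × (Δ_ctrl − Δ_drug)/Δ_ctrl with the drug Δ signed:
    when the blocked trace keeps hyperpolarizing past the control trough
    timing, Δ_drug is negative and the change exceeds 100%. Scale
    invariant: multiplying both Δ by c > 0 leaves the result unchanged.
    """
    if step is None:
        common = np.intersect1d(control.delta_mV_steps, drug.delta_mV_steps)
        if common.size == 0:
            raise ProtocolError("no common step between conditions")
        step = float(common[np.argmax(np.abs(common))])
    d_c = float(control.sag_delta[control.delta_mV_steps == step][0])
    d_d = float(drug.sag_delta[drug.delta_mV_steps == step][0])
    if d_c <= 0:
        raise SpinephysError("control sag Δ must be positive")
    return 100.0 * (d_c - d_d) / d_c


def analyze_rebound(cc_sweeps: Sequence[Sweep]) -> ReboundResult:
    """Rebound firing after hyperpolarizing current steps.

    Rebound APs are counted in the 200 ms window after step offset. The
    rebound threshold is the most depolarized step trough that elicited
    at least one rebound AP. The afterdepolarization (ADP) area is the
    integral of (V − pre-step baseline) over 50 ms starting at the first
    rebound AP's fast repolarization (the downward threshold-voltage
    recrossing after its peak).
    """
    amps, troughs, counts = [], [], []
    adp_area = np.nan
    for sw in cc_sweeps:
        if sw.mode != CURRENT_CLAMP:
            raise ProtocolError("rebound analysis requires current-clamp sweeps")
        onset, dur, rate = _geometry(sw)
        off = onset + dur
        if sw.duration - off < REBOUND_WINDOW:
            raise ProtocolError("need >=200 ms of post-step recording")
        v = sw.response
        spikes = [s for s in detect_spikes(sw)
                  if off <= s.time < off + REBOUND_WINDOW]
        t0 = round(onset * rate)
        t1 = round((onset + dur) * rate)
        trough = float(np.min(v[t0:t1]))
        amps.append(sw.meta.get("step_amplitude_pA", np.nan))
        troughs.append(trough)
        counts.append(len(spikes))

        if spikes and np.isnan(adp_area):
            first = spikes[0]
            baseline = float(np.mean(v[max(0, t0 - round(0.05 * rate)):t0]))
            ip = round(first.time * rate)
            # find the fast repolarization: V falls back below threshold_V
            seg = v[ip:]
            pk = int(np.argmax(seg[: round(0.005 * rate)]))
            below = np.flatnonzero(seg[pk:] <= first.threshold_V)
            start = ip + pk + (int(below[0]) if below.size else 0)
            n50 = round(0.050 * rate)
            win = v[start: start + n50]
            adp_area = float(np.sum(win - baseline) / rate * 1000.0)  # mV·ms

    amps_a = np.asarray(amps)
    troughs_a = np.asarray(troughs)
    counts_a = np.asarray(counts)
    rebound_mask = counts_a >= 1
    threshold = float(np.max(troughs_a[rebound_mask])) if rebound_mask.any() else np.nan
    return ReboundResult(
        step_pA=amps_a,
        trough_mV=troughs_a,
        n_rebound_APs=counts_a,
        rebound_threshold_mV=threshold,
        adp_area_mV_ms=adp_area,
    )
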
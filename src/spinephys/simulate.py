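"""Single-compartment conductance simulator and synaptic-event generator.

All simulation output is sampled at the nominal acquisition rate
(10 kHz) after integrating on a finer grid. The voltages emitted are
already junction-corrected — the correction is a no-op for synthetic
data but remains exercised through the normal API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .archetypes import (
    ArchetypeParams,
    SynapseParams,
    apply_channel_block,  # re-exported
    default_synapse,
    group_stats,
    load_config,
    make_archetype,
)
from .core import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    CellRecording,
    IntegrationError,
    ProtocolError,
    ProtocolSpec,
    StimEvent,
    Sweep,
    ValidationError,
    standard_protocols,
)

__all__ = [
    "SimulationConfig",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "simulate_evoked_synaptic",
    "generate_population",
    "apply_channel_block",
    "step_response_fn",
    "depression_amplitudes",
    "SynapticEvent",
]


@dataclass
class SimulationConfig:
    """Integration settings.

    ``dt_ms`` must divide the output sample interval (0.1 ms at 10 kHz).
    With ``noise`` off every simulation is deterministic given the
    parameters, and bit-reproducible for a fixed seed otherwise.
    """

    dt_ms: float = 0.0125
    output_rate_Hz: float = 10_000.0
    seed: int = 0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.dt_ms <= 0 or self.dt_ms > 0.05:
            raise ValidationError("dt_ms must be in (0, 0.05] ms")
        out_dt = 1000.0 / self.output_rate_Hz
        decim = out_dt / self.dt_ms
        if abs(decim - round(decim)) > 1e-9:
            raise ValidationError(
                f"dt={self.dt_ms} ms does not divide the output interval "
                f"{out_dt} ms"
            )

    @property
    def decim(self) -> int:
        return round(1000.0 / self.output_rate_Hz / self.dt_ms)


def _run_cc(params: ArchetypeParams, cmd_pA: np.ndarray, cfg: SimulationConfig,
            rng: np.random.Generator | None, v0_state=None):
    """Integrate one current-clamp sweep; returns (V, spike_times_s)."""
    p = params.to_array(with_noise=cfg.noise)
    decim = cfg.decim
    n_out = cmd_pA.size
    if cfg.noise:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        noise = rng.standard_normal(n_out * decim)
    else:
        noise = np.zeros(1)
        p[K.P_SIGI] = 0.0
    v0, h0, n0, s0, w0, r0 = v0_state if v0_state is not None else params.rest_state()
    v_out = np.empty(n_out)
    spk = np.empty(K._MAX_SPIKES)
    nspk, err = K.cc_kernel(p, cfg.dt_ms, decim, cmd_pA, noise,
                            v0, h0, n0, s0, w0, r0, v_out, spk)
    if err >= 0:
        raise IntegrationError(
            f"non-finite state at t = {err * cfg.dt_ms / 1000.0:.6f} s"
        )
    return v_out, spk[:min(nspk, K._MAX_SPIKES)] / 1000.0


def simulate_current_clamp(
    params: ArchetypeParams,
    protocol: ProtocolSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[Sweep]:
    """Run a current-clamp protocol on one model cell.

    Rest sweeps start from the cell's resting potential with zero
    command; stepped protocols hold the cell at the protocol holding
    potential with a bias current and add the step amplitude on top.
    Ground-truth spike times (s) are stored in each sweep's metadata.
    """
    if protocol.mode != CURRENT_CLAMP:
        raise ProtocolError(f"{protocol.kind} is not a current-clamp protocol")
    if rng is None and cfg.noise:
        rng = np.random.default_rng(cfg.seed)

    rate = cfg.output_rate_Hz
    n_out = round(protocol.sweep_duration * rate)
    sweeps: list[Sweep] = []
    amps = protocol.step_amplitudes or tuple([0.0] * protocol.n_sweeps)

    if protocol.kind == "rest":
        i_bias = 0.0
        v0_state = params.rest_state()
    else:
        i_bias = params.holding_current(protocol.holding_level)
        v0_state = params.state_at(protocol.holding_level)

    i0 = round(protocol.step_onset * rate)
    i1 = i0 + round(protocol.step_duration * rate)
    for sweep_idx in range(protocol.n_sweeps):
        cmd = np.full(n_out, i_bias)
        amp = amps[sweep_idx] if sweep_idx < len(amps) else 0.0
        if protocol.kind != "rest":
            cmd[i0:i1] += amp
        v, spikes = _run_cc(params, cmd, cfg, rng, v0_state)
        sweeps.append(Sweep(
            sampling_rate=rate,
            response=v,
            command=cmd,
            mode=CURRENT_CLAMP,
            t0_events=([] if protocol.kind == "rest"
                       else [StimEvent(protocol.step_onset, amp, "step")]),
            meta={
                "protocol": protocol.kind,
                "step_amplitude_pA": amp,
                "step_onset_s": protocol.step_onset,
                "step_duration_s": protocol.step_duration,
                "spike_times_s": spikes.tolist(),
                "junction_corrected": True,
                "archetype_kind": params.kind,
            },
        ))
    return sweeps


def simulate_voltage_clamp(
    params: ArchetypeParams,
    protocol: ProtocolSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[Sweep]:
    """Run a voltage-clamp step protocol (ideal clamp with fast settle)."""
    if protocol.mode != VOLTAGE_CLAMP or protocol.kind != "vc_hyperpol_steps":
        raise ProtocolError(f"{protocol.kind} is not a voltage-clamp step protocol")
    if rng is None and cfg.noise:
        rng = np.random.default_rng(cfg.seed)

    rate = cfg.output_rate_Hz
    n_out = round(protocol.sweep_duration * rate)
    i0 = round(protocol.step_onset * rate)
    i1 = i0 + round(protocol.step_duration * rate)
    hold = protocol.holding_level
    v0, h0, n0, s0, w0, r0 = params.state_at(hold)

    vc_noise = load_config()["noise"]["vc_sd_pA"] if cfg.noise else 0.0
    sweeps: list[Sweep] = []
    for amp in protocol.step_amplitudes:
        vcmd = np.full(n_out, hold)
        vcmd[i0:i1] += amp
        i_out = np.empty(n_out)
        p = params.to_array()
        err = K.vc_kernel(p, cfg.dt_ms, cfg.decim, vcmd,
                          v0, h0, n0, s0, w0, r0, i_out)
        if err >= 0:
            raise IntegrationError(
                f"non-finite state at t = {err * cfg.dt_ms / 1000.0:.6f} s"
            )
        if vc_noise > 0.0:
            i_out = i_out + rng.normal(0.0, vc_noise, size=n_out)
        sweeps.append(Sweep(
            sampling_rate=rate,
            response=i_out,
            command=vcmd,
            mode=VOLTAGE_CLAMP,
            t0_events=[StimEvent(protocol.step_onset, amp, "step")],
            meta={
                "protocol": protocol.kind,
                "step_amplitude_mV": amp,
                "step_onset_s": protocol.step_onset,
                "step_duration_s": protocol.step_duration,
                "junction_corrected": True,
                "archetype_kind": params.kind,
            },
        ))
    return sweeps


def step_response_fn(params: ArchetypeParams, cfg: SimulationConfig,
                     step_duration: float = 1.0, holding_mV: float = -70.0):
    """A ``current (pA) -> Sweep`` callable for rheobase searches.

    Each call simulates a single 1 s step from the holding potential.
    The returned sweeps are deterministic when cfg.noise is off;
    otherwise each call draws fresh membrane noise.
    """
    rng = np.random.default_rng(cfg.seed) if cfg.noise else None

    def respond(current_pA: float) -> Sweep:
        proto = ProtocolSpec(
            kind="rheobase_fine",
            holding_level=holding_mV,
            step_amplitudes=(float(current_pA),),
            step_duration=step_duration,
            n_sweeps=1,
            step_onset=0.1,
            sweep_duration=step_duration + 0.3,
        )
        return simulate_current_clamp(params, proto, cfg, rng)[0]

    return respond


# ---------------------------------------------------------------------------
# synaptic-event generation
# ---------------------------------------------------------------------------

@dataclass
class SynapticEvent:
    """Ground truth for one generated postsynaptic event."""

    stim_index: int          # -1 for barrage events not locked to release
    released: bool
    time_s: float            # event onset within the sweep
    latency_ms: float        # onset latency from its stimulus
    amplitude_pA: float      # peak amplitude (magnitude)


def depression_amplitudes(syn: SynapseParams, stim_times_s: np.ndarray) -> np.ndarray:
    """Per-stimulus amplitudes under the resource-depletion recursion.

    R_1 = 1 and R_{n+1} = 1 − (1 − R_n (1−U)) e^{−Δt/τ_rec}; the
    amplitude of response n is quantal_amp · R_n, so the first response
    is the full quantal amplitude.
    """
    n = len(stim_times_s)
    amps = np.empty(n)
    r = 1.0
    for i in range(n):
        amps[i] = syn.quantal_amp_pA * r
        if i + 1 < n:
            dt = stim_times_s[i + 1] - stim_times_s[i]
            rec = math.exp(-dt / syn.tau_rec_s)
            r = 1.0 - (1.0 - r * (1.0 - syn.depression_U)) * rec
    return amps


def _epsc_kernel_peak_norm(rise_ms: float, decay_ms: float) -> float:
    """Peak of exp(-t/τd) − exp(-t/τr) so amplitudes can be normalized."""
    tr, td = rise_ms, decay_ms
    tpk = tr * td / (td - tr) * math.log(td / tr)
    return math.exp(-tpk / td) - math.exp(-tpk / tr)


def simulate_evoked_synaptic(
    syn: SynapseParams,
    stim_times_s: list[float] | np.ndarray,
    cfg: SimulationConfig,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Sweep, list[SynapticEvent]]:
    """Generate a voltage-clamp sweep of evoked EPSCs with ground truth.

    The cell is held at −70 mV; the trace is the baseline-subtracted
    membrane current (pA, EPSCs inward/negative). Release is Bernoulli
    per stimulus; amplitudes follow the depression recursion; an
    optional barrage adds decaying-rate Poisson events in the
    (10, 500] ms post-stimulus window.
    """
    stim_times_s = np.asarray(stim_times_s, dtype=float)
    if stim_times_s.size == 0:
        raise ValidationError("at least one stimulus time required")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rate = cfg.output_rate_Hz
    if duration_s is None:
        duration_s = float(stim_times_s.max()) + 0.55
    if stim_times_s.max() >= duration_s:
        raise ValidationError("stimuli must fall within the sweep duration")
    n = round(duration_s * rate)
    trace = np.zeros(n)

    events: list[SynapticEvent] = []
    base_amps = depression_amplitudes(syn, stim_times_s)
    for i, t_stim in enumerate(stim_times_s):
        if syn.release_prob > 0.0 and rng.random() < syn.release_prob:
            lat = syn.latency_mean_ms + (syn.poly_offset_ms if syn.polysynaptic else 0.0)
            if cfg.noise or syn.polysynaptic:
                lat += syn.latency_sd_ms * rng.standard_normal()
            lat = max(lat, 0.3)
            amp = base_amps[i]
            if cfg.noise and syn.amp_cv > 0:
                # lognormal multiplicative variability, mean-preserving
                cv = syn.amp_cv
                amp *= math.exp(cv * rng.standard_normal() - 0.5 * cv * cv)
            events.append(SynapticEvent(i, True, t_stim + lat / 1000.0, lat, amp))
        elif syn.release_prob > 0.0:
            events.append(SynapticEvent(i, False, math.nan, math.nan, 0.0))

        if syn.barrage_n_mean > 0.0:
            n_ba = rng.poisson(syn.barrage_n_mean)
            for _ in range(n_ba):
                dt_ms = 10.0 + rng.exponential(syn.barrage_tau_ms)
                if dt_ms > 500.0:
                    continue
                amp = syn.barrage_amp_pA
                if cfg.noise and syn.amp_cv > 0:
                    cv = syn.amp_cv
                    amp *= math.exp(cv * rng.standard_normal() - 0.5 * cv * cv)
                events.append(SynapticEvent(-1, True, t_stim + dt_ms / 1000.0,
                                            dt_ms, amp))

    norm = _epsc_kernel_peak_norm(syn.rise_ms, syn.decay_ms)
    win = round((8.0 * syn.decay_ms / 1000.0) * rate)
    t_axis = np.arange(win) / rate * 1000.0  # ms
    for ev in events:
        if not ev.released or ev.time_s >= duration_s:
            continue
        i0 = int(ev.time_s * rate) + 1  # first sample at/after onset
        tt = t_axis[: n - i0] + (i0 / rate - ev.time_s) * 1000.0
        kern = (np.exp(-tt / syn.decay_ms) - np.exp(-tt / syn.rise_ms)) / norm
        trace[i0:i0 + kern.size] -= ev.amplitude_pA * kern

    if cfg.noise and syn.noise_sd_pA > 0:
        trace = trace + rng.normal(0.0, syn.noise_sd_pA, size=n)

    kind = "light" if syn.stim_modality == "optogenetic" else "electrical"
    sweep = Sweep(
        sampling_rate=rate,
        response=trace,
        command=np.full(n, -70.0),
        mode=VOLTAGE_CLAMP,
        t0_events=[StimEvent(float(t), None if kind == "light" else 0.0, kind)
                   for t in stim_times_s],
        meta={"protocol": "evoked", "junction_corrected": True},
    )
    return sweep, events


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def _draw(stat: dict, rng: np.random.Generator) -> float:
    """Draw from a configured marginal, truncated at 2 SD (log-SD for
    lognormal) to keep cells in the model's physiological regime."""
    mean, sd = stat["mean"], stat["sd"]
    if sd == 0:
        return mean
    if stat.get("dist", "normal") == "lognormal":
        cv = sd / abs(mean)
        sig = math.sqrt(math.log(1.0 + cv * cv))
        mu = math.log(abs(mean)) - 0.5 * sig * sig
        z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
        return math.copysign(math.exp(mu + sig * z), mean)
    z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    return mean + sd * z


DEFAULT_PROTOCOLS = ("rest", "firing_steps", "vc_hyperpol_steps", "cc_hyperpol_steps")


def generate_population(
    group: str,
    n: int,
    seed: int,
    protocols: tuple[str, ...] = DEFAULT_PROTOCOLS,
    noise: bool = True,
    dt_ms: float = 0.0125,
    config: dict | None = None,
) -> list[CellRecording]:
    """Simulate ``n`` cells of one group with the full protocol battery.

    Each cell draws its passive properties and firing archetype from the
    group's documented distributions and mixture; spike conductances
    scale with capacitance so firing dynamics are preserved across cell
    sizes. The archetype label and drawn parameters are stored in each
    recording's metadata as ground truth.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    cfg_data = config or load_config()
    g = group_stats(group, cfg_data)
    mixture = g["mixture"]
    kinds = list(mixture)
    probs = np.array([mixture[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()

    child_seeds = np.random.SeedSequence(seed).spawn(n)
    protos = standard_protocols(n_cc_hyperpol=g.get("n_cc_hyperpol_steps", 10))

    cells: list[CellRecording] = []
    for i, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        kind = kinds[rng.choice(len(kinds), p=probs)]
        cm = max(_draw(g["passive"]["Cm_pF"], rng), 2.0)
        rm = _draw(g["passive"]["Rm_GOhm"], rng)
        vrest = _draw(g["passive"]["Vrest_mV"], rng)
        params = make_archetype(group, kind, Cm_pF=cm, Rm_GOhm=rm,
                                V_rest_mV=vrest, config=cfg_data)
        cfg = SimulationConfig(dt_ms=dt_ms, seed=int(ss.generate_state(1)[0] >> 1),
                               noise=noise)
        sweep_sets = {}
        used_protos = {}
        for kindname in protocols:
            proto = protos[kindname]
            if proto.mode == VOLTAGE_CLAMP:
                sweep_sets[kindname] = simulate_voltage_clamp(params, proto, cfg, rng)
            else:
                sweep_sets[kindname] = simulate_current_clamp(params, proto, cfg, rng)
            used_protos[kindname] = proto
        cells.append(CellRecording(
            cell_id=f"{group}_{i:04d}",
            group=group,
            sweep_sets=sweep_sets,
            protocols=used_protos,
            meta={
                "truth": {
                    "archetype": kind,
                    "Cm_pF": cm,
                    "Rm_GOhm": rm,
                    "Vrest_mV": vrest,
                    "g_h_nS": params.g_h_nS,
                    "seed": int(ss.generate_state(1)[0]),
                },
            },
        ))
    return cells
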
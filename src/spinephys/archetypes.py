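"""Archetype and synapse parameter sets.

An :class:`ArchetypeParams` fully defines one simulated cell: passive
membrane (Cm, leak), spike currents (Na/K with a slow Na-inactivation
variable that produces fading/single firing through depolarization
block), a low-threshold K conductance that sets rheobase above the bare
leak prediction, and a first-order HCN gate carrying I_h.

Default parameter sets for the three cell groups (Clarke's column,
Atoh1-lineage medial and lateral) and their synaptic inputs live in a
versioned config file, ``data/archetypes.yaml``. Calibration targets are
the published group statistics (capacitance, input resistance, resting
potential, rheobase, firing-type mixtures, I_h amplitudes, evoked-EPSC
latency/jitter/failure/depression values).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import _kernels as K
from .core import ValidationError


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ArchetypeParams:
    """Conductance-model parameter set for one simulated cell.

    Conductances in nS, capacitance in pF, voltages in mV, time
    constants in ms. ``kind`` labels the firing archetype (T/F/S/U)
    used as ground truth when classifying simulated cells.
    """

    Cm_pF: float
    g_leak_nS: float
    V_rest_mV: float
    g_Na_nS: float
    g_K_nS: float
    g_KLT_nS: float = 0.0
    g_h_nS: float = 0.0
    E_Na_mV: float = 55.0
    E_K_mV: float = -90.0
    E_h_mV: float = -40.0
    E_leak_mV: float | None = None  # solved from V_rest if None
    na_shift_mV: float = 12.0
    k_shift_mV: float = 12.0
    k_tau_scale: float = 1.0  # >1 slows delayed-rectifier kinetics
    klt_Vhalf_mV: float = -47.0
    klt_k_mV: float = 5.0
    klt_tau_ms: float = 15.0
    hcn_Vhalf_mV: float = -100.0
    hcn_k_mV: float = 10.0
    hcn_tau0_ms: float = 40.0
    hcn_tau_amp_ms: float = 600.0
    hcn_tau_Vhalf_mV: float = -120.0
    hcn_tau_k_mV: float = 20.0
    slow_depth: float = 0.0
    slow_Vhalf_mV: float = -48.0
    slow_k_mV: float = 6.0
    slow_tau_ms: float = 500.0
    noise_sigma_mV: float = 0.4
    clamp_tau_ms: float = 0.2
    kind: str = "T"

    def __post_init__(self) -> None:
        if self.Cm_pF <= 0:
            raise ValidationError("Cm must be positive")
        for name in ("g_leak_nS", "g_Na_nS", "g_K_nS", "g_KLT_nS", "g_h_nS"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.slow_depth <= 1.0:
            raise ValidationError("slow_depth must be in [0, 1]")
        if self.E_leak_mV is None:
            self.E_leak_mV = self._solve_E_leak()

    # -- derived quantities -------------------------------------------------

    def _steady_gates(self, v: float):
        p = self.to_array()
        return K.steady_gates(v, p)

    def _solve_E_leak(self) -> float:
        """Reversal of the leak chosen so V_rest is a fixed point."""
        v = self.V_rest_mV
        # ionic currents at rest with steady gates, excluding leak
        p = self._array_with_EL(0.0)
        h, n, s, w, r = K.steady_gates(v, p)
        i_other = K.ionic_current(v, h, n, s, w, r, p) - p[K.P_GL] * (v - 0.0)
        return v + i_other / self.g_leak_nS

    def _array_with_EL(self, el: float) -> np.ndarray:
        p = self.to_array()
        p[K.P_EL] = el
        return p

    def rest_state(self) -> tuple[float, float, float, float, float, float]:
        """(V, h, n, s, w, r) steady state at the resting potential."""
        v = self.V_rest_mV
        h, n, s, w, r = self._steady_gates(v)
        return v, h, n, s, w, r

    def state_at(self, v: float) -> tuple[float, float, float, float, float, float]:
        h, n, s, w, r = self._steady_gates(v)
        return v, h, n, s, w, r

    def holding_current(self, v_hold: float) -> float:
        """Bias current (pA) that makes ``v_hold`` a steady state."""
        vh, h, n, s, w, r = self.state_at(v_hold)
        return K.ionic_current(v_hold, h, n, s, w, r, self.to_array())

    def noise_current_amplitude(self) -> float:
        """White-current amplitude (pA·ms^1/2) giving the target V-noise SD.

        For an OU voltage process with relaxation g/C the stationary SD
        is sigma_I / sqrt(2 C g); g is evaluated at rest.
        """
        v, h, n, s, w, r = self.rest_state()
        # Na conductance at rest is negligible; use the other conductances
        g_rest = (self.g_leak_nS + self.g_K_nS * n ** 4
                  + self.g_KLT_nS * w + self.g_h_nS * r)
        return self.noise_sigma_mV * np.sqrt(2.0 * self.Cm_pF * g_rest)

    def to_array(self, with_noise: bool = False) -> np.ndarray:
        p = np.zeros(K.NPARAMS)
        p[K.P_CM] = self.Cm_pF
        p[K.P_GL] = self.g_leak_nS
        p[K.P_EL] = self.E_leak_mV if self.E_leak_mV is not None else 0.0
        p[K.P_GNA] = self.g_Na_nS
        p[K.P_ENA] = self.E_Na_mV
        p[K.P_GK] = self.g_K_nS
        p[K.P_EK] = self.E_K_mV
        p[K.P_SHNA] = self.na_shift_mV
        p[K.P_SHK] = self.k_shift_mV
        p[K.P_GKLT] = self.g_KLT_nS
        p[K.P_VW] = self.klt_Vhalf_mV
        p[K.P_KW] = self.klt_k_mV
        p[K.P_TAUW] = self.klt_tau_ms
        p[K.P_GH] = self.g_h_nS
        p[K.P_EH] = self.E_h_mV
        p[K.P_VR] = self.hcn_Vhalf_mV
        p[K.P_KR] = self.hcn_k_mV
        p[K.P_TR0] = self.hcn_tau0_ms
        p[K.P_TRAMP] = self.hcn_tau_amp_ms
        p[K.P_TRVH] = self.hcn_tau_Vhalf_mV
        p[K.P_TRK] = self.hcn_tau_k_mV
        p[K.P_DEPTH] = self.slow_depth
        p[K.P_VS] = self.slow_Vhalf_mV
        p[K.P_KS] = self.slow_k_mV
        p[K.P_TAUS] = self.slow_tau_ms
        p[K.P_SIGI] = self.noise_current_amplitude() if with_noise else 0.0
        p[K.P_TAUC] = self.clamp_tau_ms
        p[K.P_TAUN_SCALE] = self.k_tau_scale
        return p

    @property
    def Rm_GOhm(self) -> float:
        return 1.0 / self.g_leak_nS


@dataclass
class SynapseParams:
    """Evoked synaptic input model.

    Release is Bernoulli per stimulus with probability ``release_prob``;
    amplitudes follow a presynaptic resource-depletion model
    (R_{n+1} = 1 − (1 − R_n (1−U)) e^{−Δt/τ_rec}, amplitude ∝ R_n,
    normalized so the first response equals ``quantal_amp_pA``).
    Latencies are Gaussian with SD ``latency_sd_ms`` (the jitter);
    the polysynaptic flag adds a latency offset and implies large
    jitter. A barrage adds Poisson events over a post-stimulus window
    with exponentially decaying rate.
    """

    latency_mean_ms: float = 5.6
    latency_sd_ms: float = 0.13
    release_prob: float = 0.991
    quantal_amp_pA: float = 415.0
    rise_ms: float = 0.5
    decay_ms: float = 6.0
    depression_U: float = 0.5
    tau_rec_s: float = 0.247
    amp_cv: float = 0.2
    barrage_n_mean: float = 0.0
    barrage_tau_ms: float = 150.0
    barrage_amp_pA: float = 60.0
    polysynaptic: bool = False
    poly_offset_ms: float = 6.0
    noise_sd_pA: float = 4.0
    stim_modality: str = "electrical"  # "electrical" | "optogenetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.release_prob <= 1.0:
            raise ValidationError("release_prob must be in [0, 1]")
        if not 0.0 < self.depression_U <= 1.0:
            raise ValidationError("depression utilization U must be in (0, 1]")
        if self.latency_sd_ms < 0:
            raise ValidationError("jitter must be >= 0")


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

_CONFIG_CACHE: dict | None = None


def load_config() -> dict:
    """The versioned default archetype/synapse configuration."""
    global _CONFIG_CACHE
    if _CONFIG_CACHE is None:
        ref = importlib.resources.files("spinephys.data") / "archetypes.yaml"
        _CONFIG_CACHE = yaml.safe_load(ref.read_text())
    return _CONFIG_CACHE


def group_stats(group: str, config: dict | None = None) -> dict:
    cfg = config or load_config()
    try:
        return cfg["groups"][group]
    except KeyError:
        raise ValidationError(f"unknown group {group!r}") from None


def make_archetype(
    group: str,
    kind: str | None = None,
    Cm_pF: float | None = None,
    Rm_GOhm: float | None = None,
    V_rest_mV: float | None = None,
    config: dict | None = None,
) -> ArchetypeParams:
    """Build an :class:`ArchetypeParams` from the group defaults.

    With no overrides this returns the group's default archetype: group
    mean passive properties and the group's modal firing kind (tonic for
    Clarke's column, fading for medial/lateral).
    """
    cfg = config or load_config()
    g = group_stats(group, cfg)
    kind = kind or g["default_kind"]
    try:
        kd = dict(cfg["archetype_kinds"][kind])
    except KeyError:
        raise ValidationError(f"unknown archetype kind {kind!r}") from None
    # groups may refine a kind's dynamics (firing kinetics differ between
    # cell types even within one firing class) and their K complement
    kd.update(g.get("kind_overrides", {}).get(kind, {}))
    k_shift = g.get("k_shift_mV", cfg["shifts"]["k_shift_mV"])

    cm = Cm_pF if Cm_pF is not None else g["passive"]["Cm_pF"]["mean"]
    rm = Rm_GOhm if Rm_GOhm is not None else g["passive"]["Rm_GOhm"]["mean"]
    vrest = V_rest_mV if V_rest_mV is not None else g["passive"]["Vrest_mV"]["mean"]
    dens = cfg["densities"]
    hcn = cfg["hcn"]
    klt = cfg["klt"]

    return ArchetypeParams(
        Cm_pF=cm,
        g_leak_nS=1.0 / rm,
        V_rest_mV=vrest,
        g_Na_nS=dens["g_Na_nS_per_pF"] * cm * kd.get("g_Na_scale", 1.0),
        g_K_nS=dens["g_K_nS_per_pF"] * cm * kd.get("g_K_scale", 1.0),
        g_KLT_nS=g["g_KLT_nS"] * kd.get("g_KLT_scale", 1.0),
        g_h_nS=g["g_h_nS"],
        na_shift_mV=cfg["shifts"]["na_shift_mV"],
        k_shift_mV=k_shift,
        k_tau_scale=kd.get("k_tau_scale", g.get("k_tau_scale", 1.0)),
        klt_Vhalf_mV=g.get("klt_Vhalf_mV", klt["Vhalf_mV"]),
        klt_k_mV=g.get("klt_k_mV", klt["k_mV"]),
        klt_tau_ms=g.get("klt_tau_ms", klt["tau_ms"]),
        hcn_Vhalf_mV=hcn["Vhalf_mV"],
        hcn_k_mV=hcn["k_mV"],
        hcn_tau0_ms=hcn["tau0_ms"],
        hcn_tau_amp_ms=hcn["tau_amp_ms"],
        hcn_tau_Vhalf_mV=hcn["tau_Vhalf_mV"],
        hcn_tau_k_mV=hcn["tau_k_mV"],
        E_h_mV=hcn["E_h_mV"],
        slow_depth=kd["slow_depth"],
        slow_tau_ms=kd["slow_tau_ms"],
        slow_Vhalf_mV=kd.get("slow_Vhalf_mV", -48.0),
        slow_k_mV=kd.get("slow_k_mV", 6.0),
        noise_sigma_mV=cfg["noise"]["cc_sigma_mV"],
        kind=kind,
    )


def default_synapse(preset: str, config: dict | None = None) -> SynapseParams:
    """A named synaptic-input preset from the default configuration."""
    cfg = config or load_config()
    try:
        kw = dict(cfg["synapses"][preset])
    except KeyError:
        raise ValidationError(f"unknown synapse preset {preset!r}") from None
    return SynapseParams(**kw)


def apply_channel_block(
    params: ArchetypeParams, target: str = "Ih", fraction: float = 1.0
) -> ArchetypeParams:
    """Pharmacological channel block: scale a conductance by (1 − fraction).

    ``fraction`` = 1 is a complete block (ZD-7288 applied to HCN gives
    a near-complete block in most cells); 0 is the identity.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("block fraction must be in [0, 1]")
    if target != "Ih":
        raise ValidationError(f"unknown block target {target!r}")
    # E_leak is kept as solved for the pre-drug cell: blocking HCN shifts
    # the true resting potential, as it does experimentally.
    return replace(params, g_h_nS=params.g_h_nS * (1.0 - fraction))
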
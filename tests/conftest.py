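import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spinephys as sp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg_off():
    """Noise-free simulation settings (deterministic)."""
    return sp.SimulationConfig(noise=False)


@pytest.fixture(scope="session")
def protocols():
    return sp.standard_protocols()


@pytest.fixture(scope="session")
def passive_cc_params():
    """A purely passive cell with Clarke's-column passive values."""
    return sp.ArchetypeParams(
        Cm_pF=138.1, g_leak_nS=1.0 / 0.41, V_rest_mV=-58.91,
        g_Na_nS=0.0, g_K_nS=0.0, g_KLT_nS=0.0, g_h_nS=0.0,
        noise_sigma_mV=0.0,
    )


@pytest.fixture(scope="session")
def cc_params():
    return sp.make_archetype("CC")


@pytest.fixture(scope="session")
def cc_firing_battery(cc_params, protocols, cfg_off):
    return sp.simulate_current_clamp(cc_params, protocols["firing_steps"], cfg_off)


@pytest.fixture(scope="session")
def cc_hyperpol_sweeps(cc_params, protocols, cfg_off):
    return sp.simulate_current_clamp(cc_params, protocols["cc_hyperpol_steps"], cfg_off)


@pytest.fixture(scope="session")
def cc_vc_sweeps(cc_params, protocols, cfg_off):
    return sp.simulate_voltage_clamp(cc_params, protocols["vc_hyperpol_steps"], cfg_off)


def make_spike_train_sweep(spike_times_s, duration_s=1.4, rate=10_000.0,
                           base_mV=-70.0, peak_mV=25.0, onset_s=0.1,
                           step_pA=100.0, step_dur_s=1.0, amp_decline=None):
    """Synthesize a current-clamp sweep with template APs at given times.

    Each AP is a 1.8 ms triangular spike rising from baseline to
    ``peak_mV`` and back; fast enough to trip a dV/dt detector at 10 kHz.
    ``amp_decline`` optionally maps spike index -> peak (mV) to model
    amplitude fading.
    """
    n = round(duration_s * rate)
    v = np.full(n, base_mV)
    cmd = np.zeros(n)
    i0, i1 = round(onset_s * rate), round((onset_s + step_dur_s) * rate)
    cmd[i0:i1] = step_pA
    for k, t in enumerate(spike_times_s):
        i = round(t * rate)
        pk = peak_mV if amp_decline is None else amp_decline(k)
        up = np.linspace(base_mV, pk, 8)
        down = np.linspace(pk, base_mV, 11)[1:]
        seg = np.concatenate([up, down])
        end = min(n, i + seg.size)
        v[i:end] = np.maximum(v[i:end], seg[: end - i])
    return sp.Sweep(
        sampling_rate=rate, response=v, command=cmd, mode="cc",
        t0_events=[sp.StimEvent(onset_s, step_pA, "step")],
        meta={"step_onset_s": onset_s, "step_duration_s": step_dur_s,
              "step_amplitude_pA": step_pA},
    )
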
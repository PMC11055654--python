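"""Spike detection, passive properties, rheobase, firing-type rules."""

import numpy as np
import pytest

import spinephys as sp
from spinephys.intrinsic import detect_spikes, find_rheobase_from_batteries

from conftest import make_spike_train_sweep


class TestDetectSpikes:
    def test_flat_trace_yields_no_events(self):
        sw = sp.Sweep(10_000.0, np.full(10_000, -70.0), np.zeros(10_000), "cc")
        assert detect_spikes(sw) == []

    def test_voltage_clamp_sweep_rejected(self):
        sw = sp.Sweep(10_000.0, np.zeros(100), np.zeros(100), "vc")
        with pytest.raises(sp.ModeError):
            detect_spikes(sw)

    def test_close_doublet_not_merged(self):
        sw = make_spike_train_sweep([0.200, 0.202])
        events = detect_spikes(sw)
        assert len(events) == 2
        assert events[1].time - events[0].time == pytest.approx(0.002, abs=3e-4)

    def test_detected_times_match_simulator_ground_truth(self, cc_params,
                                                         cfg_off):
        proto = sp.ProtocolSpec(
            kind="firing_steps", holding_level=-70.0,
            step_amplitudes=tuple(50.0 * k for k in range(1, 11)),
            step_duration=1.0, n_sweeps=10, step_onset=0.1, sweep_duration=1.4)
        sw = sp.simulate_current_clamp(cc_params, proto, cfg_off)[4]  # 250 pA
        truth = np.asarray(sw.meta["spike_times_s"])
        det = np.asarray([e.time for e in detect_spikes(sw)])
        assert det.size == truth.size
        # the detector marks the threshold crossing, the ground truth the
        # 0 mV upstroke: a consistent sub-ms upstroke delay apart
        offsets = truth - det
        assert np.all(offsets > 0)
        assert np.all(offsets < 1e-3)
        assert np.std(offsets) < 1e-4

    def test_amplitude_is_peak_minus_threshold(self):
        sw = make_spike_train_sweep([0.3], peak_mV=25.0)
        (ev,) = detect_spikes(sw)
        assert ev.peak == pytest.approx(25.0, abs=1.0)
        assert ev.amplitude == pytest.approx(ev.peak - ev.threshold_V)


class TestMeasurePassive:
    def test_flat_rest_recovers_vm_and_zero_rate(self, protocols):
        n = 20_000
        rest = [sp.Sweep(10_000.0, np.full(n, -59.0), np.zeros(n), "cc")
                for _ in range(5)]
        step = make_spike_train_sweep([], duration_s=0.6, base_mV=-59.0,
                                      step_pA=-50.0, step_dur_s=0.2)
        # impose the passive exponential response on the synthetic step
        t = np.arange(int(0.6 * 1e4)) / 1e4
        tau, rm = 0.0566, 0.41
        v = np.full(t.size, -59.0)
        on = (t >= 0.1) & (t < 0.3)
        v[on] += -50.0 * rm * (1 - np.exp(-(t[on] - 0.1) / tau))
        off = t >= 0.3
        v_end = -50.0 * rm * (1 - np.exp(-0.2 / tau))
        v[off] += v_end * np.exp(-(t[off] - 0.3) / tau)
        step.response = v
        rec = sp.CellRecording(
            "c", "CC",
            sweep_sets={"rest": rest, "cc_hyperpol_steps": [step]},
            protocols={"rest": protocols["rest"],
                       "cc_hyperpol_steps": protocols["cc_hyperpol_steps"]})
        props = sp.measure_passive(rec)
        assert props.Vm_rest == pytest.approx(-59.0)
        assert props.spont_rate == 0.0
        assert props.Rm == pytest.approx(0.41, rel=0.05)

    def test_spontaneous_rate_arithmetic(self, protocols):
        # 9 APs over five 2 s sweeps -> 0.9 Hz
        rest = [make_spike_train_sweep([0.5, 1.0], duration_s=2.0,
                                       base_mV=-55.0, step_pA=0.0)
                for _ in range(4)]
        rest.append(make_spike_train_sweep([0.7], duration_s=2.0,
                                           base_mV=-55.0, step_pA=0.0))
        step = make_spike_train_sweep([], duration_s=0.6, base_mV=-55.0,
                                      step_pA=-50.0, step_dur_s=0.2)
        rec = sp.CellRecording(
            "c", "CC",
            sweep_sets={"rest": rest, "cc_hyperpol_steps": [step]},
            protocols={"rest": protocols["rest"],
                       "cc_hyperpol_steps": protocols["cc_hyperpol_steps"]})
        assert sp.measure_passive(rec).spont_rate == pytest.approx(0.9)

    def test_passive_cell_recovery_within_5_percent(self, passive_cc_params,
                                                    protocols, cfg_off):
        rec = sp.CellRecording(
            "c", "CC",
            sweep_sets={
                "rest": sp.simulate_current_clamp(
                    passive_cc_params, protocols["rest"], cfg_off),
                "cc_hyperpol_steps": sp.simulate_current_clamp(
                    passive_cc_params, protocols["cc_hyperpol_steps"], cfg_off),
            },
            protocols={k: protocols[k] for k in ("rest", "cc_hyperpol_steps")})
        props = sp.measure_passive(rec)
        assert props.Rm == pytest.approx(0.41, rel=0.05)
        assert props.Cm == pytest.approx(138.1, rel=0.05)
        assert props.Vm_rest == pytest.approx(-58.91, abs=0.5)

    def test_missing_rest_protocol_raises(self):
        rec = sp.CellRecording("c", "CC")
        with pytest.raises(sp.ProtocolError):
            sp.measure_passive(rec)


class _AnalyticLIF:
    """Leak-only cell with a hard threshold: the rheobase oracle.

    For a 1 s step the cell fires iff I >= (V_thr - V0) / (Rm * (1 -
    exp(-T/tau))), which for tau << T is (V_thr - V0)/Rm.
    """

    def __init__(self, rm=0.5, tau_s=0.020, v0=-70.0, v_thr=-50.0):
        self.rm, self.tau, self.v0, self.v_thr = rm, tau_s, v0, v_thr

    @property
    def rheobase_true(self):
        return (self.v_thr - self.v0) / (self.rm * (1 - np.exp(-1.0 / self.tau)))

    def __call__(self, current_pA):
        rate = 10_000.0
        t = np.arange(int(1.3 * rate)) / rate
        v = np.full(t.size, self.v0)
        on = (t >= 0.1) & (t < 1.1)
        v[on] += current_pA * self.rm * (1 - np.exp(-(t[on] - 0.1) / self.tau))
        cross = np.flatnonzero(v >= self.v_thr)
        spikes = []
        if cross.size:
            spikes = [t[cross[0]] + 0.002]
        sw = make_spike_train_sweep(spikes, duration_s=1.3, base_mV=self.v0,
                                    step_pA=current_pA, step_dur_s=1.0)
        return sw


class TestFindRheobase:
    def test_matches_lif_closed_form(self):
        lif = _AnalyticLIF()
        res = sp.find_rheobase(lif, coarse_step=15.0, fine_step=2.0)
        assert res.excitable
        assert abs(res.rheobase - lif.rheobase_true) <= 2.0 + 1e-9
        assert abs(res.rheobase - res.coarse_estimate) <= 15.0

    def test_firing_at_first_coarse_step_searched_below(self):
        lif = _AnalyticLIF(rm=4.0)  # rheobase ~5 pA, below first coarse step
        res = sp.find_rheobase(lif, coarse_step=15.0, fine_step=2.0)
        assert res.rheobase <= 15.0

    def test_silent_cell_reported_not_excitable(self):
        lif = _AnalyticLIF(rm=0.01)  # rheobase 2000 pA > protocol max
        res = sp.find_rheobase(lif, i_max=500.0)
        assert not res.excitable
        assert np.isnan(res.rheobase)

    def test_medial_archetype_near_configured_target(self, cfg_off):
        p = sp.make_archetype("medial")
        res = sp.find_rheobase(sp.step_response_fn(p, cfg_off))
        target = sp.load_config()["groups"]["medial"]["rheobase_target_pA"]
        assert res.excitable
        assert abs(res.rheobase - target) < 0.5 * target

    def test_recorded_batteries(self):
        lif = _AnalyticLIF()
        coarse = []
        for amp in np.arange(15.0, 151.0, 15.0):
            sw = lif(amp)
            sw.meta["step_amplitude_pA"] = amp
            coarse.append(sw)
        fine = []
        for amp in np.arange(30.0, 60.1, 2.0):
            sw = lif(amp)
            sw.meta["step_amplitude_pA"] = amp
            fine.append(sw)
        res = find_rheobase_from_batteries(coarse, fine)
        assert abs(res.rheobase - lif.rheobase_true) <= 2.0 + 1e-9


def _battery(amp_map):
    """Ten synthetic step sweeps; amp_map: step index -> (times, decline)."""
    sweeps = []
    for i in range(10):
        times, decline = amp_map.get(i, ([], None))
        sweeps.append(make_spike_train_sweep(
            times, step_pA=50.0 * (i + 1), amp_decline=decline))
    return sweeps


class TestClassifyFiringType:
    def test_all_silent_is_single_with_flag(self):
        res = sp.classify_firing_type(_battery({}))
        assert res.label == "S"
        assert res.non_excitable

    def test_few_spikes_everywhere_is_single(self):
        res = sp.classify_firing_type(
            _battery({i: ([0.15, 0.18], None) for i in range(10)}))
        assert res.label == "S"
        assert not res.non_excitable

    def test_constructed_fading_battery(self):
        # step 5: last-three amplitudes at 70% of the first AP; step 6:
        # stronger mean reduction with early failure and rising baseline
        t5 = list(np.arange(0.12, 0.60, 0.02))
        decline5 = lambda k: -70 + 95.0 * (1.0 - 0.3 * min(k / 5.0, 1.0))
        t6 = list(np.arange(0.12, 0.40, 0.02))
        decline6 = lambda k: -70 + 95.0 * (1.0 - 0.45 * min(k / 4.0, 1.0))
        base = {i: (list(np.arange(0.12, 1.05, 0.05)), None) for i in range(5)}
        base[5] = (t5, decline5)
        base[6] = (t6, decline6)
        sweeps = _battery(base)
        # baseline rise in step 6 after failure
        v = sweeps[6].response
        v[round(0.5 * 1e4): round(1.1 * 1e4)] += 10.0
        res = sp.classify_firing_type(sweeps)
        assert res.label == "F"

    def test_tonic_battery_stable_and_monotone(self):
        base = {i: (list(np.arange(0.12, 1.05, 0.4 / (i + 2))), None)
                for i in range(10)}
        res = sp.classify_firing_type(_battery(base))
        assert res.label == "T"

    def test_simulator_tonic_archetype_is_tonic_and_deterministic(
            self, cc_firing_battery):
        r1 = sp.classify_firing_type(cc_firing_battery)
        r2 = sp.classify_firing_type(cc_firing_battery)
        assert r1.label == r2.label == "T"

    def test_label_invariant_to_uniform_offset(self, cc_firing_battery):
        shifted = []
        for sw in cc_firing_battery:
            s2 = sw.copy()
            s2.response = s2.response + 7.0
            shifted.append(s2)
        assert sp.classify_firing_type(shifted).label == \
            sp.classify_firing_type(cc_firing_battery).label

    def test_wrong_battery_shape_rejected(self, cc_firing_battery):
        with pytest.raises(sp.ProtocolError):
            sp.classify_firing_type(cc_firing_battery[:7])


class TestFICurve:
    def test_silent_cell_all_zero(self):
        curve = sp.build_fI_curve(_battery({}))
        assert [n for _, n in curve] == [0] * 10

    def test_tonic_cc_monotone_and_capped(self, cc_firing_battery):
        curve = sp.build_fI_curve(cc_firing_battery)
        counts = [n for _, n in curve]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert max(counts) <= 109  # highest rate observed at 500 pA

    def test_fading_medial_archetype_peaks_then_declines(self, protocols,
                                                         cfg_off):
        p = sp.make_archetype("medial", "F")
        sweeps = sp.simulate_current_clamp(p, protocols["firing_steps"], cfg_off)
        counts = [n for _, n in sp.build_fI_curve(sweeps)]
        peak = int(np.argmax(counts))
        assert peak <= 5  # saturates by ~250-300 pA
        assert counts[-1] < counts[peak]
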
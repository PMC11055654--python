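"""EPSC detection, thresholds, response taxonomy, jitter, train metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import spinephys as sp
from spinephys.archetypes import default_synapse
from spinephys.synaptic import EPSCEvent


def _flat_vc(duration_s=0.7, rate=10_000.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = round(duration_s * rate)
    resp = rng.normal(0.0, noise_sd, n) if noise_sd else np.zeros(n)
    return sp.Sweep(rate, resp, np.full(n, -70.0), "vc",
                    t0_events=[sp.StimEvent(0.1, 50.0, "electrical")])


def _evoked(stim=0.1, events=(), seed=0, noise=True):
    """Sweep with specified (latency_ms, amplitude_pA) ground-truth events."""
    syn = sp.SynapseParams(release_prob=0.0, noise_sd_pA=4.0 if noise else 0.0,
                           amp_cv=0.0)
    cfg = sp.SimulationConfig(seed=seed, noise=noise)
    sw, _ = sp.simulate_evoked_synaptic(syn, [stim], cfg, duration_s=0.7)
    rate = sw.sampling_rate
    for lat, amp in events:
        t0 = stim + lat / 1000.0
        i0 = int(t0 * rate) + 1
        tt = (np.arange(i0, sw.n_samples) / rate - t0) * 1000.0
        kern = np.exp(-tt / 6.0) - np.exp(-tt / 0.5)
        kern /= kern.max()
        sw.response[i0:] -= amp * kern
    return sw


class TestDetectEpscs:
    def test_flat_trace_no_events(self):
        assert sp.detect_epscs(_flat_vc(), 0.1) == []
        assert sp.detect_epscs(_flat_vc(noise_sd=4.0), 0.1) == []

    def test_current_clamp_rejected(self):
        sw = sp.Sweep(10_000.0, np.zeros(100), np.zeros(100), "cc")
        with pytest.raises(sp.ModeError):
            sp.detect_epscs(sw, 0.0)

    def test_single_event_latency_and_amplitude(self):
        # one EPSC at the published distal-stimulation values
        sw = _evoked(events=[(5.6, 415.0)], noise=False)
        (ev,) = sp.detect_epscs(sw, 0.1)
        assert ev.latency_ms == pytest.approx(5.6, abs=0.5)
        assert ev.amplitude_pA == pytest.approx(415.0, rel=0.03)
        assert 0.1 < ev.rise_10_90_ms < 2.0
        assert 3.0 < ev.decay_tau_ms < 12.0

    def test_recovery_rate_against_generator_truth(self):
        syn = default_synapse("cc_electrical_mono")
        stim = np.arange(20) / 20.0 + 0.05
        rng = np.random.default_rng(17)
        total = found = 0
        for _ in range(20):
            cfg = sp.SimulationConfig(seed=int(rng.integers(2 ** 31)))
            sw, truth = sp.simulate_evoked_synaptic(syn, stim, cfg)
            for k, t in enumerate(stim):
                ev = sp.detect_epscs(sw, t, window_ms=45.0)
                tr = [e for e in truth if e.stim_index == k and e.released]
                if tr and tr[0].amplitude_pA >= 12.0:
                    total += 1
                    if ev and abs(ev[0].latency_ms - tr[0].latency_ms) < 0.5:
                        found += 1
        assert total > 300
        assert found / total >= 0.95

    def test_artifact_window_blanked(self):
        # an "event" inside the 1 ms artifact window is not reported
        sw = _evoked(events=[(0.4, 300.0)], noise=False)
        ev = sp.detect_epscs(sw, 0.1)
        assert all(e.latency_ms > 1.0 for e in ev)


def _ev(lat_amp):
    return [EPSCEvent(lat, amp, 0.5, 6.0, 0.1 + lat / 1000.0)
            for lat, amp in lat_amp]


class TestTaxonomy:
    @pytest.mark.parametrize("events,expected", [
        ([], "NR"),
        ([(5.6, 415.0)], "Si"),
        ([(3.0, 100.0), (6.0, 90.0), (9.0, 80.0)], "Multi"),
        ([(3.0, 100.0), (6.0, 90.0), (8.0, 80.0), (9.5, 70.0)], "Multi"),
        ([(4.0, 400.0), (20.0, 60.0), (50.0, 55.0), (120.0, 70.0),
          (200.0, 50.0)], "Si+Ba"),
        ([(15.0, 60.0), (40.0, 55.0), (90.0, 70.0)], "Ba"),
        ([(4.0, 80.0), (20.0, 60.0), (50.0, 55.0), (120.0, 70.0)], "Ba"),
        ([(5.0, 60.0), (50.0, 60.0)], "Ba"),
    ])
    def test_rule_table(self, events, expected):
        assert sp.classify_evoked_response(_ev(events)) == expected

    @given(st.lists(st.tuples(st.floats(1.1, 500.0), st.floats(5.0, 500.0)),
                    max_size=12))
    def test_taxonomy_total_and_single_valued(self, pairs):
        label = sp.classify_evoked_response(_ev(pairs))
        assert label in ("Si", "Multi", "Ba", "Si+Ba", "NR")
        assert (label == "NR") == (len(pairs) == 0)


class TestStimThreshold:
    def _ladder(self, pattern):
        """pattern: intensity -> list of bools (sweep responds or not)."""
        out = {}
        for inten, flags in pattern.items():
            out[inten] = [
                _evoked(events=[(6.0, 200.0)] if f else [], seed=i, noise=True)
                for i, f in enumerate(flags)]
        return out

    def test_all_respond_threshold_is_lowest(self):
        ladder = self._ladder({25.0: [True] * 5, 100.0: [True] * 5})
        res = sp.determine_stim_threshold(ladder, stim_time_s=0.1)
        assert res.threshold_uA == 25.0

    def test_three_of_five_rule_matches_enumeration(self):
        # oracle: direct enumeration of the 5-sweep response patterns
        for k in range(6):
            flags = [i < k for i in range(5)]
            ladder = self._ladder({50.0: flags, 200.0: [True] * 5})
            res = sp.determine_stim_threshold(ladder, stim_time_s=0.1)
            expected = 50.0 if sum(flags) >= 3 else 200.0
            assert res.threshold_uA == expected, f"k={k}"

    def test_silent_everywhere_is_nonresponsive(self):
        ladder = self._ladder({25.0: [False] * 5, 5000.0: [False] * 5})
        res = sp.determine_stim_threshold(ladder, stim_time_s=0.1)
        assert not res.responsive
        assert np.isnan(res.threshold_uA)

    def test_short_ladder_warns_and_applies_proportional_rule(self):
        ladder = self._ladder({25.0: [True, True, False]})
        with pytest.warns(UserWarning, match="proportional"):
            res = sp.determine_stim_threshold(ladder, stim_time_s=0.1)
        assert res.threshold_uA == 25.0


class TestLatencyJitter:
    def test_identical_latencies_zero_jitter_mono(self):
        sweeps = [_evoked(events=[(5.6, 300.0)], noise=False)
                  for _ in range(5)]
        res = sp.compute_latency_jitter(sweeps, stim_time_s=0.1)
        assert res.jitter_ms == pytest.approx(0.0, abs=0.02)
        assert res.connectivity_call == "mono"

    def test_jitter_within_chi2_interval(self):
        # 7 sweeps with latencies ~ N(13.5, 0.35): the sample SD lies in
        # the chi-square 95% interval for n = 7 and the call is mono
        rng = np.random.default_rng(4)
        lats = 13.5 + 0.35 * rng.standard_normal(7)
        sweeps = [_evoked(events=[(l, 120.0)], noise=False) for l in lats]
        res = sp.compute_latency_jitter(sweeps, stim_time_s=0.1,
                                        modality="optogenetic")
        lo = 0.35 * np.sqrt(sps.chi2.ppf(0.025, 6) / 6)
        hi = 0.35 * np.sqrt(sps.chi2.ppf(0.975, 6) / 6)
        assert lo <= res.jitter_ms <= hi
        assert res.connectivity_call == "mono"

    def test_high_jitter_called_polysynaptic(self):
        rng = np.random.default_rng(5)
        lats = np.abs(40.0 + 36.5 * rng.standard_normal(7)) + 2.0
        sweeps = [_evoked(events=[(l, 120.0)], noise=False) for l in lats]
        res = sp.compute_latency_jitter(sweeps, stim_time_s=0.1,
                                        modality="optogenetic")
        assert res.jitter_ms > 10.0
        assert res.connectivity_call == "poly"

    def test_too_few_sweeps_rejected(self):
        sweeps = [_evoked(events=[(5.0, 100.0)], noise=False)] * 3
        with pytest.raises(sp.InsufficientDataError):
            sp.compute_latency_jitter(sweeps, stim_time_s=0.1)

    def test_estimator_consistency_over_replicates(self):
        # across many replicate cells the mean sample SD approaches
        # c4(7) * sigma, within 5% of the generating SD
        syn = default_synapse("medial_opto_mono")
        rng = np.random.default_rng(6)
        jits = []
        for _ in range(300):
            sweeps = []
            for _ in range(7):
                cfg = sp.SimulationConfig(seed=int(rng.integers(2 ** 31)))
                sw, _ = sp.simulate_evoked_synaptic(syn, [0.05], cfg,
                                                    duration_s=0.25)
                sweeps.append(sw)
            try:
                jits.append(sp.compute_latency_jitter(
                    sweeps, modality="optogenetic").jitter_ms)
            except sp.InsufficientDataError:
                continue
        assert len(jits) > 280
        assert np.mean(jits) == pytest.approx(0.35, rel=0.05)


class TestTrains:
    def _train(self, noise, seed=0, syn=None):
        syn = syn or default_synapse("cc_electrical_mono")
        stim = np.arange(20) / 20.0 + 0.1
        cfg = sp.SimulationConfig(noise=noise, seed=seed)
        sw, _ = sp.simulate_evoked_synaptic(syn, stim, cfg)
        return sw, stim

    def test_constant_amplitudes_no_failure_no_depression(self):
        syn = sp.SynapseParams(release_prob=1.0, depression_U=1e-9,
                               tau_rec_s=1e9, noise_sd_pA=0.0, amp_cv=0.0)
        sw, stim = self._train(noise=False, syn=syn)
        res = sp.analyze_train([sw], stim_times_s=stim)
        assert res.failure_pct == 0.0
        assert res.depression_pct == pytest.approx(0.0, abs=0.2)

    def test_depression_matches_recursion_closed_form(self):
        syn = default_synapse("cc_electrical_mono")
        sw, stim = self._train(noise=False)
        res = sp.analyze_train([sw], stim_times_s=stim)
        r, u, x = 1.0, syn.depression_U, np.exp(-0.05 / syn.tau_rec_s)
        for _ in range(19):
            r = 1.0 - (1.0 - r * (1.0 - u)) * x
        closed = 100.0 * (1.0 - r)
        assert res.depression_pct == pytest.approx(closed, abs=0.1)

    def test_failure_rate_matches_binomial_expectation(self):
        rng = np.random.default_rng(8)
        fails = []
        for cell in range(8):
            sweeps = []
            for _ in range(20):
                sw, stim = self._train(noise=True,
                                       seed=int(rng.integers(2 ** 31)))
                sweeps.append(sw)
            fails.append(sp.analyze_train(sweeps, stim_times_s=stim).failure_pct)
        p_fail = 100.0 * (1.0 - 0.991)
        n = 8 * 20 * 20
        tol = 100.0 * 1.96 * np.sqrt(0.991 * 0.009 / n) + 1e-9
        assert np.mean(fails) == pytest.approx(p_fail, abs=3 * tol)

    def test_connectivity_rule_table(self):
        from spinephys.synaptic import JitterResult, TrainResult
        j = lambda jit, mod="electrical": JitterResult(5.6, jit, 7, "", mod)
        t = lambda f: TrainResult(20, 1, f, 50.0, 400.0, 120.0)
        assert sp.call_connectivity(j(0.13), t(0.9)) == "mono"
        assert sp.call_connectivity(j(36.5), t(0.0)) == "poly"
        assert sp.call_connectivity(j(0.1), t(40.0)) == "poly"
        assert sp.call_connectivity(j(0.1)) == "mono"
        assert sp.call_connectivity(j(1.5, "optogenetic")) == "mono"
        assert sp.call_connectivity(j(1.5, "electrical")) == "poly"


class TestEndToEndTaxonomy:
    def test_barrage_preset_classifies_as_barrage(self):
        syn = default_synapse("barrage")
        cfg = sp.SimulationConfig(seed=5)
        sw, _ = sp.simulate_evoked_synaptic(syn, [0.1], cfg, duration_s=0.7)
        events = sp.detect_epscs(sw, 0.1)
        assert len(events) >= 3
        assert sp.classify_evoked_response(events) == "Ba"

    def test_mono_plus_barrage_classifies_si_ba(self):
        from dataclasses import replace
        syn = replace(default_synapse("cc_electrical_mono"),
                      barrage_n_mean=5.0, barrage_amp_pA=60.0)
        cfg = sp.SimulationConfig(seed=9)
        sw, _ = sp.simulate_evoked_synaptic(syn, [0.1], cfg, duration_s=0.7)
        label = sp.classify_evoked_response(sp.detect_epscs(sw, 0.1))
        assert label == "Si+Ba"
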
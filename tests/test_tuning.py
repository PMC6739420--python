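"""Optotagging, triggered averages, shuffle nulls, tuning and firing onset."""

import numpy as np
import pytest

import collic
from collic.kinematics import EulerTrace, detect_motion_events
from collic.synthetic import (
    HeadEvent,
    SpikeTrain,
    StimLog,
    generate_head_trace,
    generate_spike_train,
    generate_stim_log,
)
from collic.tuning import (
    characteristic_angle,
    classify_tuning,
    firing_onset,
    optotag,
    shuffle_null,
    sta_lta_compare,
    triggered_average,
)


def bout_trace(amplitudes, spacing_s=4.0, duration_ms=250.0, axis="yaw",
               start_s=3.0, seed=0, **kwargs):
    """Trace with isolated bouts and triggers 100 ms before each onset."""
    events = [
        HeadEvent(axis, start_s + k * spacing_s, float(a), duration_ms)
        for k, a in enumerate(amplitudes)
    ]
    total = start_s + len(amplitudes) * spacing_s + 3.0
    trace, truth = generate_head_trace(total, events, seed=seed, **kwargs)
    triggers = np.array([e.onset_s - 0.1 for e in events])
    return trace, truth, triggers


class TestOptotag:
    def _unit(self, latency_ms, pulses):
        times = pulses.onsets + latency_ms / 1000.0
        return SpikeTrain("u", times, session_length_s=pulses.onsets[-1] + 5)

    def test_three_ms_responder_is_tagged(self):
        pulses = generate_stim_log(60, inter_trial_s=1.0, duration_s=0.005)
        r = optotag(self._unit(3.0, pulses), pulses)
        assert r.tagged
        assert r.median_latency_ms == pytest.approx(3.0, abs=0.01)
        assert r.response_probability == 1.0

    def test_eight_ms_responder_is_not_tagged(self):
        pulses = generate_stim_log(60, inter_trial_s=1.0, duration_s=0.005)
        assert not optotag(self._unit(8.0, pulses), pulses).tagged

    def test_silent_unit_is_not_tagged(self):
        pulses = generate_stim_log(60, inter_trial_s=1.0, duration_s=0.005)
        unit = SpikeTrain("u", np.empty(0), session_length_s=100.0)
        assert not optotag(unit, pulses).tagged

    def test_no_pulses_rejected(self):
        unit = SpikeTrain("u", np.array([1.0]), session_length_s=10.0)
        with pytest.raises(ValueError):
            optotag(unit, StimLog(onsets=np.empty(0), duration_s=0.005))

    def test_synthetic_optotag_injection_passes(self):
        pulses = generate_stim_log(60, inter_trial_s=1.0, duration_s=0.005)
        trace, truth = generate_head_trace(80.0, seed=0)
        unit = generate_spike_train(
            trace, truth, base_rate_hz=2.0, burst_rate_hz=2.0,
            light_pulses=pulses, seed=1,
        )
        r = optotag(unit, pulses)
        assert r.tagged
        assert 1.0 <= r.median_latency_ms <= 4.0


class TestTriggeredAverage:
    def test_flat_trace_gives_zero_curve_and_vector(self, flat_trace):
        avg = triggered_average(flat_trace, np.array([3.0, 5.0]), "yaw")
        assert np.all(avg.curve == 0)
        assert avg.displacement_vector == 0.0

    def test_curve_geometry(self, flat_trace):
        avg = triggered_average(flat_trace, np.array([3.0]), "yaw")
        assert avg.curve.size == 151
        assert avg.curve[50] == 0.0

    def test_positive_ramps_give_positive_vector(self):
        trace, _, trig = bout_trace([20.0] * 8)
        avg = triggered_average(trace, trig, "yaw")
        assert avg.n_triggers == 8
        assert avg.displacement_vector == pytest.approx(20.0, abs=1e-9)

    def test_negative_ramps_give_negative_vector(self):
        """Max precedes min, so the displacement is deemed negative."""
        trace, _, trig = bout_trace([-20.0] * 8)
        avg = triggered_average(trace, trig, "yaw")
        assert avg.displacement_vector == pytest.approx(-20.0, abs=1e-9)

    def test_triggers_without_context_dropped(self):
        trace, _, trig = bout_trace([20.0] * 3)
        avg = triggered_average(trace, np.concatenate([[0.2], trig]), "yaw")
        assert avg.n_triggers == 3
        with pytest.raises(ValueError):
            triggered_average(trace, np.array([0.2]), "yaw")

    def test_vector_scales_linearly_with_trace(self):
        trace, _, trig = bout_trace([15.0, 15.0, 15.0], wander_sd=1.0, seed=4)
        scaled = EulerTrace(trace.time, 3 * trace.yaw, 3 * trace.pitch, 3 * trace.roll)
        a = triggered_average(trace, trig, "yaw")
        b = triggered_average(scaled, trig, "yaw")
        assert b.displacement_vector == pytest.approx(
            3 * a.displacement_vector, rel=1e-12
        )
        assert np.allclose(b.curve, 3 * a.curve)


class TestShuffleNull:
    def _session(self, seed=0):
        events = [HeadEvent("yaw", 160.0 + 0.5 * k, 15.0, 250.0) for k in range(8)]
        trace, truth = generate_head_trace(200.0, events, seed=seed)
        spikes = np.array([e.onset_s - 0.08 for e in events])
        unit = SpikeTrain("u", spikes, session_length_s=200.0)
        return trace, unit

    def test_spike_count_preserved(self):
        trace, unit = self._session()
        null = shuffle_null(trace, unit, "yaw", n_shuffles=20, seed=0)
        assert null.vectors.size == 20
        # conservation is structural: shifts are modulo the session length
        assert np.all((unit.times + null.shifts_s[0]) % 200.0 <= 200.0)

    def test_locked_spikes_exceed_null(self):
        """Motion confined to one epoch, spikes locked to it: the real
        vector stands clear of the shuffled distribution."""
        trace, unit = self._session()
        real = triggered_average(trace, unit.times, "yaw").displacement_vector
        null = shuffle_null(trace, unit, "yaw", n_shuffles=100, seed=1)
        assert real > np.percentile(null.vectors, 95)
        assert abs(null.mean) < real / 2

    def test_seeded_determinism(self):
        trace, unit = self._session()
        a = shuffle_null(trace, unit, "yaw", n_shuffles=15, seed=7)
        b = shuffle_null(trace, unit, "yaw", n_shuffles=15, seed=7)
        assert np.array_equal(a.vectors, b.vectors)

    def test_short_session_rejected(self):
        trace, _ = generate_head_trace(100.0, seed=0)
        unit = SpikeTrain("u", np.array([5.0]), session_length_s=100.0)
        with pytest.raises(ValueError):
            shuffle_null(trace, unit, "yaw")


class TestClassifyTuning:
    def _epoch(self, amp, seed):
        trace, _, trig = bout_trace([amp] * 12, wander_sd=0.3, noise_sd=0.05,
                                    seed=seed)
        return triggered_average(trace, trig, "yaw")

    def _null(self, seed=0):
        rng = np.random.default_rng(seed)
        from collic.tuning import ShuffleNull

        return ShuffleNull("yaw", rng.normal(0.0, 1.0, 200), np.zeros(200))

    def test_consistent_epochs_are_tuned(self):
        res = classify_tuning(
            {"light1": self._epoch(15.0, 1), "light2": self._epoch(15.0, 2)},
            self._null(),
        )
        assert res.tuned
        assert all(p < 0.05 for p in res.p_values.values())

    def test_opposite_epochs_are_not_tuned(self):
        res = classify_tuning(
            {"light1": self._epoch(15.0, 1), "light2": self._epoch(-15.0, 2)},
            self._null(),
        )
        assert not res.tuned

    def test_vectors_within_null_are_not_tuned(self):
        trace, _ = generate_head_trace(60.0, wander_sd=0.2, seed=3)
        trig = np.linspace(5, 55, 12)
        avg = triggered_average(trace, trig, "yaw")
        null = self._null()
        null.vectors = null.vectors + avg.displacement_vector  # null centred on real
        res = classify_tuning({"light1": avg, "light2": avg}, null)
        assert not res.tuned

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError):
            classify_tuning({"light1": self._epoch(15.0, 1)}, self._null())

    def test_characteristic_angle_pools_post_spike_events(self):
        trace, _, trig = bout_trace([18.0] * 10)
        events = detect_motion_events(trace, "yaw")
        angle = characteristic_angle(events, trig)
        assert angle == pytest.approx(18.0, abs=0.5)


class TestFiringOnset:
    def _burst_unit(self, lead_ms, n_onsets=30, seed=0, post_only=False):
        rng = np.random.default_rng(seed)
        onsets = 20.0 + 12.0 * np.arange(n_onsets)
        session = float(onsets[-1] + 20.0)
        base = np.sort(rng.uniform(0, session, size=int(3 * session)))
        extra = []
        for o in onsets:
            t0 = o if post_only else o - lead_ms / 1000.0
            extra.append(np.sort(rng.uniform(t0, t0 + 0.25, size=12)))
        times = np.sort(np.concatenate([base] + extra))
        return SpikeTrain("u", times, session_length_s=session), onsets

    def test_pre_movement_burst_onset_recovered(self):
        unit, onsets = self._burst_unit(80.0, seed=1)
        res = firing_onset(unit, onsets, n_shuffles=150, seed=2)
        assert res.significant
        assert -120.0 <= res.onset_ms <= -40.0

    def test_post_onset_firing_gives_positive_onset(self):
        unit, onsets = self._burst_unit(0.0, seed=3, post_only=True)
        res = firing_onset(unit, onsets, n_shuffles=150, seed=4)
        assert res.significant
        assert res.onset_ms >= 0.0

    def test_type_i_error_control(self):
        """Independent homogeneous units rarely yield a significant onset."""
        rng = np.random.default_rng(0)
        onsets = 20.0 + 12.0 * np.arange(25)
        session = float(onsets[-1] + 20.0)
        hits = 0
        n_runs = 200
        for k in range(n_runs):
            times = np.sort(rng.uniform(0, session, size=900))
            unit = SpikeTrain("u", times, session_length_s=session)
            res = firing_onset(unit, onsets, n_shuffles=80, seed=k)
            hits += int(res.significant)
        assert hits / n_runs <= 0.06

    def test_too_few_onsets_rejected(self):
        unit = SpikeTrain("u", np.arange(0, 200.0, 0.5), session_length_s=200.0)
        with pytest.raises(ValueError):
            firing_onset(unit, np.arange(20.0, 30.0, 1.0))


class TestStaLtaCompare:
    def test_identical_vectors_agree(self):
        trace, _, trig = bout_trace([20.0] * 8)
        sta = triggered_average(trace, trig, "yaw")
        res = sta_lta_compare(sta, sta)
        assert res.direction_agreement
        assert res.vector_difference_deg == 0.0

    def test_light_driven_bouts_with_preceding_spikes_agree(self):
        stim = generate_stim_log(10)
        events = [HeadEvent("yaw", float(o) + 0.3, 20.0, 250.0) for o in stim.onsets]
        trace, truth = generate_head_trace(115.0, events, wander_sd=0.3, seed=5)
        spikes = np.array([e.onset_s - 0.1 for e in events])
        sta = triggered_average(trace, spikes, "yaw")
        lta = triggered_average(trace, stim.onsets, "yaw")
        assert sta_lta_compare(sta, lta).direction_agreement

    def test_opposite_vectors_disagree(self):
        t1, _, g1 = bout_trace([20.0] * 8)
        t2, _, g2 = bout_trace([-20.0] * 8)
        a = triggered_average(t1, g1, "yaw")
        b = triggered_average(t2, g2, "yaw")
        assert not sta_lta_compare(a, b).direction_agreement

    def test_axis_mismatch_rejected(self):
        trace, _, trig = bout_trace([20.0] * 8)
        a = triggered_average(trace, trig, "yaw")
        b = triggered_average(trace, trig, "pitch")
        with pytest.raises(ValueError):
            sta_lta_compare(a, b)
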
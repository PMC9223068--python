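import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bedwatch.fall_detector import (
    DetectorConfig,
    DetectorState,
    FEATURE_NAMES,
    FeatureVector,
    LabeledWindow,
    Phase,
    TrainConfig,
    TrainedModel,
    classify,
    denormalize,
    detect_fall_events,
    extract_features,
    gateway_process,
    normalize,
    step,
    train,
)
from bedwatch.sensors import Event, EventKind, svm
from bedwatch.simulator import make_labeled_windows

from _reference import random_spiky_trace, reference_fall_event_times
from conftest import constant_window, imu

CFG = DetectorConfig()


def quiescent_trace_with_spikes(spike_times_ms, duration_ms=6000, rate_hz=50.0, spike_g=3.0):
    dt = 1000.0 / rate_hz
    n = int(duration_ms / dt)
    samples = []
    for i in range(n):
        t = int(round(i * dt))
        ax = spike_g if any(abs(t - s) < dt / 2 for s in spike_times_ms) else 1.0
        samples.append(imu(t, ax=ax))
    return samples


class TestStateMachine:
    def test_supra_threshold_peak_opens_capture_window(self):
        state, event = step(DetectorState.initial(), imu(100, ax=3.0), CFG)
        assert event is None
        assert state.phase is Phase.POST_PEAK
        assert state.time_reference_ms == 1100
        assert len(state.log) == 1 and state.log[0].t_ms == 100

    def test_sub_threshold_sample_leaves_sampling_untouched(self):
        initial = DetectorState.initial()
        state, event = step(initial, imu(100, ax=1.0), CFG)
        assert state == initial and event is None

    def test_exact_threshold_does_not_trigger(self):
        state, _ = step(DetectorState.initial(), imu(0, ax=2.5), CFG)
        assert state.phase is Phase.SAMPLING

    def test_out_of_order_sample_rejected(self):
        state, _ = step(DetectorState.initial(), imu(100, ax=3.0), CFG)
        with pytest.raises(ValueError, match="out-of-order"):
            step(state, imu(100, ax=1.0), CFG)

    def test_single_spike_emits_one_event_after_quiescence(self):
        trace = quiescent_trace_with_spikes([1000])
        events = detect_fall_events(trace, CFG)
        assert [e.t_ms for e in events] == reference_fall_event_times(trace)
        assert len(events) == 1
        assert events[0].t_ms > 3500
        assert events[0].window[0].t_ms == 1000  # log starts at the peak

    def test_second_spike_cancels_and_restarts_capture(self):
        trace = quiescent_trace_with_spikes([0, 1800])
        events = detect_fall_events(trace, CFG)
        assert [e.t_ms for e in events] == reference_fall_event_times(trace)
        assert len(events) == 1
        assert events[0].t_ms > 4300
        assert events[0].window[0].t_ms == 1800  # log cleared at the second peak

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_incremental_replay_matches_brute_force_reference(self, seed):
        """Sample-by-sample stepping equals the whole-trace reference detector."""
        trace = random_spiky_trace(np.random.default_rng(seed))
        events = detect_fall_events(trace, CFG)
        assert [e.t_ms for e in events] == reference_fall_event_times(trace)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_events_require_a_preceding_peak(self, seed):
        trace = random_spiky_trace(np.random.default_rng(seed))
        events = detect_fall_events(trace, CFG)
        mags = [svm(s.ax, s.ay, s.az) for s in trace]
        crossings = sum(
            1
            for i in range(len(trace))
            if mags[i] > CFG.fall_threshold_g and (i == 0 or mags[i - 1] <= CFG.fall_threshold_g)
        )
        assert len(events) <= crossings
        for ev in events:
            assert any(
                mags[i] > CFG.fall_threshold_g and trace[i].t_ms < ev.t_ms
                for i in range(len(trace))
            )


class TestFeatures:
    def test_constant_window_has_zero_spread(self):
        fv = extract_features(constant_window(1.0, n=10), rate_hz=50.0)
        assert fv.svm_mean == pytest.approx(1.0)
        assert fv.svm_var == 0.0
        assert fv.acc_y_mean == 0.0 and fv.acc_z_mean == 0.0
        assert fv.acc_y_std == 0.0 and fv.gyr_z_std == 0.0
        assert fv.fourier_acc_svm == 0.0

    def test_two_sample_population_statistics(self):
        window = (imu(0, ay=0.0), imu(20, ay=2.0))
        fv = extract_features(window, rate_hz=50.0)
        assert fv.acc_y_mean == pytest.approx(1.0)
        assert fv.acc_y_std == pytest.approx(1.0)  # population, not sample
        assert fv.svm_mean == pytest.approx(1.0)

    def test_fourier_feature_recovers_sinusoid_amplitude(self):
        rate, n, freq, amp = 50.0, 50, 5.0, 0.3
        window = tuple(
            imu(int(i * 20), ax=1.0 + amp * math.sin(2 * math.pi * freq * i / rate))
            for i in range(n)
        )
        fv = extract_features(window, rate_hz=rate)
        assert fv.fourier_acc_svm == pytest.approx(amp, rel=1e-6)

    def test_fall_time_spans_peak_to_last_supra_sample(self):
        window = [imu(0, ax=3.0), imu(20, ax=1.0), imu(40, ax=2.8), imu(60, ax=1.0)]
        fv = extract_features(window, rate_hz=50.0)
        assert fv.fall_time_ms == 40.0
        only_peak = [imu(0, ax=3.0), imu(20, ax=1.0)]
        assert extract_features(only_peak, rate_hz=50.0).fall_time_ms == 0.0

    @pytest.mark.parametrize("c", [0.5, 2.0, 3.7])
    def test_acceleration_scaling_law(self, c):
        window = [imu(i * 20, ax=1.0 + 0.1 * i, ay=0.2 * i) for i in range(10)]
        scaled = [imu(s.t_ms, c * s.ax, c * s.ay, c * s.az, s.gx, s.gy, s.gz) for s in window]
        base = extract_features(window, 50.0)
        got = extract_features(scaled, 50.0)
        assert got.svm_mean == pytest.approx(c * base.svm_mean)
        assert got.svm_var == pytest.approx(c * c * base.svm_var)

    def test_empty_and_irregular_windows_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_features((), 50.0)
        with pytest.raises(ValueError, match="spacing"):
            extract_features((imu(0), imu(20), imu(100)), 50.0)


class TestNormalization:
    means = np.arange(13, dtype=float)
    stds = np.ones(13) * 2.0

    def test_training_means_map_to_zero(self):
        z = normalize(FeatureVector.from_array(self.means), self.means, self.stds)
        assert np.allclose(z, 0.0)

    def test_one_std_above_mean_maps_to_one(self):
        z = normalize(self.means + self.stds, self.means, self.stds)
        assert np.allclose(z, 1.0)

    def test_roundtrip_and_zero_variance_convention(self):
        stds = self.stds.copy()
        stds[3] = 0.0
        x = self.means + 1.5
        z = normalize(x, self.means, stds)
        assert z[3] == 0.0
        back = denormalize(z, self.means, stds)
        expected = x.copy()
        expected[3] = self.means[3]  # zero-variance features recover the mean
        assert np.allclose(back, expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(12), self.means, self.stds)


class TestClassifier:
    def test_separable_toy_set_is_learned_exactly(self, toy_model):
        assert classify(toy_model, constant_window(3.0)) == "FALL"
        assert classify(toy_model, constant_window(1.0)) == "ADL"

    def test_quiescent_window_is_adl(self, toy_model):
        assert classify(toy_model, constant_window(0.0)) == "ADL"

    def test_decision_invariant_to_sample_duplication(self, toy_model):
        """Doubling the sampling density leaves the window statistics, hence
        the decision, unchanged."""
        window = constant_window(3.0, n=5, dt=20)
        doubled = tuple(
            imu(i * 10, ax=3.0) for i in range(10)
        )
        assert classify(toy_model, window) == classify(toy_model, doubled) == "FALL"

    def test_training_is_deterministic(self):
        dataset = make_labeled_windows(3, seed=5)
        a = train(dataset, TrainConfig(), seed=1)
        b = train(dataset, TrainConfig(), seed=1)
        assert a.to_json() == b.to_json()

    def test_single_class_dataset_rejected(self):
        dataset = [LabeledWindow(constant_window(1.0), "ADL", "sit")] * 4
        with pytest.raises(ValueError, match="both"):
            train(dataset, TrainConfig(), seed=0)

    def test_model_roundtrips_through_json(self, tmp_path, toy_model):
        path = tmp_path / "model.json"
        toy_model.save(path)
        loaded = TrainedModel.load(path)
        assert loaded == toy_model
        assert classify(loaded, constant_window(3.0)) == "FALL"
        payload = json.loads(path.read_text())
        assert payload["feature_names"] == list(FEATURE_NAMES)

    def test_radial_kernel_also_separates_toy_set(self):
        dataset = [LabeledWindow(constant_window(3.0), "FALL", "forward_fall")] * 4 + [
            LabeledWindow(constant_window(1.0), "ADL", "sit")
        ] * 4
        model = train(dataset, TrainConfig(kernel="radial"), seed=0)
        assert classify(model, constant_window(3.0)) == "FALL"
        assert classify(model, constant_window(1.0)) == "ADL"

    def test_synthetic_corpus_heldout_accuracy_and_backward_confusion(self):
        """On the simulated nine-activity protocol the classifier beats
        chance, and the backward fall is the hardest fall type (it overlaps
        the sit activity by construction)."""
        model = train(make_labeled_windows(10, seed=0), TrainConfig(), seed=0)
        test = make_labeled_windows(5, seed=1)
        errors: dict[str, int] = {}
        correct = 0
        for w in test:
            predicted = classify(model, w.window)
            correct += predicted == w.label
            if predicted != w.label:
                errors[w.activity] = errors.get(w.activity, 0) + 1
        assert correct / len(test) > 0.75
        backward = errors.get("backward_fall", 0)
        for fall in ("forward_fall", "left_fall", "right_fall"):
            assert backward >= errors.get(fall, 0)


class TestGateway:
    def test_fall_window_raises_alarm(self, toy_model):
        event = Event(0, EventKind.FALL_EVENT, source="s1", window=constant_window(3.0))
        alarm = gateway_process(event, toy_model)
        assert alarm is not None and alarm.kind is EventKind.ALARM
        assert alarm.reason.value == "FALL" and alarm.source == "s1"

    def test_adl_window_raises_nothing(self, toy_model):
        event = Event(0, EventKind.FALL_EVENT, window=constant_window(1.0))
        assert gateway_process(event, toy_model) is None

    def test_empty_window_and_wrong_kind_rejected(self, toy_model):
        with pytest.raises(ValueError, match="empty"):
            gateway_process(Event(0, EventKind.FALL_EVENT, window=()), toy_model)
        with pytest.raises(ValueError, match="FALL_EVENT"):
            gateway_process(Event(0, EventKind.MOVEMENT_EVENT), toy_model)
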
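"""Matched-filter detector checked against naive oracles and the exact
likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medetect.detect import (
    MedOutput,
    SupportError,
    auto_threshold,
    compute_Q,
    detect_and_classify,
    gaussian_energy,
    matched_filter,
    med_output,
)
from medetect.model import (
    EventSequence,
    GaussianChannelModel,
    MultimodalModel,
    MultimodalRecording,
    PointProcessChannelModel,
    TemporalResponse,
    joint_log_likelihood,
)

DELTA = 0.005


def naive_matched_filter(signal, kernel):
    """O(n*m) sliding dot product with zero padding outside the signal."""
    n, m = len(signal), len(kernel.values)
    lag0 = kernel.lag_bins
    out = np.zeros(n)
    for t in range(n):
        for j in range(m):
            idx = t + lag0 + j
            if 0 <= idx < n:
                out[t] += kernel.values[j] * signal[idx]
    return out


class TestMatchedFilter:
    def test_impulse_response_is_time_reversed_kernel(self):
        kernel = TemporalResponse(0.0, np.array([1.0, 2.0, 3.0]), DELTA)
        signal = np.zeros(20)
        signal[10] = 1.0
        out = matched_filter(signal, kernel)
        # out[t] = r(10 - t): support at t in {8, 9, 10}
        np.testing.assert_allclose(out[8:11], [3.0, 2.0, 1.0])
        assert np.all(out[:8] == 0) and np.all(out[11:] == 0)

    def test_matched_signal_peaks_at_event_time(self):
        kernel = TemporalResponse(0.0, np.array([0.2, 1.0, 0.5, 0.1]), DELTA)
        signal = np.zeros(50)
        signal[30:34] = kernel.values
        out = matched_filter(signal, kernel)
        assert np.argmax(out) == 30  # Cauchy-Schwarz

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n=st.integers(16, 64),
        m=st.integers(1, 12),
        start_bins=st.integers(-4, 8),
        seed=st.integers(0, 1000),
    )
    def test_matches_naive_sliding_dot_product(self, n, m, start_bins, seed):
        rng = np.random.default_rng(seed)
        kernel = TemporalResponse(start_bins * DELTA, rng.normal(size=m), DELTA)
        signal = rng.normal(size=n)
        np.testing.assert_allclose(
            matched_filter(signal, kernel),
            naive_matched_filter(signal, kernel),
            atol=1e-10,
        )

    def test_empty_kernel_returns_zeros_with_warning(self):
        kernel = TemporalResponse(0.0, np.empty(0), DELTA)
        with pytest.warns(UserWarning):
            out = matched_filter(np.ones(10), kernel)
        assert np.all(out == 0)


class TestOffsetTerms:
    def test_zero_kernel_Q_is_baseline_times_duration(self):
        r = TemporalResponse(0.0, np.zeros(10), DELTA)
        ch = PointProcessChannelModel(r, np.array([2.0]), np.log(15.0))
        assert compute_Q(ch, 0, 4.0) == pytest.approx(15.0 * 4.0)

    def test_null_tuning_Q_is_baseline_times_duration(self):
        r = TemporalResponse(0.0, np.ones(10) * 3.0, DELTA)
        ch = PointProcessChannelModel(r, np.array([0.0, 1.0]), np.log(15.0))
        assert compute_Q(ch, 0, 4.0) == pytest.approx(15.0 * 4.0)

    def test_boxcar_Q_closed_form_matches_numeric_sum(self):
        h, w, alpha = 0.8, 1.3, np.log(12.0)
        n = 40
        r = TemporalResponse(0.0, np.full(n, h), DELTA)
        ch = PointProcessChannelModel(r, np.array([w]), alpha)
        closed = 12.0 * (n * DELTA * np.exp(h * w) + (4.0 - n * DELTA))
        numeric = 12.0 * (
            np.sum(np.exp(r.values * w)) * DELTA + (4.0 - n * DELTA)
        )
        assert compute_Q(ch, 0, 4.0) == pytest.approx(closed, rel=1e-9)
        assert compute_Q(ch, 0, 4.0) == pytest.approx(numeric, rel=1e-12)

    def test_support_exceeding_duration_rejected(self):
        r = TemporalResponse(0.0, np.ones(1000), DELTA)
        ch = PointProcessChannelModel(r, np.array([1.0]), np.log(5.0))
        with pytest.raises(SupportError):
            compute_Q(ch, 0, 1.0)

    def test_gaussian_energy_direct_sum(self, rng):
        vals = rng.normal(size=17)
        ch = GaussianChannelModel(
            TemporalResponse(0.0, vals, DELTA), np.array([0.0, -1.7]), 1.0
        )
        assert gaussian_energy(ch, 0) == 0.0
        assert gaussian_energy(ch, 1) == pytest.approx(
            0.5 * np.sum((vals * -1.7) ** 2)
        )

    def test_unit_norm_kernel_energy_is_half_phi_squared(self, rng):
        vals = rng.normal(size=9)
        vals /= np.linalg.norm(vals)
        ch = GaussianChannelModel(
            TemporalResponse(0.0, vals, DELTA), np.array([2.5]), 1.0
        )
        assert gaussian_energy(ch, 0) == pytest.approx(2.5**2 / 2)


class TestMedOutput:
    def test_traces_reproduce_likelihood_differences(self, toy_model, toy_recording):
        """With k = 1, trace differences equal brute-force joint
        log-likelihood differences over a grid of (time, class) candidates."""
        out = med_output(toy_recording, toy_model)
        delta = toy_model.delta
        grid_bins = range(60, 340, 20)  # interior candidates
        ref_ll = joint_log_likelihood(toy_recording, toy_model, 60 * delta, 0)
        ref_trace = out.traces[0, 60]
        for b in grid_bins:
            for c in range(2):
                ll = joint_log_likelihood(toy_recording, toy_model, b * delta, c)
                assert out.traces[c, b] - ref_trace == pytest.approx(
                    ll - ref_ll, abs=1e-6
                )

    def test_identical_tuning_collapses_traces(self, toy_recording):
        delta = toy_recording.delta
        r = TemporalResponse(0.0, np.hanning(20), delta)
        pp = PointProcessChannelModel(r, np.array([0.7, 0.7]), np.log(10.0))
        g = GaussianChannelModel(r, np.array([1.1, 1.1]), 1.0)
        model = MultimodalModel([pp], [g], 2, delta)
        out = med_output(toy_recording, model)
        np.testing.assert_allclose(out.traces[0], out.traces[1])
        assert np.all(out.argmax_class == 0)  # ties to lowest index

    def test_no_gaussian_channels_independent_of_k(self, toy_model, toy_recording):
        pp_only = MultimodalModel(toy_model.pp_channels, [], 2, toy_model.delta)
        rec = MultimodalRecording(
            toy_recording.spikes,
            np.empty((0, toy_recording.n_bins)),
            toy_recording.duration,
            toy_recording.delta,
        )
        out1 = med_output(rec, pp_only.with_k(1.0))
        out2 = med_output(rec, pp_only.with_k(37.0))
        np.testing.assert_array_equal(out1.traces, out2.traces)

    def test_field_rescaling_invariance(self, toy_model, toy_recording):
        """Scaling fields and kernels by c and sigma2 by c^2 leaves traces
        unchanged."""
        c = 3.7
        scaled_g = [
            GaussianChannelModel(
                TemporalResponse(ch.r.start, ch.r.values * c, ch.r.delta),
                ch.phi,
                ch.sigma2 * c * c,
            )
            for ch in toy_model.gauss_channels
        ]
        scaled_model = MultimodalModel(
            toy_model.pp_channels, scaled_g, 2, toy_model.delta
        )
        scaled_rec = MultimodalRecording(
            toy_recording.spikes,
            toy_recording.fields * c,
            toy_recording.duration,
            toy_recording.delta,
        )
        out = med_output(toy_recording, toy_model)
        out_scaled = med_output(scaled_rec, scaled_model)
        np.testing.assert_allclose(out.traces, out_scaled.traces, rtol=1e-9)

    def test_zero_kernel_field_channel_is_inert(self, toy_model, toy_recording):
        extra = GaussianChannelModel(
            TemporalResponse(0.0, np.zeros(10), toy_model.delta),
            np.array([1.0, 2.0]),
            1.0,
        )
        bigger = MultimodalModel(
            toy_model.pp_channels,
            toy_model.gauss_channels + [extra],
            2,
            toy_model.delta,
        )
        rec2 = MultimodalRecording(
            toy_recording.spikes,
            np.vstack([toy_recording.fields, np.random.default_rng(0).normal(size=toy_recording.n_bins)]),
            toy_recording.duration,
            toy_recording.delta,
        )
        out = med_output(toy_recording, toy_model)
        out2 = med_output(rec2, bigger)
        np.testing.assert_allclose(out.traces, out2.traces, atol=1e-9)

    def test_zero_kernel_spike_channel_shifts_by_class_constant(
        self, toy_model, toy_recording
    ):
        extra = PointProcessChannelModel(
            TemporalResponse(0.0, np.zeros(10), toy_model.delta),
            np.array([0.5, 1.5]),
            np.log(20.0),
        )
        bigger = MultimodalModel(
            toy_model.pp_channels + [extra],
            toy_model.gauss_channels,
            2,
            toy_model.delta,
        )
        rec2 = MultimodalRecording(
            np.vstack(
                [toy_recording.spikes, np.zeros(toy_recording.n_bins, dtype=np.int8)]
            ),
            toy_recording.fields,
            toy_recording.duration,
            toy_recording.delta,
        )
        out = med_output(toy_recording, toy_model)
        out2 = med_output(rec2, bigger)
        diff = out2.traces - out.traces
        # constant -Q = -e^alpha * T per class (zero kernel: same for both)
        np.testing.assert_allclose(diff, -20.0 * toy_recording.duration, rtol=1e-9)

    def test_causal_output_is_shifted_acausal(self, toy_model, toy_recording):
        out = med_output(toy_recording, toy_model)
        out_c = med_output(toy_recording, toy_model, causal=True)
        t2 = max(ch.r.stop for ch in toy_model.pp_channels + toy_model.gauss_channels)
        d = int(round(t2 / toy_model.delta))
        assert out_c.delay == pytest.approx(t2)
        np.testing.assert_allclose(out_c.traces[:, d:], out.traces[:, : -d])
        assert np.all(out_c.traces[:, :d] == 0)


class TestDetections:
    def _hand_output(self, x, delta=0.001):
        return MedOutput(np.vstack([x]), delta)

    def test_all_below_threshold_empty(self):
        out = self._hand_output(np.sin(np.linspace(0, 20, 2000)))
        assert detect_and_classify(out, threshold=2.0) == []

    def test_greedy_suppression_keeps_taller_of_close_peaks(self):
        x = np.zeros(1000)
        x[400] = 3.0  # peaks 50 ms apart at 1 ms bins
        x[450] = 5.0
        out = self._hand_output(x)
        dets = detect_and_classify(out, threshold=1.0, min_separation=0.2)
        assert len(dets) == 1
        assert dets[0].time == pytest.approx(0.450)
        assert dets[0].score == 5.0

    def test_high_snr_events_detected_and_classified(self):
        from medetect.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n_events=2, snr=10.0, seed=6)
        model, events, rec = simulate_dataset(cfg)
        out = med_output(rec, model)
        x = out.max_trace
        bins = np.arange(out.n_bins)
        near = np.zeros(out.n_bins, dtype=bool)
        for t in events.times:
            near |= np.abs(bins * cfg.delta - t) <= 0.2
        noise_ceiling = x[~near].max()
        event_floor = min(
            x[np.abs(bins * cfg.delta - t) <= 0.2].max() for t in events.times
        )
        assert noise_ceiling < event_floor  # events separable from background
        thr = 0.5 * (noise_ceiling + event_floor)
        dets = detect_and_classify(out, thr, min_separation=0.2)
        assert len(dets) == 2
        for det, t, c in zip(dets, events.times, events.classes):
            assert abs(det.time - t) < 0.2
            assert det.class_idx == c

    def test_causal_detection_times_compensate_delay(self):
        from medetect.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n_events=2, snr=10.0, seed=6)
        model, events, rec = simulate_dataset(cfg)
        out_a = med_output(rec, model)
        out_c = med_output(rec, model, causal=True)
        thr = 0.5 * (np.median(out_a.max_trace) + out_a.max_trace.max())
        t_a = [d.time for d in detect_and_classify(out_a, thr)]
        t_c = [d.time for d in detect_and_classify(out_c, thr)]
        np.testing.assert_allclose(t_a, t_c, atol=1e-9)

    def test_auto_threshold_separates_bimodal_peak_heights(self, rng):
        # noise ripple peaks near 1, twenty event peaks near 10
        x = np.zeros(20000)
        x[np.arange(100, 20000, 37)] = rng.uniform(0.5, 1.5, len(range(100, 20000, 37)))
        x[np.arange(500, 20000, 1000)] = rng.uniform(9.0, 11.0, 20)
        out = MedOutput(np.vstack([x]), 0.001)
        thr = auto_threshold(out)
        assert 1.5 < thr < 9.0

    def test_edge_flag_near_recording_boundary(self):
        x = np.zeros(1000)
        x[50] = 4.0  # within the 0.3 s support of the start
        x[500] = 4.0
        out = MedOutput(np.vstack([x]), 0.001, support=0.3)
        dets = detect_and_classify(out, threshold=1.0)
        assert [d.edge for d in dets] == [True, False]
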
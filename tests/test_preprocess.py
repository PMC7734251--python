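"""Unit and property tests for the EMG conditioning chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fatigueloop.preprocess import (
    BurstAnnotation,
    EMGRecording,
    EnvelopeSignal,
    bandpass_filter,
    burst_f1,
    burst_threshold,
    detect_bursts,
    envelope,
    mask_artifacts,
    rectify,
)

FS = 5000.0


def _rec(x, fs=FS, roles=("AF",)):
    return EMGRecording(data=np.atleast_2d(x), fs=fs, roles=roles)


class TestBandpass:
    def test_midband_tone_preserved(self):
        t = np.arange(0, 2, 1 / FS)
        rec = _rec(np.sin(2 * np.pi * 1000 * t))
        out = bandpass_filter(rec).data[0][2000:-2000]  # skip edge transients
        amp = (out.max() - out.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_subband_tone_attenuated(self):
        t = np.arange(0, 2, 1 / FS)
        rec = _rec(np.sin(2 * np.pi * 10 * t))
        out = bandpass_filter(rec).data[0]
        assert np.abs(out).max() < 0.1  # > 90 % attenuation

    def test_dc_removed(self):
        rec = _rec(np.full(5000, 3.3))
        out = bandpass_filter(rec).data[0]
        assert np.abs(out).max() < 1e-6

    def test_high_edge_above_nyquist_rejected(self):
        rec = _rec(np.zeros(1000), fs=3000.0)
        with pytest.raises(ValueError, match="2000.*1500|1500.*2000"):
            bandpass_filter(rec, 60, 2000)

    def test_causal_mode_differs_from_zero_phase(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal(5000))
        a = bandpass_filter(rec, zero_phase=True).data[0]
        b = bandpass_filter(rec, zero_phase=False).data[0]
        assert not np.allclose(a, b)


class TestRectifyEnvelope:
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=30)
    def test_rectify_is_abs_and_idempotent(self, values):
        rec = _rec(np.array(values))
        once = rectify(rec)
        assert np.array_equal(once.data, np.abs(rec.data))
        assert np.array_equal(rectify(once).data, once.data)

    def test_envelope_of_constant_is_constant(self):
        rec = _rec(np.full(1000, 0.7))
        env = envelope(rec, window_ms=25)
        assert np.allclose(env.values, 0.7)
        assert env.values.size == 1000

    def test_envelope_impulse_plateau(self):
        # 25 ms at 5 kHz = 125 samples: a unit impulse averages to 1/125
        x = np.zeros(1000)
        x[500] = 1.0
        env = envelope(_rec(x), window_ms=25)
        assert env.values.max() == pytest.approx(1 / 125)

    def test_envelope_rejects_unrectified_input(self):
        with pytest.raises(ValueError, match="rectified"):
            envelope(_rec(np.array([-1.0, 1.0] * 600)))

    def test_envelope_separates_bursts_from_gaps(self, short_gait_session,
                                                 rest_recording):
        rec, truth = short_gait_session
        env = envelope(rectify(rec), channel="AF")
        t = np.arange(env.values.size) / rec.fs
        inside = np.zeros(t.size, dtype=bool)
        for a, b in truth.bursts["AF"]:
            inside |= (t >= a) & (t < b)
        assert env.values[inside].mean() > 10 * env.values[~inside].mean()


class TestThresholdAndDetection:
    def test_threshold_is_mean_plus_1p5_sd(self):
        v = np.tile([0.01, 0.03], 5000)  # mean 0.02, SD 0.01
        env = EnvelopeSignal(values=v, fs=FS)
        assert burst_threshold(env) == pytest.approx(0.035)

    def test_threshold_constant_envelope(self):
        env = EnvelopeSignal(values=np.full(10000, 0.02), fs=FS)
        assert burst_threshold(env) == pytest.approx(0.02)

    def test_threshold_invariant_to_reordering(self, rng):
        v = rng.exponential(0.01, 10000)
        a = burst_threshold(EnvelopeSignal(values=v, fs=FS))
        b = burst_threshold(EnvelopeSignal(values=rng.permutation(v), fs=FS))
        assert a == pytest.approx(b)

    def test_threshold_requires_one_second(self):
        with pytest.raises(ValueError, match="1 s"):
            burst_threshold(EnvelopeSignal(values=np.ones(100), fs=FS))

    def test_all_subthreshold_yields_no_bursts(self):
        env = EnvelopeSignal(values=np.full(5000, 0.001), fs=FS)
        assert len(detect_bursts(env, threshold=0.01)) == 0

    def test_two_rect_pulses_detected(self):
        v = np.zeros(5000)
        v[1000:1500] = 1.0  # 100 ms
        v[3000:3500] = 1.0
        ann = detect_bursts(EnvelopeSignal(values=v, fs=FS), threshold=0.5)
        assert len(ann) == 2
        assert ann.intervals[0] == pytest.approx([0.2, 0.3], abs=0.001)
        assert ann.intervals[1] == pytest.approx([0.6, 0.7], abs=0.001)

    def test_short_gap_merged_short_run_dropped(self):
        v = np.zeros(5000)
        v[1000:1100] = 1.0
        v[1130:1300] = 1.0  # 6 ms gap -> merged
        v[3000:3040] = 1.0  # 8 ms run -> dropped
        ann = detect_bursts(EnvelopeSignal(values=v, fs=FS), threshold=0.5,
                            min_duration_ms=15, merge_gap_ms=10)
        assert len(ann) == 1
        assert ann.intervals[0] == pytest.approx([0.2, 0.26], abs=0.001)

    @given(
        st.lists(st.sampled_from([0.0, 0.2, 1.0]), min_size=1, max_size=120),
        st.sampled_from([0.0, 2.0, 6.0]),
        st.sampled_from([0.0, 3.0]),
    )
    @settings(derandomize=True, max_examples=80)
    def test_matches_brute_force_scan(self, values, min_ms, gap_ms):
        """Vectorized detection equals an exhaustive per-sample scan."""
        fs = 1000.0
        env = EnvelopeSignal(values=np.array(values), fs=fs)
        ann = detect_bursts(env, threshold=0.5, min_duration_ms=min_ms,
                            merge_gap_ms=gap_ms)
        expected = _brute_force_bursts(np.array(values), 0.5, fs, min_ms, gap_ms)
        assert np.allclose(ann.intervals, expected)

    def test_scaling_signal_and_threshold_together(self, short_gait_session,
                                                   rest_recording):
        rec, _ = short_gait_session
        env = envelope(rectify(rec), channel="AF")
        thr = burst_threshold(envelope(rectify(rest_recording), channel="AF"))
        a = detect_bursts(env, thr)
        scaled = EnvelopeSignal(values=env.values * 7.5, fs=env.fs, role=env.role)
        b = detect_bursts(scaled, thr * 7.5)
        assert np.allclose(a.intervals, b.intervals)


def _brute_force_bursts(values, thr, fs, min_ms, gap_ms):
    """Independent oracle: per-sample scan, then merge, then filter."""
    runs = []
    start = None
    for i, v in enumerate(values):
        if v >= thr and start is None:
            start = i
        elif v < thr and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(values)])
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < gap_ms * 1e-3 * fs:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kept = [r for r in merged if r[1] - r[0] >= min_ms * 1e-3 * fs]
    return np.array(kept, dtype=float).reshape(-1, 2) / fs


class TestArtifacts:
    def test_clean_signal_empty_mask(self, rest_recording):
        mask = mask_artifacts(rest_recording, clip_level=1.0)
        assert not mask.any()
        assert mask.shape == rest_recording.data.shape

    def test_injected_transient_flagged_with_spread(self, rest_recording):
        data = rest_recording.data.copy()
        fs = rest_recording.fs
        data[0, 10000:10250] = 5.0  # 50-ms square transient
        rec = rest_recording.replace(data=data)
        mask = mask_artifacts(rec, clip_level=1.0, spread_ms=50.0)
        assert mask[0, 10000:10250].all()
        assert mask[0, 10000 - int(0.04 * fs)]  # dilated before onset
        assert not mask[0, 10000 - int(0.2 * fs)]
        assert not mask[1].any()


class TestTypesValidation:
    def test_recording_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            EMGRecording(data=np.array([[0.0, np.nan]]), fs=FS, roles=("AF",))

    def test_annotation_rejects_overlap(self):
        with pytest.raises(ValueError, match="sorted|overlap"):
            BurstAnnotation(intervals=[[0.0, 1.0], [0.5, 2.0]], role="AF",
                            threshold=0.1)

    def test_burst_f1_boundary_tolerance(self):
        truth = np.array([[1.0, 1.2], [2.0, 2.2]])
        near = [[1.01, 1.21], [2.02, 2.18]]
        assert burst_f1(near, truth, tolerance_s=0.03) == 1.0
        assert burst_f1([[1.2, 1.4]], truth, tolerance_s=0.03) == 0.0
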
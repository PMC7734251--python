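"""EMG conditioning chain: band-pass filter, rectification, envelope, bursts.

The chain mirrors a real-time intramuscular EMG monitor for treadmill
gait: raw differential EMG is band-pass filtered (fourth-order Butterworth,
60–2000 Hz), rectified, smoothed with a 25-ms moving average to form an
envelope, and muscle-contraction bursts are segmented wherever the envelope
exceeds a threshold computed from a resting segment (resting mean plus 1.5
resting standard deviations).

Time coordinates are seconds from session start; burst intervals are
half-open ``[onset, offset)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import ndimage

DEFAULT_BAND = (60.0, 2000.0)
DEFAULT_FILTER_ORDER = 4
DEFAULT_ENVELOPE_MS = 25.0
DEFAULT_MIN_BURST_MS = 15.0
DEFAULT_MERGE_GAP_MS = 10.0

AF = "AF"  # affected (paretic) hind limb
UN = "UN"  # unaffected hind limb


@dataclass
class EMGRecording:
    """Multi-channel EMG in millivolts with channel roles.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in mV.
    fs
        Sampling rate in Hz.
    roles
        Channel role labels, e.g. ``("AF", "UN")``; one per row of ``data``.
    meta
        Free-form session metadata (subject id, group, day, schedule, ...).
    """

    data: np.ndarray
    fs: float
    roles: tuple[str, ...] = (AF, UN)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if len(self.roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.roles)} roles for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EMG samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, role: str) -> np.ndarray:
        """Return the 1-D sample array for a channel role."""
        try:
            idx = self.roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}; have {self.roles}")
        return self.data[idx]

    def replace(self, **kwargs) -> "EMGRecording":
        return dataclasses.replace(self, **kwargs)


@dataclass
class EnvelopeSignal:
    """Nonnegative EMG envelope (mV) for one channel."""

    values: np.ndarray
    fs: float
    window_ms: float = DEFAULT_ENVELOPE_MS
    role: str = AF

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


@dataclass
class BurstAnnotation:
    """Detected burst intervals for one channel, half-open ``[onset, offset)`` in s."""

    intervals: np.ndarray  # shape (n, 2), seconds
    role: str
    threshold: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 0] >= iv[:, 1]):
                raise ValueError("burst onsets must precede offsets")
            if np.any(np.diff(iv[:, 0]) < 0) or np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("burst intervals must be sorted and non-overlapping")
        self.intervals = iv

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def __len__(self) -> int:
        return self.intervals.shape[0]


def _design_bandpass(low: float, high: float, order: int, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(
            f"band-pass high edge {high} Hz must be below the Nyquist "
            f"frequency {nyq} Hz (fs={fs} Hz)"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    recording: EMGRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
    zero_phase: bool = True,
) -> EMGRecording:
    """Fourth-order Butterworth band-pass of every channel.

    ``zero_phase=True`` (offline default) applies the filter forward and
    backward so burst onsets are not delayed by group delay; set it to
    ``False`` for the causal filtering a streaming system would apply.
    """
    sos = _design_bandpass(low, high, order, recording.fs)
    if zero_phase:
        out = sps.sosfiltfilt(sos, recording.data, axis=1)
    else:
        out = sps.sosfilt(sos, recording.data, axis=1)
    return recording.replace(data=out)


def rectify(recording: EMGRecording) -> EMGRecording:
    """Full-wave rectification: elementwise absolute value."""
    return recording.replace(data=np.abs(recording.data))


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    # centered moving average; the window shrinks at the edges so no
    # fabricated samples enter the estimate
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    half_lo = (win - 1) // 2
    half_hi = win // 2
    idx = np.arange(n)
    lo = np.clip(idx - half_lo, 0, n)
    hi = np.clip(idx + half_hi + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def envelope(
    recording: EMGRecording,
    window_ms: float = DEFAULT_ENVELOPE_MS,
    channel: str | None = None,
) -> EnvelopeSignal:
    """Moving-average envelope of a rectified channel.

    The window is centered and shrinks at the session edges; output length
    equals input length.  Input must already be rectified (nonnegative).
    """
    if channel is None:
        if len(recording.roles) != 1:
            raise ValueError(
                "recording has multiple channels; pass channel='AF' or 'UN'"
            )
        channel = recording.roles[0]
    x = recording.channel(channel)
    if np.any(x < 0):
        raise ValueError("envelope input must be rectified (nonnegative)")
    win = int(round(window_ms * 1e-3 * recording.fs))
    if win < 1:
        raise ValueError(
            f"window of {window_ms} ms spans less than one sample at fs={recording.fs}"
        )
    return EnvelopeSignal(
        values=_moving_average(x, win),
        fs=recording.fs,
        window_ms=window_ms,
        role=channel,
    )


def burst_threshold(resting_envelope: EnvelopeSignal, k: float = 1.5) -> float:
    """Burst threshold: resting-envelope mean plus ``k`` standard deviations."""
    v = resting_envelope.values
    if v.size == 0:
        raise ValueError("resting segment is empty")
    if v.size < resting_envelope.fs:  # < 1 s
        raise ValueError("resting segment must be at least 1 s long")
    return float(np.mean(v) + k * np.std(v))


def detect_bursts(
    env: EnvelopeSignal,
    threshold: float,
    min_duration_ms: float = DEFAULT_MIN_BURST_MS,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
    mask: np.ndarray | None = None,
) -> BurstAnnotation:
    """Segment maximal supra-threshold runs of the envelope into bursts.

    Gaps shorter than ``merge_gap_ms`` between consecutive runs are bridged,
    then runs shorter than ``min_duration_ms`` are discarded.  Samples where
    ``mask`` is True (artifacts) are excluded before segmentation.
    """
    fs = env.fs
    above = env.values >= threshold
    if mask is not None:
        above = above & ~np.asarray(mask, dtype=bool)
    runs = _bool_runs(above)
    if runs.size:
        gap = int(round(merge_gap_ms * 1e-3 * fs))
        runs = _merge_runs(runs, gap)
        min_len = int(round(min_duration_ms * 1e-3 * fs))
        runs = runs[(runs[:, 1] - runs[:, 0]) >= min_len]
    intervals = runs / fs
    return BurstAnnotation(
        intervals=intervals,
        role=env.role,
        threshold=threshold,
        params={
            "min_duration_ms": min_duration_ms,
            "merge_gap_ms": merge_gap_ms,
            "window_ms": env.window_ms,
        },
    )


def _bool_runs(b: np.ndarray) -> np.ndarray:
    """Start/stop sample indices (half-open) of True runs in a boolean array."""
    d = np.diff(b.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if b.size and b[0]:
        starts = np.concatenate(([0], starts))
    if b.size and b[-1]:
        stops = np.concatenate((stops, [b.size]))
    return np.column_stack((starts, stops)).astype(float)


def _merge_runs(runs: np.ndarray, max_gap: int) -> np.ndarray:
    merged = [runs[0].copy()]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1][1] = stop
        else:
            merged.append(np.array([start, stop]))
    return np.array(merged)


def mask_artifacts(
    recording: EMGRecording,
    clip_level: float,
    spread_ms: float = 50.0,
) -> np.ndarray:
    """Flag motion-artifact samples exceeding ``clip_level`` mV.

    An automated surrogate for manual artifact inspection: any sample whose
    absolute value exceeds ``clip_level`` is flagged, and flags are dilated
    by ``spread_ms`` on each side.  Returns a boolean array shaped like
    ``recording.data``; flagged spans should be excluded from MPF windows
    and burst statistics.
    """
    hot = np.abs(recording.data) > clip_level
    if not hot.any():
        return hot
    spread = int(round(spread_ms * 1e-3 * recording.fs))
    if spread > 0:
        structure = np.ones((1, 2 * spread + 1), dtype=bool)
        hot = ndimage.binary_dilation(hot, structure=structure)
    return hot


def suggest_clip_level(calibration: EMGRecording, factor: float = 3.0) -> float:
    """Artifact clip level: ``factor`` times the 99.9th |amplitude| percentile
    of a clean calibration segment."""
    return factor * float(np.percentile(np.abs(calibration.data), 99.9))


def burst_f1(
    detected: BurstAnnotation | Sequence[Sequence[float]],
    truth: np.ndarray,
    tolerance_s: float = 0.030,
) -> float:
    """F1 score of detected vs ground-truth burst intervals.

    A detected burst matches a true burst when both boundaries agree within
    ``tolerance_s`` (greedy one-to-one matching in time order).
    """
    det = detected.intervals if isinstance(detected, BurstAnnotation) else np.asarray(detected, float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if det.shape[0] == 0 and tru.shape[0] == 0:
        return 1.0
    if det.shape[0] == 0 or tru.shape[0] == 0:
        return 0.0
    used = np.zeros(tru.shape[0], dtype=bool)
    tp = 0
    for onset, offset in det:
        cand = np.flatnonzero(
            ~used
            & (np.abs(tru[:, 0] - onset) <= tolerance_s)
            & (np.abs(tru[:, 1] - offset) <= tolerance_s)
        )
        if cand.size:
            used[cand[0]] = True
            tp += 1
    precision = tp / det.shape[0]
    recall = tp / tru.shape[0]
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
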
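"""Mean power frequency (MPF) fatigue metrics on 4-s analysis windows.

MPF is the power-spectrum-weighted mean frequency of an EMG segment,

    MPF = (integral of f * s(f) df) / (integral of s(f) df),

with ``s(f)`` the power spectral density; it declines as a muscle fatigues.
Fatigue is tracked as the *MPF drop rate*,

    drop rate = (baseline MPF - running MPF) / baseline MPF * 100 %,

where the baseline is the mean MPF over the first 20 s of the session's
treadmill-on time (five 4-s windows).  The drop rate is signed: a running
MPF above baseline yields a negative value.

The spectral estimator defaults to Welch's method (1-s segments, 50 %
overlap, Hann taper) within each 4-s window; a raw periodogram is
selectable for cross-checks.  Spectral integration is clipped to the
band-pass edges so out-of-band estimator leakage cannot bias the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from fatigueloop.preprocess import DEFAULT_BAND, EMGRecording

MPF_WINDOW_S = 4.0
BASELINE_WINDOWS = 5  # first 20 s of treadmill-on time


def compute_mpf(
    segment: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    method: str = "welch",
) -> float:
    """Power-weighted mean frequency of one EMG segment, in Hz.

    Returns NaN for a segment with (numerically) zero in-band power; the
    value is undefined there, not zero.
    """
    x = np.asarray(segment, dtype=float).ravel()
    if x.size < 0.5 * fs:
        raise ValueError("segment must be at least 0.5 s long")
    if method == "welch":
        nperseg = min(x.size, int(round(fs)))  # 1-s segments
        f, s = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                         noverlap=nperseg // 2)
    elif method == "periodogram":
        f, s = sps.periodogram(x, fs=fs)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    inband = (f >= band[0]) & (f <= band[1])
    f, s = f[inband], s[inband]
    total = np.trapezoid(s, f)
    if total <= 0 or not np.isfinite(total):
        return float("nan")
    return float(np.trapezoid(f * s, f) / total)


def drop_rate(baseline_mpf_hz: float, running_mpf_hz: float) -> float:
    """MPF drop rate in percent; negative when running MPF exceeds baseline."""
    if not baseline_mpf_hz > 0:
        raise ValueError(f"baseline MPF must be positive, got {baseline_mpf_hz}")
    return (baseline_mpf_hz - running_mpf_hz) / baseline_mpf_hz * 100.0


@dataclass
class MPFSeries:
    """Per-window MPF values for one channel at the 4-s cadence.

    ``times_run`` are window starts in treadmill-on (accumulated running)
    time; ``times_wall`` are window starts on the session wall clock.
    Windows during rest or artifact-masked spans are absent (not recorded
    as zero).  ``drop_rates`` is populated by :func:`with_drop_rates`.
    """

    times_run: np.ndarray
    times_wall: np.ndarray
    mpf_hz: np.ndarray
    channel: str
    window_s: float = MPF_WINDOW_S
    baseline_hz: float | None = None
    drop_rates: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_run = np.asarray(self.times_run, dtype=float)
        self.times_wall = np.asarray(self.times_wall, dtype=float)
        self.mpf_hz = np.asarray(self.mpf_hz, dtype=float)
        if not (self.times_run.shape == self.times_wall.shape == self.mpf_hz.shape):
            raise ValueError("times and MPF arrays must have matching shapes")

    def __len__(self) -> int:
        return self.mpf_hz.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_run_s": self.times_run,
            "time_wall_s": self.times_wall,
            "mpf_hz": self.mpf_hz,
            "channel": self.channel,
        })
        if self.drop_rates is not None:
            df["drop_rate_pct"] = self.drop_rates
        return df


def mpf_series(
    recording: EMGRecording,
    schedule: list | None = None,
    channel: str = "AF",
    window_s: float = MPF_WINDOW_S,
    band: tuple[float, float] = DEFAULT_BAND,
    method: str = "welch",
    mask: np.ndarray | None = None,
) -> MPFSeries:
    """MPF per contiguous 4-s window of treadmill-on time.

    ``schedule`` is a list of run/rest segments (objects with ``kind``,
    ``start_s``, ``end_s``, as produced by the session controllers); if
    omitted, the whole recording is treated as one run segment.  Windows
    are tiled from the start of each run segment; a window that would
    overlap a rest boundary is excluded.  Windows intersecting ``mask``
    (boolean per-sample artifact flags for this channel) get NaN.
    """
    fs = recording.fs
    x = recording.channel(channel)
    if schedule is None:
        from fatigueloop.control import Segment
        schedule = [Segment("run", 0.0, recording.duration)]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = mask[recording.roles.index(channel)]
    nwin = int(round(window_s * fs))
    times_run, times_wall, values = [], [], []
    run_elapsed = 0.0
    for seg in schedule:
        if seg.kind != "run":
            continue
        start = int(round(seg.start_s * fs))
        stop = int(round(seg.end_s * fs))
        n_full = (stop - start) // nwin
        for k in range(n_full):
            a = start + k * nwin
            b = a + nwin
            if mask is not None and mask[a:b].any():
                v = float("nan")
            else:
                v = compute_mpf(x[a:b], fs, band=band, method=method)
            times_wall.append(a / fs)
            times_run.append(run_elapsed + k * window_s)
            values.append(v)
        run_elapsed += seg.end_s - seg.start_s
    return MPFSeries(
        times_run=np.array(times_run),
        times_wall=np.array(times_wall),
        mpf_hz=np.array(values),
        channel=channel,
        window_s=window_s,
        params={"band": band, "method": method},
    )


def baseline_mpf(series: MPFSeries, n_windows: int = BASELINE_WINDOWS) -> float:
    """Session baseline: mean MPF of the first ``n_windows`` 4-s windows (20 s)."""
    if len(series) < n_windows:
        raise ValueError(
            f"need at least {n_windows} MPF windows for a baseline, "
            f"have {len(series)}"
        )
    first = series.mpf_hz[:n_windows]
    if np.isnan(first).any():
        raise ValueError("baseline windows contain undefined MPF values")
    return float(np.mean(first))


def with_drop_rates(series: MPFSeries, baseline_hz: float | None = None) -> MPFSeries:
    """Return a copy of ``series`` with baseline and drop-rate columns filled."""
    if baseline_hz is None:
        baseline_hz = baseline_mpf(series)
    rates = np.array([
        drop_rate(baseline_hz, v) if np.isfinite(v) else float("nan")
        for v in series.mpf_hz
    ])
    return MPFSeries(
        times_run=series.times_run,
        times_wall=series.times_wall,
        mpf_hz=series.mpf_hz,
        channel=series.channel,
        window_s=series.window_s,
        baseline_hz=float(baseline_hz),
        drop_rates=rates,
        params=dict(series.params),
    )
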
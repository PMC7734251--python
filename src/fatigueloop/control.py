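"""Closed-loop (FAT-C) and forced (FOR-T) treadmill session controllers.

The controller's native clock is the 4-s MPF analysis window.  In a
fatigue-controlled (FAT-C) session the monitored channel's MPF drop rate is
evaluated once per window against a moderate-fatigue threshold (default
11 %); the first exceedance halts the belt, raises an alarm, inserts a
fixed rest (default 3 min), and running then resumes against the *original*
session baseline (one baseline per session).  The session ends when the
accumulated treadmill-on time reaches the dose target (default 30 min at
16 m/min), so FAT-C and FOR-T deliver identical running dose and speed and
differ only in fatigue management.

The forced (FOR-T) session is a single continuous run of the same dose;
the drop-rate series is still recorded for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fatigueloop.fatigue import (
    BASELINE_WINDOWS,
    MPF_WINDOW_S,
    MPFSeries,
    compute_mpf,
    drop_rate,
    with_drop_rates,
)
from fatigueloop.preprocess import AF, DEFAULT_BAND, EMGRecording, bandpass_filter

VALID_GROUPS = ("CTRL", "FOR-T", "FAT-C")


@dataclass
class SessionProtocol:
    """Session-level training protocol configuration.

    Defaults mirror the study protocol: belt speed 16 m/min, accumulated
    running target 30 min, 3-min rest on each fatigue trigger, 11 % MPF
    drop-rate threshold monitored on the affected (AF) limb.
    """

    group: str = "FAT-C"
    belt_speed: float = 16.0  # m/min
    run_target_min: float = 30.0
    rest_min: float = 3.0
    threshold_pct: float = 11.0
    monitored: str = AF
    max_wall_min: float = 120.0
    mpf_window_s: float = MPF_WINDOW_S
    baseline_windows: int = BASELINE_WINDOWS
    band: tuple[float, float] = DEFAULT_BAND
    schedule: list | None = None  # optional explicit [(kind, duration_s), ...]

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected {VALID_GROUPS}")
        if self.threshold_pct <= 0:
            raise ValueError("fatigue threshold must be positive")
        if self.rest_min <= 0 or self.run_target_min <= 0:
            raise ValueError("rest and run-target durations must be positive")


@dataclass
class Segment:
    """One contiguous run or rest span on the session wall clock, seconds."""

    kind: str  # "run" | "rest"
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TriggerEvent:
    """A fatigue-threshold crossing that halted the belt."""

    time_s: float  # wall-clock time at the end of the triggering window
    drop_rate_pct: float
    window_index: int  # index into the run-window sequence


@dataclass
class ControllerLog:
    """Auditable record of one simulated session."""

    protocol: SessionProtocol
    segments: list = field(default_factory=list)
    triggers: list = field(default_factory=list)
    series: MPFSeries | None = None
    baseline_hz: float | None = None
    completed: bool = True
    recording: EMGRecording | None = None

    @property
    def accumulated_run_s(self) -> float:
        return sum(s.duration_s for s in self.segments if s.kind == "run")

    @property
    def wall_time_s(self) -> float:
        return self.segments[-1].end_s if self.segments else 0.0

    @property
    def n_rests(self) -> int:
        return sum(1 for s in self.segments if s.kind == "rest")

    def validate(self) -> None:
        """Check the log's structural invariants; raises on violation."""
        t = 0.0
        for seg in self.segments:
            if abs(seg.start_s - t) > 1e-9 or seg.end_s <= seg.start_s:
                raise ValueError("segments must be contiguous and non-empty")
            t = seg.end_s
        rest_starts = [s.start_s for s in self.segments if s.kind == "rest"]
        trigger_times = [tr.time_s for tr in self.triggers]
        if self.protocol.group == "FAT-C":
            for rs in rest_starts:
                if not any(abs(rs - tt) < 1e-6 for tt in trigger_times):
                    raise ValueError(f"rest at {rs} s has no matching trigger")
            for tr in self.triggers:
                if tr.drop_rate_pct < self.protocol.threshold_pct:
                    raise ValueError(
                        f"trigger at {tr.time_s} s fired below threshold "
                        f"({tr.drop_rate_pct:.2f} < {self.protocol.threshold_pct})"
                    )


def _window_mpf(window: np.ndarray, fs: float,
                band: tuple[float, float] = DEFAULT_BAND) -> float:
    """The controller's per-window measurement chain: band-pass then MPF."""
    rec = EMGRecording(data=window[None, :], fs=fs, roles=("X",))
    filt = bandpass_filter(rec, band[0], band[1])
    return compute_mpf(filt.data[0], fs, band=band)


def _run_session(protocol: SessionProtocol, source, closed_loop: bool,
                 keep_recording: bool = True) -> ControllerLog:
    fs = source.fs
    w = protocol.mpf_window_s
    ch_idx = 0 if protocol.monitored == AF else 1
    target_windows = int(round(protocol.run_target_min * 60.0 / w))
    rest_s = protocol.rest_min * 60.0

    chunks: list[np.ndarray] = []
    segments: list[Segment] = []
    triggers: list[TriggerEvent] = []
    times_run: list[float] = []
    times_wall: list[float] = []
    mpfs: list[float] = []

    baseline: float | None = None
    t_wall = 0.0
    run_windows_done = 0
    seg_start = 0.0
    completed = True

    def close_run_segment(end: float) -> None:
        if end > seg_start + 1e-9:
            segments.append(Segment("run", seg_start, end))

    while run_windows_done < target_windows:
        if t_wall >= protocol.max_wall_min * 60.0:
            completed = False
            break
        window = source.next_window(w, running=True)
        if keep_recording:
            chunks.append(window)
        v = _window_mpf(window[ch_idx], fs, protocol.band)
        times_wall.append(t_wall)
        times_run.append(run_windows_done * w)
        mpfs.append(v)
        run_windows_done += 1
        t_wall += w

        if baseline is None and run_windows_done == protocol.baseline_windows:
            baseline = float(np.nanmean(mpfs[: protocol.baseline_windows]))

        if (
            closed_loop
            and baseline is not None
            and run_windows_done > protocol.baseline_windows
            and np.isfinite(v)
        ):
            dr = drop_rate(baseline, v)
            if dr >= protocol.threshold_pct and run_windows_done < target_windows:
                triggers.append(
                    TriggerEvent(
                        time_s=t_wall, drop_rate_pct=dr,
                        window_index=run_windows_done - 1,
                    )
                )
                close_run_segment(t_wall)
                # rest is exact on the simulation clock, not window-quantized
                rest_chunk = source.next_window(rest_s, running=False)
                if keep_recording:
                    chunks.append(rest_chunk)
                t_wall += rest_s
                segments.append(Segment("rest", segments[-1].end_s, t_wall))
                seg_start = t_wall

    close_run_segment(t_wall)

    series = MPFSeries(
        times_run=np.array(times_run),
        times_wall=np.array(times_wall),
        mpf_hz=np.array(mpfs),
        channel=protocol.monitored,
        window_s=w,
        params={"band": protocol.band, "method": "welch"},
    )
    if baseline is not None:
        series = with_drop_rates(series, baseline)

    recording = None
    if keep_recording and chunks:
        recording = EMGRecording(
            data=np.concatenate(chunks, axis=1),
            fs=fs,
            meta={
                "group": protocol.group,
                "schedule": [(s.kind, s.start_s, s.end_s) for s in segments],
            },
        )
    log = ControllerLog(
        protocol=protocol,
        segments=segments,
        triggers=triggers,
        series=series,
        baseline_hz=baseline,
        completed=completed,
        recording=recording,
    )
    log.validate()
    return log


def run_fatc_session(protocol: SessionProtocol, source,
                     keep_recording: bool = True) -> ControllerLog:
    """Run one closed-loop fatigue-controlled session.

    ``source`` is a streaming EMG supplier with the
    :class:`~fatigueloop.synthetic.GaitEMGSource` interface
    (``next_window(duration_s, running)`` and an ``fs`` attribute).  The
    monitored channel's drop rate is checked once per 4-s window after the
    20-s baseline is established; each exceedance triggers an alarm and a
    3-min rest, and the session completes when the accumulated running time
    reaches the protocol target.
    """
    if protocol.group != "FAT-C":
        raise ValueError(f"protocol group must be FAT-C, got {protocol.group!r}")
    return _run_session(protocol, source, closed_loop=True,
                        keep_recording=keep_recording)


def run_fort_session(protocol: SessionProtocol, source,
                     keep_recording: bool = True) -> ControllerLog:
    """Run one forced continuous session (no rests, drop rate still logged)."""
    if protocol.group != "FOR-T":
        raise ValueError(f"protocol group must be FOR-T, got {protocol.group!r}")
    return _run_session(protocol, source, closed_loop=False,
                        keep_recording=keep_recording)


@dataclass
class ReplayReport:
    """Offline re-validation of a controller log against its recording."""

    n_windows: int
    disagreements: list  # (window_index, kind, detail)
    max_mpf_diff_hz: float

    @property
    def ok(self) -> bool:
        return not self.disagreements


def replay_session(log: ControllerLog, recording: EMGRecording,
                   atol_hz: float = 1e-6) -> ReplayReport:
    """Recompute every windowed drop rate offline and audit each decision.

    Verifies that (a) offline per-window MPFs match the online log, (b)
    every trigger fired at or above threshold, and (c) every rest segment
    is preceded by a trigger.  Returns a report listing any disagreement.
    """
    proto = log.protocol
    expected = log.wall_time_s
    if abs(recording.duration - expected) > proto.mpf_window_s:
        raise ValueError(
            f"recording duration {recording.duration:.1f} s does not match "
            f"log wall time {expected:.1f} s"
        )
    # mirror the online chain exactly: per-window band-pass, then MPF,
    # windows tiled from the start of each run segment
    fs = recording.fs
    x = recording.channel(proto.monitored)
    nwin = int(round(proto.mpf_window_s * fs))
    off_times, off_mpfs = [], []
    run_elapsed = 0.0
    for seg in log.segments:
        if seg.kind != "run":
            continue
        a0 = int(round(seg.start_s * fs))
        for k in range((int(round(seg.end_s * fs)) - a0) // nwin):
            a = a0 + k * nwin
            off_times.append(run_elapsed + k * proto.mpf_window_s)
            off_mpfs.append(_window_mpf(x[a:a + nwin], fs, proto.band))
        run_elapsed += seg.duration_s
    offline = MPFSeries(
        times_run=np.array(off_times),
        times_wall=np.array(off_times),
        mpf_hz=np.array(off_mpfs),
        channel=proto.monitored,
        window_s=proto.mpf_window_s,
    )
    disagreements = []
    n = min(len(offline), len(log.series))
    diffs = np.abs(offline.mpf_hz[:n] - log.series.mpf_hz[:n])
    max_diff = float(np.nanmax(diffs)) if n else 0.0
    for i in np.flatnonzero(diffs > atol_hz):
        disagreements.append((int(i), "mpf_mismatch",
                              f"offline {offline.mpf_hz[i]:.6f} Hz vs "
                              f"online {log.series.mpf_hz[i]:.6f} Hz"))
    if len(offline) != len(log.series):
        disagreements.append((-1, "window_count",
                              f"offline {len(offline)} vs online {len(log.series)}"))

    trigger_windows = {tr.window_index for tr in log.triggers}
    if log.baseline_hz is not None:
        for i in range(proto.baseline_windows, n):
            dr = drop_rate(log.baseline_hz, offline.mpf_hz[i])
            fired = i in trigger_windows
            if proto.group == "FAT-C":
                if fired and dr < proto.threshold_pct - 1e-9:
                    disagreements.append((i, "trigger_below_threshold", f"{dr:.3f}%"))
                # a non-trigger run window at/above threshold is a missed stop,
                # unless it is the session's final window (dose already met)
                if (not fired and dr >= proto.threshold_pct
                        and i < len(log.series) - 1):
                    disagreements.append((i, "missed_trigger", f"{dr:.3f}%"))
    for seg in log.segments:
        if seg.kind == "rest" and not any(
            abs(tr.time_s - seg.start_s) < 1e-6 for tr in log.triggers
        ):
            disagreements.append((-1, "unexplained_rest", f"rest at {seg.start_s} s"))
    return ReplayReport(
        n_windows=n, disagreements=disagreements, max_mpf_diff_hz=max_diff
    )
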
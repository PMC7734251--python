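"""Serialization of recordings, annotations, MPF series and session logs.

Recordings travel either as EDF (one channel per limb, physical units mV)
or as a two-column CSV with a JSON sidecar carrying the sampling rate,
channel roles and session schedule.  The EDF writer/reader here implements
the plain EDF layout (ASCII header, 16-bit little-endian samples, 1-s data
records); sessions whose length is not a whole number of seconds are
zero-padded to the record boundary.

Burst annotations are written as BED-like 3-column TSV (channel, onset_s,
offset_s) with a JSON parameter sidecar; MPF series and controller logs as
tidy CSV plus a JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fatigueloop.control import ControllerLog, Segment, SessionProtocol
from fatigueloop.fatigue import MPFSeries
from fatigueloop.preprocess import BurstAnnotation, EMGRecording
from fatigueloop.synthetic import GroundTruth

_DIG_MAX = 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: EMGRecording, path: str | Path) -> Path:
    """Write a recording to plain EDF (16-bit, 1-s data records)."""
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError(f"EDF export requires an integer sampling rate, got {fs}")
    ns = len(recording.roles)
    n = recording.n_samples
    n_records = int(np.ceil(n / spr))
    padded = np.zeros((ns, n_records * spr))
    padded[:, :n] = recording.data

    # quantize the physical range to what the 8-char ASCII field can carry,
    # rounded up so no sample exceeds it
    phys_max = float(np.ceil((float(np.max(np.abs(padded))) or 1.0) * 1e5) / 1e5)
    scale = _DIG_MAX / phys_max
    digital = np.clip(np.rint(padded * scale), -_DIG_MAX, _DIG_MAX).astype("<i2")

    header = b"".join([
        _ascii("0", 8),
        _ascii(recording.meta.get("subject", "X"), 80),
        _ascii(recording.meta.get("group", "Startdate X"), 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),
        _ascii(ns, 4),
    ])
    fields = [
        (16, [f"EMG {r}" for r in recording.roles]),
        (80, ["intramuscular electrode"] * ns),
        (8, ["mV"] * ns),
        (8, [f"{-phys_max:.5f}"[:8] for _ in range(ns)]),
        (8, [f"{phys_max:.5f}"[:8] for _ in range(ns)]),
        (8, [str(-_DIG_MAX)] * ns),
        (8, [str(_DIG_MAX)] * ns),
        (80, ["BP:60-2000Hz"] * ns),
        (8, [str(spr)] * ns),
        (32, [""] * ns),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            for ch in range(ns):
                fh.write(digital[ch, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> EMGRecording:
    """Read a plain EDF file written by :func:`write_edf` (or compatible)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_records = int(head[236:244].decode().strip())
        record_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig = fh.read(256 * ns)

        def field(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig[base + i * width: base + (i + 1) * width].decode().strip()
                for i in range(ns)
            ]

        labels = field(0, 16)
        phys_min = [float(v) for v in field(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in field(16 + 80 + 8 + 8, 8)]
        dig_min = [int(v) for v in field(16 + 80 + 8 + 16, 8)]
        dig_max = [int(v) for v in field(16 + 80 + 8 + 24, 8)]
        spr = [int(v) for v in field(16 + 80 + 8 + 32 + 80, 8)]
        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_record = sum(spr)
    raw = raw[: n_records * per_record].reshape(n_records, per_record)
    data = np.empty((ns, n_records * spr[0]))
    offsets = np.cumsum([0] + spr)
    for ch in range(ns):
        gain = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
        chunk = raw[:, offsets[ch]:offsets[ch + 1]].astype(float)
        data[ch] = ((chunk - dig_min[ch]) * gain + phys_min[ch]).ravel()
    roles = tuple(lab.replace("EMG", "").strip() or f"ch{i}"
                  for i, lab in enumerate(labels))
    return EMGRecording(data=data, fs=spr[0] / record_dur, roles=roles)


def write_csv_recording(recording: EMGRecording, path: str | Path) -> Path:
    """Write samples as CSV (one column per channel) plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(
        {role: recording.data[i] for i, role in enumerate(recording.roles)}
    ).to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "fs_hz": recording.fs,
        "roles": list(recording.roles),
        "units": "mV",
        "meta": _jsonable(recording.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_csv_recording(path: str | Path) -> EMGRecording:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    roles = tuple(sidecar["roles"])
    data = np.stack([df[r].to_numpy(dtype=float) for r in roles])
    return EMGRecording(data=data, fs=float(sidecar["fs_hz"]), roles=roles,
                        meta=sidecar.get("meta", {}))


def write_bursts(annotations: list[BurstAnnotation], path: str | Path) -> Path:
    """Burst intervals as 3-column TSV plus JSON with thresholds/parameters."""
    path = Path(path)
    rows = []
    for ann in annotations:
        for onset, offset in ann.intervals:
            rows.append({"channel": ann.role, "onset_s": onset, "offset_s": offset})
    pd.DataFrame(rows, columns=["channel", "onset_s", "offset_s"]).to_csv(
        path, sep="\t", index=False
    )
    meta = {
        ann.role: {"threshold_mv": ann.threshold, **_jsonable(ann.params)}
        for ann in annotations
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_bursts(path: str | Path) -> list[BurstAnnotation]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    out = []
    for role, sub in df.groupby("channel"):
        info = dict(meta.get(role, {}))
        out.append(BurstAnnotation(
            intervals=sub[["onset_s", "offset_s"]].to_numpy(dtype=float),
            role=str(role),
            threshold=float(info.pop("threshold_mv", 0.0)),
            params=info,
        ))
    return out


def write_mpf_series(series: MPFSeries, path: str | Path) -> Path:
    """Tidy CSV (time, MPF, drop rate, channel) with a JSON metadata sidecar."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    meta = {
        "window_s": series.window_s,
        "baseline_hz": series.baseline_hz,
        "channel": series.channel,
        "params": _jsonable(series.params),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def write_controller_log(log: ControllerLog, path: str | Path) -> Path:
    """Event table CSV plus JSON summary for one session log."""
    path = Path(path)
    rows = [
        {"event": "segment", "kind": s.kind, "start_s": s.start_s,
         "end_s": s.end_s, "drop_rate_pct": None}
        for s in log.segments
    ] + [
        {"event": "trigger", "kind": "alarm", "start_s": t.time_s,
         "end_s": t.time_s, "drop_rate_pct": t.drop_rate_pct}
        for t in log.triggers
    ]
    pd.DataFrame(rows).sort_values("start_s").to_csv(path, index=False)
    summary = {
        "group": log.protocol.group,
        "threshold_pct": log.protocol.threshold_pct,
        "baseline_hz": log.baseline_hz,
        "accumulated_run_min": log.accumulated_run_s / 60.0,
        "wall_time_min": log.wall_time_s / 60.0,
        "n_rests": log.n_rests,
        "n_triggers": len(log.triggers),
        "completed": log.completed,
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=1))
    return path


def read_controller_log(path: str | Path,
                        protocol: SessionProtocol | None = None) -> ControllerLog:
    path = Path(path)
    df = pd.read_csv(path)
    summary = json.loads(path.with_suffix(".json").read_text())
    proto = protocol or SessionProtocol(
        group=summary["group"], threshold_pct=summary["threshold_pct"]
    )
    segments = [
        Segment(r.kind, float(r.start_s), float(r.end_s))
        for r in df[df.event == "segment"].itertuples()
    ]
    from fatigueloop.control import TriggerEvent
    triggers = [
        TriggerEvent(float(r.start_s), float(r.drop_rate_pct), -1)
        for r in df[df.event == "trigger"].itertuples()
    ]
    return ControllerLog(
        protocol=proto, segments=segments, triggers=triggers,
        baseline_hz=summary.get("baseline_hz"),
        completed=bool(summary.get("completed", True)),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
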
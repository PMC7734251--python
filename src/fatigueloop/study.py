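"""End-to-end study simulation: signals -> processing -> control -> outcomes -> stats.

A study mirrors the three-arm design: control (CTRL, no treadmill), forced
training (FOR-T) and fatigue-controlled training (FAT-C), default n = 11
per arm, outcomes observed daily from day 2 (baseline) through day 14,
with treadmill sessions on days 3-14.  Each trained subject-day runs a
full simulated session through the closed-loop (or forced) controller, the
offline burst-detection chain and the symmetry index; daily mNSS and SI
trajectories feed the statistical battery with the day-2 value as
covariate.

Per-subject seeds are derived from the master seed by stable hashing of
the subject id, so any subject's data can be regenerated independently of
execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fatigueloop.control import (
    ControllerLog,
    SessionProtocol,
    run_fatc_session,
    run_fort_session,
)
from fatigueloop.outcomes import symmetry_index
from fatigueloop.preprocess import (
    AF,
    UN,
    burst_threshold,
    detect_bursts,
    envelope,
    rectify,
)
from fatigueloop.stats import TestResult, ancova
from fatigueloop.synthetic import (
    DEFAULT_FS,
    FatigueModel,
    GaitEMGSource,
    GaitPattern,
    GroupParams,
    simulate_resting_segment,
    simulate_study,
)


@dataclass
class StudyDesign:
    """Multi-subject study configuration."""

    n_per_group: dict = field(
        default_factory=lambda: {"CTRL": 11, "FOR-T": 11, "FAT-C": 11}
    )
    day_start: int = 2  # baseline observation day
    day_end: int = 14
    seed: int = 0
    fs: float = DEFAULT_FS
    simulate_signals: bool = True
    out_dir: str | Path | None = None
    save_raw: bool = False
    group_effects: dict | None = None  # group -> GroupParams overrides
    fatigue: FatigueModel | None = None
    protocol_kwargs: dict = field(default_factory=dict)  # SessionProtocol overrides

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} needs n >= 1")
        if self.day_end < self.day_start:
            raise ValueError("day range must be non-decreasing")

    @property
    def training_days(self) -> list[int]:
        """Days with treadmill sessions: every day after the baseline day."""
        return list(range(self.day_start + 1, self.day_end + 1))


@dataclass
class StudyResult:
    """Everything a simulated study produces."""

    trajectories: pd.DataFrame  # subject x day mNSS / subscores / SI
    sessions: pd.DataFrame  # one row per simulated treadmill session
    stats: dict  # outcome -> list[TestResult]
    failures: list = field(default_factory=list)
    logs: dict = field(default_factory=dict)  # (subject, day) -> ControllerLog


def _session_seed(master: int, subject: str, day: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [master, zlib.crc32(subject.encode()), day]
    )


def _asymmetry_for_si(si_pct: float) -> float:
    """Invert SI = -a / (2 + a) * 200 for the generator's duty asymmetry."""
    si = min(si_pct, 0.0)
    return -2.0 * si / (200.0 + si)


def run_session_for_subject(
    group: str,
    si_target_pct: float,
    seed: np.random.SeedSequence | int,
    fs: float = DEFAULT_FS,
    protocol: SessionProtocol | None = None,
    fatigue: FatigueModel | None = None,
    keep_recording: bool = True,
) -> tuple[ControllerLog, dict]:
    """One subject-day treadmill session processed end to end.

    Runs the protocol controller on a fresh generator whose burst-duty
    asymmetry is set so that its ground-truth SI equals ``si_target_pct``,
    then applies the offline chain (rectify, envelope, resting threshold,
    burst detection) and measures the symmetry index.  Returns the
    controller log plus a dict of measured outcomes.
    """
    rng = np.random.default_rng(seed)
    sub_seed = int(rng.integers(2**31))
    proto = protocol or SessionProtocol(group=group)
    fat = FatigueModel(**{
        k: getattr(fatigue, k)
        for k in ("accumulation_rate", "recovery_tau", "kappa", "center_freq_rest")
    }) if fatigue else FatigueModel()
    gait = GaitPattern.from_speed(
        proto.belt_speed, asymmetry=_asymmetry_for_si(si_target_pct)
    )
    source = GaitEMGSource(fatigue=fat, gait=gait, fs=fs, seed=sub_seed)
    runner = run_fatc_session if group == "FAT-C" else run_fort_session
    log = runner(proto, source, keep_recording=True)

    measured: dict = {
        "n_rests": log.n_rests,
        "n_triggers": len(log.triggers),
        "accumulated_run_min": log.accumulated_run_s / 60.0,
        "baseline_mpf_hz": log.baseline_hz,
        "mean_drop_rate_pct": float(np.nanmean(log.series.drop_rates))
        if log.series.drop_rates is not None else float("nan"),
    }
    rest = simulate_resting_segment(5.0, seed=sub_seed + 1, fs=fs)
    rect = rectify(log.recording)
    rest_rect = rectify(rest)
    bursts = {}
    for role in (AF, UN):
        thr = burst_threshold(envelope(rest_rect, channel=role))
        bursts[role] = detect_bursts(envelope(rect, channel=role), thr)
    measured["si_pct"] = symmetry_index(bursts[AF], bursts[UN])
    measured["si_true_pct"] = source.ground_truth().true_si()
    if not keep_recording:
        log.recording = None
    return log, measured


def run_study(design: StudyDesign) -> StudyResult:
    """Simulate the whole study; deterministic given the design's seed.

    Outcome trajectories are generated for every subject; trained subjects
    (FOR-T, FAT-C) additionally get one simulated treadmill session per
    training day, processed end to end.  A failing subject-day is logged
    and skipped, not fatal.  When ``design.out_dir`` is set, per-session
    logs and study-level tables are written under
    ``<out_dir>/<subject>/<day>/``.
    """
    from fatigueloop import io as flio

    trajectories = simulate_study(
        group_effects=design.group_effects,
        seed=design.seed,
        n_per_group=design.n_per_group,
        days=(design.day_start, design.day_end),
    )
    out_dir = Path(design.out_dir) if design.out_dir else None

    session_rows = []
    failures = []
    logs: dict = {}
    if design.simulate_signals:
        si_lookup = trajectories.set_index(["subject", "day"])["si"]
        trained = trajectories[
            trajectories.group.isin(("FOR-T", "FAT-C"))
        ][["subject", "group"]].drop_duplicates()
        for _, row in trained.iterrows():
            for day in design.training_days:
                try:
                    log, measured = run_session_for_subject(
                        row.group,
                        si_target_pct=float(si_lookup[(row.subject, day)]),
                        seed=_session_seed(design.seed, row.subject, day),
                        fs=design.fs,
                        protocol=SessionProtocol(
                            group=row.group, **design.protocol_kwargs
                        ),
                        fatigue=design.fatigue,
                        keep_recording=design.save_raw,
                    )
                except Exception as exc:  # study continues past one bad subject
                    failures.append((row.subject, day, repr(exc)))
                    continue
                logs[(row.subject, day)] = log
                session_rows.append({
                    "subject": row.subject, "group": row.group, "day": day,
                    **measured,
                })
                if out_dir is not None:
                    sdir = out_dir / row.subject / f"day{day:02d}"
                    sdir.mkdir(parents=True, exist_ok=True)
                    flio.write_controller_log(log, sdir / "session_log.csv")
                    if log.series is not None:
                        flio.write_mpf_series(log.series, sdir / "mpf_series.csv")
                    if design.save_raw and log.recording is not None:
                        flio.write_csv_recording(log.recording, sdir / "emg.csv")

    sessions = pd.DataFrame(session_rows)
    stats = _study_stats(trajectories, sessions, design)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        trajectories.to_csv(out_dir / "trajectories.csv", index=False)
        if not sessions.empty:
            sessions.to_csv(out_dir / "sessions.csv", index=False)
        _stats_frame(stats).to_csv(out_dir / "stats_report.csv", index=False)

    return StudyResult(
        trajectories=trajectories, sessions=sessions, stats=stats,
        failures=failures, logs=logs,
    )


def _study_stats(trajectories: pd.DataFrame, sessions: pd.DataFrame,
                 design: StudyDesign) -> dict:
    """The study's trajectory comparisons with the day-2 covariate."""
    stats: dict[str, list[TestResult]] = {}
    base = trajectories[trajectories.day == design.day_start]
    for outcome in ("mnss", "si"):
        df = trajectories.dropna(subset=[outcome]).copy()
        cov = base.set_index("subject")[outcome]
        df["baseline"] = df.subject.map(cov)
        df = df[df.day > design.day_start].dropna(subset=["baseline"])
        if df.group.nunique() < 2 or len(df) < 6:
            continue
        stats[outcome] = ancova(
            df, value=outcome, group="group", covariate="baseline",
            timepoint="day",
        )
    return stats


def _stats_frame(stats: dict) -> pd.DataFrame:
    rows = []
    for outcome, results in stats.items():
        for r in results:
            rows.append({
                "outcome": outcome, "effect": r.effect, "F": r.statistic,
                "df1": r.df[0], "df2": r.df[1], "p": r.pvalue,
                "partial_eta_sq": r.effect_size,
            })
    return pd.DataFrame(rows)


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> dict:
    """Generate a tiny canned dataset with known ground truth.

    A desk-scale closed-loop session (2-min running dose, 20-s rests, fast
    fatigue accumulation) plus a resting segment, written as CSV, EDF,
    burst TSV, ground-truth JSON and a controller log.  Regenerates
    identically from the same seed.
    """
    from fatigueloop import io as flio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proto = SessionProtocol(
        group="FAT-C", run_target_min=2.0, rest_min=1.0 / 3.0,
    )
    fat = FatigueModel(accumulation_rate=0.02, recovery_tau=5.0)
    gait = GaitPattern(asymmetry=0.4)
    source = GaitEMGSource(fatigue=fat, gait=gait, seed=seed)
    log = run_fatc_session(proto, source)
    truth = source.ground_truth(log.segments)

    rest = simulate_resting_segment(5.0, seed=seed + 1)
    rect = rectify(log.recording)
    bursts = []
    for role in (AF, UN):
        thr = burst_threshold(envelope(rectify(rest), channel=role))
        bursts.append(detect_bursts(envelope(rect, channel=role), thr))

    paths = {
        "recording_csv": flio.write_csv_recording(log.recording, out / "session.csv"),
        "recording_edf": flio.write_edf(log.recording, out / "session.edf"),
        "rest_csv": flio.write_csv_recording(rest, out / "rest.csv"),
        "bursts": flio.write_bursts(bursts, out / "bursts.tsv"),
        "truth": flio.write_ground_truth(truth, out / "truth.json"),
        "log": flio.write_controller_log(log, out / "session_log.csv"),
    }
    paths["n_rests"] = log.n_rests
    paths["seed"] = seed
    return paths
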
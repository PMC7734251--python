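"""Ground-truthed synthetic gait EMG and outcome-trajectory generator.

Signal model
------------
Treadmill gait EMG is modelled as band-limited Gaussian noise gated by a
periodic stride envelope.  Within each burst the noise has a Gaussian power
spectrum centred at

    cf(F) = center_freq_rest * (1 - kappa * F),

where ``F`` in [0, 1] is a latent fatigue state.  ``F`` accumulates
linearly in time while the belt runs and recovers exponentially (time
constant ``recovery_tau``) during rest, producing the characteristic
monotone-to-plateau drop-rate profile under forced running and a sawtooth
under fatigue-controlled running.  ``kappa`` is the maximum fractional MPF
compression, so at full fatigue the measured MPF drop rate plateaus near
``100 * kappa`` percent.

Because the spectrum is shaped directly in the frequency domain, the MPF of
a generated segment is analytically controllable (it equals ``cf(F)`` up to
truncation at the band edges), which makes the generator usable as an
oracle for the measurement chain.

Outcome model
-------------
Daily modified Neurological Severity Score (mNSS, 0-18, lower is better)
trajectories decay exponentially from a day-2 baseline toward a group
asymptote; the bilateral symmetry index (SI) starts negative (longer
unaffected-limb bursts) and relaxes toward zero at a group-specific rate.
All randomness flows from one seeded generator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fatigueloop.preprocess import AF, UN, DEFAULT_BAND, EMGRecording

DEFAULT_FS = 5000.0  # Hz; Nyquist-valid for the 60-2000 Hz band
ACQUISITION_FS = 40000.0  # hardware-fidelity rate, supported but slow

GROUPS = ("CTRL", "FOR-T", "FAT-C")


@dataclass
class FatigueModel:
    """Latent fatigue state and its coupling to the EMG spectrum.

    Parameters
    ----------
    accumulation_rate
        Linear fatigue accumulation per second of running (1/s).  The
        default drives the drop rate past an 11 % threshold after roughly
        10 minutes of continuous running.
    recovery_tau
        Exponential recovery time constant during rest, seconds.
    kappa
        Maximum fractional MPF compression in [0, 1); drop rate ~ kappa*F.
    center_freq_rest
        Spectral centre of burst noise at F=0, Hz.
    F
        Initial fatigue state in [0, 1].
    """

    accumulation_rate: float = 1.0 / 1000.0
    recovery_tau: float = 60.0
    kappa: float = 0.18
    center_freq_rest: float = 800.0
    F: float = 0.0
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")
        if not 0.0 <= self.kappa < 1.0:
            raise ValueError("kappa must lie in [0, 1)")
        if self.center_freq_rest * (1.0 - self.kappa) <= self.band[0]:
            raise ValueError(
                "fully fatigued spectral centre "
                f"{self.center_freq_rest * (1 - self.kappa):.1f} Hz would fall "
                f"below the low band edge {self.band[0]} Hz"
            )
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be positive")

    def center_freq(self, F: float | np.ndarray | None = None):
        """Burst spectral centre at fatigue state ``F`` (defaults to current)."""
        if F is None:
            F = self.F
        return self.center_freq_rest * (1.0 - self.kappa * np.asarray(F))

    def step(self, dt: float, running: bool) -> float:
        """Advance the fatigue state by ``dt`` seconds; returns the new F."""
        if running:
            self.F = min(1.0, self.F + self.accumulation_rate * dt)
        else:
            self.F = self.F * float(np.exp(-dt / self.recovery_tau))
        return self.F


@dataclass
class GaitPattern:
    """Stride timing and burst morphology of treadmill gait.

    ``burst_duty`` is the fraction of the stride during which the affected
    (AF) muscle is active; the unaffected (UN) limb's duty is lengthened by
    the dimensionless ``asymmetry`` factor (``duty_un = burst_duty * (1 +
    asymmetry)``), so a positive asymmetry yields a negative symmetry
    index.  ``amplitude`` is the nominal burst peak in mV (about 2.5 noise
    standard deviations).
    """

    stride_rate: float = 2.0  # strides/s at 16 m/min belt speed
    burst_duty: float = 0.35
    asymmetry: float = 0.0
    amplitude: float = 0.5  # mV
    ramp_s: float = 0.010

    def __post_init__(self) -> None:
        if not 0.0 < self.burst_duty < 1.0:
            raise ValueError("burst_duty must lie in (0, 1)")
        if self.duty(UN) >= 1.0:
            raise ValueError("asymmetry pushes UN duty past a full stride")
        if self.amplitude <= 0 or self.stride_rate <= 0:
            raise ValueError("amplitude and stride_rate must be positive")

    @classmethod
    def from_speed(
        cls, speed_m_per_min: float, stride_length_m: float = 0.13, **kwargs
    ) -> "GaitPattern":
        """Derive the stride rate from belt speed and stride length."""
        return cls(stride_rate=speed_m_per_min / 60.0 / stride_length_m, **kwargs)

    def duty(self, role: str) -> float:
        if role == AF:
            return self.burst_duty
        if role == UN:
            return self.burst_duty * (1.0 + self.asymmetry)
        raise KeyError(f"unknown channel role {role!r}")


@dataclass
class GroundTruth:
    """Generator-side truth for one simulated session."""

    bursts: dict  # role -> (n, 2) array of [onset, offset) in s
    f_times: np.ndarray  # wall-clock sample times of the F trajectory, s
    f_values: np.ndarray  # latent fatigue state F in [0, 1]
    schedule: list = field(default_factory=list)

    def true_si(self) -> float:
        """Symmetry index implied by the true burst durations, percent."""
        d_af = float(np.sum(self.bursts[AF][:, 1] - self.bursts[AF][:, 0]))
        d_un = float(np.sum(self.bursts[UN][:, 1] - self.bursts[UN][:, 0]))
        n_af = max(len(self.bursts[AF]), 1)
        n_un = max(len(self.bursts[UN]), 1)
        m_af, m_un = d_af / n_af, d_un / n_un
        return (m_af - m_un) / (m_af + m_un) * 200.0

    def to_dict(self) -> dict:
        return {
            "bursts": {r: iv.tolist() for r, iv in self.bursts.items()},
            "f_times": self.f_times.tolist(),
            "f_values": self.f_values.tolist(),
            "schedule": [
                {"kind": s.kind, "start_s": s.start_s, "end_s": s.end_s}
                for s in self.schedule
            ],
        }


def _shaped_noise(
    n: int, fs: float, rng: np.random.Generator, psd: np.ndarray
) -> np.ndarray:
    """Stationary Gaussian noise with the given one-sided PSD shape, unit RMS."""
    coef = (rng.standard_normal(psd.size) + 1j * rng.standard_normal(psd.size))
    coef *= np.sqrt(psd)
    coef[0] = 0.0
    x = np.fft.irfft(coef, n)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0:
        x /= rms
    return x


class GaitEMGSource:
    """Stateful streaming generator of two-channel gait EMG.

    Produces samples in arbitrary-duration quanta via :meth:`next_window`,
    advancing the latent fatigue state according to whether the belt is
    running, and records ground-truth burst intervals and the F trajectory.
    Stride phase is locked to absolute session time, so bursts are
    continuous across window boundaries.
    """

    def __init__(
        self,
        fatigue: FatigueModel | None = None,
        gait: GaitPattern | None = None,
        fs: float = DEFAULT_FS,
        seed: int | np.random.Generator = 0,
        spectral_width: float = 150.0,
        noise_floor: float = 0.005,  # mV RMS electrode noise between bursts
    ):
        self.fatigue = fatigue if fatigue is not None else FatigueModel()
        self.gait = gait if gait is not None else GaitPattern()
        band = self.fatigue.band
        if fs < 2.0 * band[1]:
            raise ValueError(
                f"sampling rate {fs} Hz is below the Nyquist rate "
                f"{2 * band[1]} Hz for the {band[0]}-{band[1]} Hz band"
            )
        self.fs = float(fs)
        self.rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        self.spectral_width = spectral_width
        self.noise_floor = noise_floor
        self.t = 0.0  # absolute session time, s
        self._truth_bursts: dict[str, list] = {AF: [], UN: []}
        self._f_times: list[float] = []
        self._f_values: list[float] = []

    def _gate(self, t: np.ndarray, duty: float) -> np.ndarray:
        period = 1.0 / self.gait.stride_rate
        active = duty * period
        ramp = min(self.gait.ramp_s, active / 2.0)
        tau = np.mod(t, period)  # time within stride
        g = np.zeros_like(tau)
        inside = tau < active
        g[inside] = 1.0
        if ramp > 0:
            rising = inside & (tau < ramp)
            g[rising] = 0.5 * (1.0 - np.cos(np.pi * tau[rising] / ramp))
            falling = inside & (tau > active - ramp)
            g[falling] = 0.5 * (1.0 - np.cos(np.pi * (active - tau[falling]) / ramp))
        return g

    def _true_intervals(self, t0: float, t1: float, duty: float) -> list:
        period = 1.0 / self.gait.stride_rate
        active = duty * period
        m0 = int(np.floor(t0 / period))
        m1 = int(np.ceil(t1 / period))
        out = []
        for m in range(m0, m1 + 1):
            a, b = m * period, m * period + active
            a, b = max(a, t0), min(b, t1)
            if b - a > 1e-12:
                out.append((a, b))
        return out

    def _burst_psd(self, freqs: np.ndarray, cf: float) -> np.ndarray:
        band = self.fatigue.band
        psd = np.exp(-((freqs - cf) ** 2) / (2.0 * self.spectral_width**2))
        psd[(freqs < band[0]) | (freqs > band[1])] = 0.0
        return psd

    def _floor_psd(self, freqs: np.ndarray) -> np.ndarray:
        band = self.fatigue.band
        return ((freqs >= band[0]) & (freqs <= band[1])).astype(float)

    def next_window(self, duration_s: float = 4.0, running: bool = True) -> np.ndarray:
        """Generate the next ``duration_s`` seconds; returns ``(2, n)`` mV."""
        n = int(round(duration_s * self.fs))
        t = self.t + np.arange(n) / self.fs
        freqs = np.fft.rfftfreq(n, 1.0 / self.fs)
        self._f_times.append(self.t)
        self._f_values.append(self.fatigue.F)

        out = np.empty((2, n))
        if running:
            # quasi-stationary within one window: F at the window midpoint
            f_mid = min(
                1.0,
                self.fatigue.F + self.fatigue.accumulation_rate * duration_s / 2.0,
            )
            cf = float(self.fatigue.center_freq(f_mid))
            burst_psd = self._burst_psd(freqs, cf)
            burst_rms = self.gait.amplitude / 2.5
            for i, role in enumerate((AF, UN)):
                duty = self.gait.duty(role)
                carrier = _shaped_noise(n, self.fs, self.rng, burst_psd) * burst_rms
                floor = (
                    _shaped_noise(n, self.fs, self.rng, self._floor_psd(freqs))
                    * self.noise_floor
                )
                out[i] = carrier * self._gate(t, duty) + floor
                self._truth_bursts[role].extend(
                    self._true_intervals(self.t, self.t + duration_s, duty)
                )
        else:
            floor_psd = self._floor_psd(freqs)
            for i in range(2):
                out[i] = (
                    _shaped_noise(n, self.fs, self.rng, floor_psd) * self.noise_floor
                )
        self.fatigue.step(duration_s, running)
        self.t += duration_s
        return out

    def ground_truth(self, schedule: list | None = None) -> GroundTruth:
        """Snapshot of the accumulated ground truth."""
        bursts = {}
        for role, ivs in self._truth_bursts.items():
            merged: list[list[float]] = []
            for a, b in ivs:
                if merged and a - merged[-1][1] < 1e-9:
                    merged[-1][1] = b
                else:
                    merged.append([a, b])
            bursts[role] = np.array(merged).reshape(-1, 2)
        return GroundTruth(
            bursts=bursts,
            f_times=np.array(self._f_times),
            f_values=np.array(self._f_values),
            schedule=list(schedule) if schedule else [],
        )


def simulate_gait_emg(
    protocol,
    fatigue: FatigueModel | None = None,
    gait: GaitPattern | None = None,
    seed: int = 0,
    fs: float = DEFAULT_FS,
) -> tuple[EMGRecording, GroundTruth]:
    """Simulate one treadmill session under a fixed run/rest schedule.

    ``protocol`` is a :class:`~fatigueloop.control.SessionProtocol`; if it
    carries an explicit ``schedule`` (list of ``(kind, duration_s)``) that
    is followed, otherwise the session is one continuous run of the
    protocol's accumulated-run target (the forced-running case).  For the
    closed-loop protocol, where rests depend on the measured drop rate, use
    :func:`fatigueloop.control.run_fatc_session` instead.
    """
    fatigue = fatigue if fatigue is not None else FatigueModel()
    gait = gait if gait is not None else GaitPattern.from_speed(
        protocol.belt_speed
    )
    source = GaitEMGSource(fatigue=fatigue, gait=gait, fs=fs, seed=seed)
    if getattr(protocol, "schedule", None):
        plan = list(protocol.schedule)
    else:
        plan = [("run", protocol.run_target_min * 60.0)]

    from fatigueloop.control import Segment

    chunks = []
    segments = []
    t = 0.0
    for kind, dur in plan:
        remaining = float(dur)
        while remaining > 1e-9:
            step = min(4.0, remaining)
            chunks.append(source.next_window(step, running=(kind == "run")))
            remaining -= step
        segments.append(Segment(kind, t, t + float(dur)))
        t += float(dur)
    data = np.concatenate(chunks, axis=1)
    rec = EMGRecording(
        data=data,
        fs=fs,
        roles=(AF, UN),
        meta={
            "group": getattr(protocol, "group", None),
            "belt_speed_m_per_min": protocol.belt_speed,
            "schedule": [(s.kind, s.start_s, s.end_s) for s in segments],
        },
    )
    return rec, source.ground_truth(segments)


def simulate_resting_segment(
    duration_s: float,
    noise_level: float = 0.010,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    band: tuple[float, float] = DEFAULT_BAND,
) -> EMGRecording:
    """Stationary two-channel resting EMG.

    ``noise_level`` is the total resting RMS in mV, including the low-level
    postural muscle tone a resting animal maintains on top of pure
    electrode noise; it therefore sits above the inter-burst floor seen
    during gait, which is what makes the resting mean-plus-1.5-SD rule a
    conservative burst threshold.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    if noise_level == 0:
        data = np.zeros((2, n))
    else:
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        psd = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
        data = np.stack(
            [_shaped_noise(n, fs, rng, psd) * noise_level for _ in range(2)]
        )
    return EMGRecording(data=data, fs=fs, roles=(AF, UN), meta={"kind": "rest"})


# ---------------------------------------------------------------------------
# Daily outcome trajectories
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Per-group trajectory parameters for the outcome simulator.

    mNSS decays as ``floor + (baseline - floor) * exp(-(day-2)/tau)``;
    SI rises linearly from its day-2 baseline at ``si_slope_per_day``
    (percentage points per day), capped at zero (perfect symmetry).
    """

    mnss_baseline_mean: float = 10.5
    mnss_baseline_sd: float = 1.2
    mnss_tau_days: float = 5.0
    mnss_floor: float = 4.5
    mnss_noise_sd: float = 0.7
    si_baseline_mean: float = -40.0
    si_baseline_sd: float = 10.0
    si_slope_per_day: float = 0.0
    si_noise_sd: float = 8.0


DEFAULT_GROUP_EFFECTS: dict[str, GroupParams] = {
    # spontaneous recovery only; no treadmill, hence no SI
    "CTRL": GroupParams(mnss_tau_days=6.0, mnss_floor=6.5),
    # forced running: recovery plateaus higher, symmetry does not improve
    "FOR-T": GroupParams(mnss_tau_days=5.0, mnss_floor=4.5,
                         si_slope_per_day=0.5),
    # fatigue-controlled: fastest, deepest recovery and SI relaxing to zero
    "FAT-C": GroupParams(mnss_tau_days=4.5, mnss_floor=2.5,
                         si_slope_per_day=3.0),
}

MNSS_SUBSCALE_MAX = {"motor": 6, "sensory": 2, "beam": 6, "reflex": 4}


def _subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject generator derived by stable hashing of the subject id."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(subject_id.encode())])
    )


def _decompose_mnss(total: int, rng: np.random.Generator) -> dict[str, int]:
    """Split a total mNSS into subscale integers respecting each maximum."""
    remaining = total
    parts = {}
    keys = list(MNSS_SUBSCALE_MAX)
    for i, key in enumerate(keys):
        cap = MNSS_SUBSCALE_MAX[key]
        tail_cap = sum(MNSS_SUBSCALE_MAX[k] for k in keys[i + 1:])
        lo = max(0, remaining - tail_cap)
        hi = min(cap, remaining)
        parts[key] = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        remaining -= parts[key]
    return parts


def simulate_study(
    design=None,
    group_effects: dict[str, GroupParams] | None = None,
    seed: int = 0,
    n_per_group: dict[str, int] | None = None,
    days: tuple[int, int] = (2, 14),
) -> pd.DataFrame:
    """Simulate daily mNSS and SI trajectories for every subject.

    Returns a tidy frame with one row per subject x day: columns
    ``subject, group, day, mnss, motor, sensory, beam, reflex, si``.
    mNSS is integer-valued in [0, 18] and every day-2 baseline exceeds 6
    (the study's recruitment rule).  SI is absent (NaN) for CTRL subjects,
    who never run on the treadmill.
    """
    if design is not None:
        n_per_group = dict(design.n_per_group)
        days = (design.day_start, design.day_end)
        seed = design.seed if seed == 0 else seed
    if n_per_group is None:
        n_per_group = {g: 11 for g in GROUPS}
    for g in n_per_group:
        if g not in GROUPS:
            raise ValueError(f"unknown group label {g!r}; expected one of {GROUPS}")
    effects = dict(DEFAULT_GROUP_EFFECTS)
    if group_effects:
        for g in group_effects:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}; expected one of {GROUPS}")
        effects.update(group_effects)

    day_range = np.arange(days[0], days[1] + 1)
    rows = []
    for group, n in n_per_group.items():
        p = effects[group]
        for j in range(n):
            subject = f"{group}-{j + 1:02d}"
            rng = _subject_rng(seed, subject)
            # day-2 baseline mNSS; recruitment requires > 6
            base = int(np.clip(
                np.rint(rng.normal(p.mnss_baseline_mean, p.mnss_baseline_sd)),
                7, 18,
            ))
            si0 = rng.normal(p.si_baseline_mean, p.si_baseline_sd)
            si0 = float(np.clip(si0, -200.0, 0.0))
            for day in day_range:
                dt = day - days[0]
                mean_mnss = p.mnss_floor + (base - p.mnss_floor) * np.exp(
                    -dt / p.mnss_tau_days
                )
                noise = rng.normal(0.0, p.mnss_noise_sd) if p.mnss_noise_sd else 0.0
                mnss = int(np.clip(np.rint(mean_mnss + noise), 0, 18))
                if day == days[0]:
                    mnss = base  # baseline is the recruitment measurement
                parts = _decompose_mnss(mnss, rng)
                if group == "CTRL":
                    si = float("nan")
                else:
                    mean_si = min(0.0, si0 + p.si_slope_per_day * dt)
                    si_noise = (
                        rng.normal(0.0, p.si_noise_sd) if p.si_noise_sd else 0.0
                    )
                    si = float(np.clip(mean_si + si_noise, -200.0, 200.0))
                rows.append({
                    "subject": subject, "group": group, "day": int(day),
                    "mnss": mnss, **parts, "si": si,
                })
    return pd.DataFrame(rows)
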
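"""Bilateral gait symmetry index and mNSS score handling.

The symmetry index (SI) compares EMG burst durations of the affected (AF)
and unaffected (UN) hind limbs during treadmill running:

    SI = (BurstDuration_AF - BurstDuration_UN)
         / (BurstDuration_AF + BurstDuration_UN) * 200 %

Zero means perfect bilateral balance; negative values mean the unaffected
limb's bursts are longer (the typical post-stroke pattern); the range is
[-200, 200] %.  "BurstDuration" is reduced per limb over the session; the
mean burst duration is the default reducer (total duration is available —
with near-equal burst counts per limb the two agree).

The modified Neurological Severity Score (mNSS) grades deficits from 0
(normal) to 18 (maximal), decomposed into motor (max 6), sensory (max 2),
beam balance (max 6) and reflex/abnormal-movement (max 4) subscales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from fatigueloop.preprocess import BurstAnnotation

MNSS_MAX = {"motor": 6, "sensory": 2, "beam": 6, "reflex": 4}


@dataclass(frozen=True)
class MNSSScore:
    """One modified Neurological Severity Score observation."""

    motor: int
    sensory: int
    beam: int
    reflex: int

    @property
    def total(self) -> int:
        return self.motor + self.sensory + self.beam + self.reflex


def validate_mnss(score: MNSSScore) -> MNSSScore:
    """Validate subscale ranges; raises naming the offending subscale."""
    for name, cap in MNSS_MAX.items():
        v = getattr(score, name)
        if not isinstance(v, (int, np.integer)):
            raise ValueError(f"mNSS subscale {name!r} must be an integer, got {v!r}")
        if not 0 <= v <= cap:
            raise ValueError(
                f"mNSS subscale {name!r} = {v} outside its range 0-{cap}"
            )
    return score


def _mean_duration(bursts: BurstAnnotation | np.ndarray) -> tuple[float, int]:
    iv = bursts.intervals if isinstance(bursts, BurstAnnotation) else np.asarray(
        bursts, float).reshape(-1, 2)
    n = iv.shape[0]
    if n == 0:
        return 0.0, 0
    return float(np.mean(iv[:, 1] - iv[:, 0])), n


def _total_duration(bursts: BurstAnnotation | np.ndarray) -> tuple[float, int]:
    iv = bursts.intervals if isinstance(bursts, BurstAnnotation) else np.asarray(
        bursts, float).reshape(-1, 2)
    n = iv.shape[0]
    return float(np.sum(iv[:, 1] - iv[:, 0])) if n else 0.0, n


def symmetry_index(
    bursts_af: BurstAnnotation | np.ndarray,
    bursts_un: BurstAnnotation | np.ndarray,
    reducer: str = "mean",
) -> float:
    """Symmetry index in percent from per-limb burst annotations.

    A limb with no bursts contributes zero duration, driving SI to the
    formula limit of +/-200 %; with zero bursts on both limbs the index is
    undefined and a ValueError is raised.
    """
    reduce = {"mean": _mean_duration, "total": _total_duration}[reducer]
    d_af, n_af = reduce(bursts_af)
    d_un, n_un = reduce(bursts_un)
    if n_af == 0 and n_un == 0:
        raise ValueError("symmetry index undefined: no bursts on either limb")
    return (d_af - d_un) / (d_af + d_un) * 200.0


@dataclass
class SymmetryRecord:
    """Per-subject, per-day symmetry outcome."""

    subject: str
    day: int
    si_pct: float
    mean_duration_af_s: float
    mean_duration_un_s: float
    n_bursts_af: int
    n_bursts_un: int

    def __post_init__(self) -> None:
        if not -200.0 <= self.si_pct <= 200.0:
            raise ValueError(f"SI {self.si_pct} outside [-200, 200] %")


def daily_summary(
    records: pd.DataFrame,
    value: str,
    by: tuple[str, str] = ("group", "day"),
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Mean and t-based confidence interval per group x day cell.

    ``records`` is tidy (one row per subject x day).  Cells with a single
    observation get an undefined (NaN) interval; empty cells are absent.
    """
    out = []
    for keys, cell in records.groupby(list(by), observed=True):
        v = cell[value].dropna().to_numpy(dtype=float)
        if v.size == 0:
            continue
        mean = float(np.mean(v))
        if v.size >= 2:
            sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
            tcrit = float(sstats.t.ppf(0.5 + confidence / 2.0, v.size - 1))
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            lo = hi = float("nan")
        out.append({
            **dict(zip(by, keys)),
            "n": int(v.size), "mean": mean, "ci_low": lo, "ci_high": hi,
        })
    return pd.DataFrame(out)
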
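"""EWMA control chart: limits, trace, Westgard multirules, alarm detection.

The monitored statistic follows the recursion ``q_{t+1} = lam*x_t + (1-lam)*q_t``
over accepted (non-excluded) results. Control limits use the asymptotic EWMA
standard deviation ``sd_train * sqrt(lam / (2 - lam))`` by default; the exact
time-varying factor ``sqrt(1 - (1-lam)**(2t))`` is available behind a flag and
only matters for roughly the first ``3/lam`` points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core_model import ResultStream, ValidationError

__all__ = [
    "MIN_TRAINING_N",
    "AlarmLevel",
    "ControlLimits",
    "EWMATrace",
    "AlarmRecord",
    "AlarmLog",
    "RuleViolation",
    "compute_control_limits",
    "ewma_run",
    "westgard_evaluate",
    "detect_alarms",
]

MIN_TRAINING_N = 30

#: Westgard rules that only warn (all others reject).
WARNING_RULES = frozenset({"1-2S"})


class AlarmLevel(str, enum.Enum):
    WARNING = "warning"
    ACTION = "action"


@dataclass(frozen=True)
class ControlLimits:
    center: float
    sd_train: float
    sd_ewma: float
    warn_low: float
    warn_high: float
    action_low: float
    action_high: float

    def __post_init__(self) -> None:
        if not (
            self.action_low < self.warn_low < self.center < self.warn_high < self.action_high
        ):
            raise ValidationError("control limits must nest: action < warn < center < warn < action")

    def zscores(self, q: np.ndarray) -> np.ndarray:
        return (np.asarray(q, dtype=float) - self.center) / self.sd_ewma


@dataclass
class EWMATrace:
    """EWMA values aligned one-to-one with the accepted results."""

    q: np.ndarray
    lam: float
    init: float
    timestamps: Optional[pd.DatetimeIndex] = None

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class RuleViolation:
    index: int
    rule: str
    level: AlarmLevel


@dataclass(frozen=True)
class AlarmRecord:
    index: int
    timestamp: Optional[pd.Timestamp]
    level: AlarmLevel
    rule: str


@dataclass
class AlarmLog:
    records: list[AlarmRecord] = field(default_factory=list)
    episodes: list[tuple[int, int]] = field(default_factory=list)
    n_points: int = 0

    def alarmed_indices(self, level: Optional[AlarmLevel] = None) -> np.ndarray:
        idx = {r.index for r in self.records if level is None or r.level == level}
        return np.asarray(sorted(idx), dtype=int)

    def alarm_mask(self, level: Optional[AlarmLevel] = None) -> np.ndarray:
        mask = np.zeros(self.n_points, dtype=bool)
        idx = self.alarmed_indices(level)
        if idx.size:
            mask[idx] = True
        return mask


def compute_control_limits(
    training_values,
    lam: float,
    k_warn: float = 2.0,
    k_action: float = 3.0,
) -> ControlLimits:
    """Center line and warning/action envelope from post-truncation training data."""
    arr = np.asarray(training_values, dtype=float)
    if arr.size < MIN_TRAINING_N:
        raise ValidationError(
            f"insufficient training data: {arr.size} < {MIN_TRAINING_N} accepted values"
        )
    if not (0.0 < lam < 1.0):
        raise ValidationError(f"lambda {lam} outside (0, 1)")
    if not (0.0 < k_warn < k_action):
        raise ValidationError("require 0 < k_warn < k_action")
    center = float(np.mean(arr))
    sd_train = float(np.std(arr, ddof=1))
    if sd_train == 0.0:
        raise ValidationError("training data has zero variance")
    sd_ewma = sd_train * float(np.sqrt(lam / (2.0 - lam)))
    return ControlLimits(
        center=center,
        sd_train=sd_train,
        sd_ewma=sd_ewma,
        warn_low=center - k_warn * sd_ewma,
        warn_high=center + k_warn * sd_ewma,
        action_low=center - k_action * sd_ewma,
        action_high=center + k_action * sd_ewma,
    )


def ewma_update(q: float, x: float, lam: float) -> float:
    return lam * x + (1.0 - lam) * q


def ewma_run(stream: ResultStream | Sequence[float], lam: float, init: float) -> EWMATrace:
    """Run the EWMA recursion over the accepted results of a stream.

    ``trace[t]`` is the estimate after consuming accepted observation ``t``;
    excluded results are skipped entirely and contribute no trace point.
    """
    if not (0.0 < lam < 1.0):
        raise ValidationError(f"lambda {lam} outside (0, 1)")
    timestamps = None
    if isinstance(stream, ResultStream):
        x = stream.accepted_values()
        timestamps = stream.accepted_timestamps()
    else:
        x = np.asarray(stream, dtype=float)
    if x.size == 0:
        return EWMATrace(q=np.empty(0), lam=lam, init=float(init), timestamps=timestamps)
    # q_t = lam*x_t + (1-lam)*q_{t-1} is an IIR filter with state (1-lam)*q.
    # Filtering deviations from init keeps a constant stream an exact fixed point.
    dq, _ = signal.lfilter([lam], [1.0, -(1.0 - lam)], x - float(init), zi=[0.0])
    q = float(init) + dq
    return EWMATrace(q=q, lam=lam, init=float(init), timestamps=timestamps)


def westgard_evaluate(zscores) -> list[RuleViolation]:
    """Evaluate the 1-2S / 1-3S / 2-2S / R-4S / 10-X multirules on a z-series.

    Per index: 1-2S warns when ``|z| > 2``; 1-3S rejects when ``|z| > 3``;
    2-2S rejects when two consecutive points are both above +2 or both below
    -2; R-4S rejects when a consecutive pair has opposite signs and a range
    exceeding 4; 10-X rejects when ten consecutive points fall strictly on
    one side of 0.
    """
    z = np.asarray(zscores, dtype=float)
    out: list[RuleViolation] = []
    for i in range(z.size):
        zi = z[i]
        if abs(zi) > 3.0:
            out.append(RuleViolation(i, "1-3S", AlarmLevel.ACTION))
        if abs(zi) > 2.0:
            out.append(RuleViolation(i, "1-2S", AlarmLevel.WARNING))
        if i >= 1:
            zp = z[i - 1]
            if (zi > 2.0 and zp > 2.0) or (zi < -2.0 and zp < -2.0):
                out.append(RuleViolation(i, "2-2S", AlarmLevel.ACTION))
            if zi * zp < 0 and abs(zi - zp) > 4.0:
                out.append(RuleViolation(i, "R-4S", AlarmLevel.ACTION))
        if i >= 9:
            window = z[i - 9 : i + 1]
            if np.all(window > 0) or np.all(window < 0):
                out.append(RuleViolation(i, "10-X", AlarmLevel.ACTION))
    return out


def _merge_episodes(indices: np.ndarray) -> list[tuple[int, int]]:
    if indices.size == 0:
        return []
    episodes = []
    start = prev = int(indices[0])
    for i in indices[1:]:
        i = int(i)
        if i == prev + 1:
            prev = i
        else:
            episodes.append((start, prev))
            start = prev = i
    episodes.append((start, prev))
    return episodes


def detect_alarms(
    trace: EWMATrace,
    limits: ControlLimits,
    rules_enabled: frozenset[str] | set[str] = frozenset({"limit_chart"}),
) -> AlarmLog:
    """Scan a trace against its limits (and optionally the multirules).

    Per point: action when q leaves the action band or a rejecting Westgard
    rule fires on the z-series; warning when q sits between the warning and
    action bands or 1-2S fires. Consecutive alarmed points are merged into
    episodes.
    """
    q = np.asarray(trace.q, dtype=float)
    log = AlarmLog(n_points=q.size)
    ts = trace.timestamps

    def stamp(i: int) -> Optional[pd.Timestamp]:
        return ts[i] if ts is not None and len(ts) == q.size else None

    if "limit_chart" in rules_enabled:
        outside_action = (q < limits.action_low) | (q > limits.action_high)
        outside_warn = (q < limits.warn_low) | (q > limits.warn_high)
        for i in np.flatnonzero(outside_action):
            log.records.append(
                AlarmRecord(int(i), stamp(int(i)), AlarmLevel.ACTION, "ewma>k_action")
            )
        for i in np.flatnonzero(outside_warn & ~outside_action):
            log.records.append(
                AlarmRecord(int(i), stamp(int(i)), AlarmLevel.WARNING, "ewma>k_warn")
            )

    if "westgard" in rules_enabled:
        for v in westgard_evaluate(limits.zscores(q)):
            log.records.append(AlarmRecord(v.index, stamp(v.index), v.level, v.rule))

    log.records.sort(key=lambda r: (r.index, r.level != AlarmLevel.ACTION, r.rule))
    log.episodes = _merge_episodes(log.alarmed_indices())
    return log
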
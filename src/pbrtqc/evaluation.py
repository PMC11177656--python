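"""Scoring alarm logs against a quality-risk register.

Conventions fixed here:

* Risk periods are half-open ``[onset, closure)``; a sample exactly at the
  onset instant is positive, one at the closure instant is negative.
* Ped is event-level: the percentage of risk events receiving at least one
  alarm inside their window, so ``Ped + FNR = 100`` by construction.
* FPR is sample-level: alarmed accepted samples outside every risk window,
  over all such negative samples.
* ANPed counts accepted samples from event onset up to and including the
  first alarmed sample, averaged over detected events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_model import PerformanceReport, QualityRiskEvent, ResultStream, ValidationError
from .monitor import AlarmLevel, AlarmLog, ControlLimits, EWMATrace

__all__ = [
    "LabeledStream",
    "ConfusionCounts",
    "ROCCurve",
    "ModelSelection",
    "label_stream",
    "confusion_counts",
    "event_metrics",
    "compute_anped",
    "roc_auc",
    "roc_auc_from_scores",
    "select_optimal",
    "DEFAULT_K_GRID",
]

DEFAULT_K_GRID = np.round(np.arange(0.0, 6.0 + 1e-9, 0.05), 10)


@dataclass
class LabeledStream:
    """Per-accepted-sample ground-truth labels against the risk register."""

    labels: np.ndarray  # bool, True inside a risk period
    event_ids: np.ndarray  # int, index into `events` for positives, -1 otherwise
    events: list[QualityRiskEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels))

    @property
    def n_negative(self) -> int:
        return int(np.sum(~self.labels))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    unit: str = "sample"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCCurve:
    points: np.ndarray  # (n, 2) array of (fpr, tpr), fpr non-decreasing
    thresholds: np.ndarray


@dataclass
class ModelSelection:
    analyte: str
    selected: Optional[PerformanceReport]
    provisional: bool
    reason: str = ""


def label_stream(
    stream: ResultStream, events: Sequence[QualityRiskEvent]
) -> LabeledStream:
    """Label each accepted sample positive iff it falls in [onset, closure).

    Overlapping windows resolve to the earliest-onset event id.
    """
    ts = stream.accepted_timestamps()
    n = len(ts)
    labels = np.zeros(n, dtype=bool)
    event_ids = np.full(n, -1, dtype=int)
    ordered = sorted(range(len(events)), key=lambda k: events[k].onset)
    for k in reversed(ordered):  # earliest onset applied last wins
        e = events[k]
        mask = (ts >= e.onset) & (ts < e.closure)
        labels |= np.asarray(mask)
        event_ids[np.asarray(mask)] = k
    return LabeledStream(labels=labels, event_ids=event_ids, events=list(events))


def confusion_counts(alarm_mask: np.ndarray, labeled: LabeledStream) -> ConfusionCounts:
    """Sample-level confusion counts; tp+fp+tn+fn equals the scored samples."""
    alarm_mask = np.asarray(alarm_mask, dtype=bool)
    if alarm_mask.size != len(labeled):
        raise ValidationError("alarm mask and labels cover different sample counts")
    pos = labeled.labels
    return ConfusionCounts(
        tp=int(np.sum(alarm_mask & pos)),
        fp=int(np.sum(alarm_mask & ~pos)),
        tn=int(np.sum(~alarm_mask & ~pos)),
        fn=int(np.sum(~alarm_mask & pos)),
    )


def _detected_events(alarm_mask: np.ndarray, labeled: LabeledStream) -> set[int]:
    hit = np.asarray(alarm_mask, dtype=bool) & labeled.labels
    return set(int(k) for k in np.unique(labeled.event_ids[hit]) if k >= 0)


def event_metrics(
    alarms: AlarmLog | np.ndarray,
    labeled: LabeledStream,
    level: Optional[AlarmLevel] = None,
) -> tuple[Optional[float], Optional[float], float]:
    """(Ped %, FNR %, sample FPR %) for one alarm log against the labels.

    Ped/FNR are None (undefined) when the register is empty. ``level``
    restricts which alarm records count (default: any level).
    """
    mask = alarms.alarm_mask(level) if isinstance(alarms, AlarmLog) else np.asarray(
        alarms, dtype=bool
    )
    if mask.size != len(labeled):
        raise ValidationError("alarms and labels cover different sample counts")
    n_events = len(labeled.events)
    if n_events == 0:
        ped = fnr = None
    else:
        # an event with zero in-window accepted samples can never alarm
        detected = _detected_events(mask, labeled)
        ped = 100.0 * len(detected) / n_events
        fnr = 100.0 - ped
    n_neg = labeled.n_negative
    fpr = 100.0 * float(np.sum(mask & ~labeled.labels)) / n_neg if n_neg else 0.0
    return ped, fnr, fpr


def compute_anped(
    alarms: AlarmLog | np.ndarray,
    labeled: LabeledStream,
    level: Optional[AlarmLevel] = None,
    rounded: bool = True,
) -> Optional[float]:
    """Mean accepted-sample count from onset to first in-window alarm.

    Counting is 1-based: an alarm on the first in-window accepted sample
    gives 1 for that event. Returns None when no event was detected.
    """
    mask = alarms.alarm_mask(level) if isinstance(alarms, AlarmLog) else np.asarray(
        alarms, dtype=bool
    )
    per_event: list[int] = []
    for k in range(len(labeled.events)):
        in_window = labeled.event_ids == k
        idx = np.flatnonzero(in_window & mask)
        if idx.size == 0:
            continue
        first_alarm = idx[0]
        window_idx = np.flatnonzero(in_window)
        # samples from onset up to and including the first alarmed one
        per_event.append(int(np.searchsorted(window_idx, first_alarm)) + 1)
    if not per_event:
        return None
    mean = float(np.mean(per_event))
    return float(round(mean)) if rounded else mean


def roc_auc_from_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    k_grid: Optional[np.ndarray] = None,
) -> tuple[ROCCurve, float]:
    """ROC/AUC from per-sample scores: threshold k flags ``score > k``.

    The swept thresholds are the supplied grid augmented with the observed
    score values, so the curve passes through every attainable operating
    point and the trapezoid AUC equals the rank (pairwise-concordance) AUC —
    in particular it is invariant to strictly monotone rescaling of the
    scores. Raises when all labels belong to one class (AUC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size != labels.size:
        raise ValidationError("scores and labels cover different sample counts")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: labels contain a single class")
    if k_grid is None:
        k_grid = DEFAULT_K_GRID
    thresholds = np.unique(np.concatenate([np.asarray(k_grid, dtype=float), scores]))
    tpr = np.array([np.sum(scores[labels] > k) / n_pos for k in thresholds])
    fpr = np.array([np.sum(scores[~labels] > k) / n_neg for k in thresholds])
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCCurve(points=pts, thresholds=thresholds), auc


def roc_auc(
    trace: EWMATrace,
    limits: ControlLimits,
    labeled: LabeledStream,
    k_grid: Optional[np.ndarray] = None,
) -> tuple[ROCCurve, float]:
    """ROC over the EWMA deviation score ``|q - center| / sd_ewma``."""
    scores = np.abs(limits.zscores(trace.q))
    if scores.size != len(labeled):
        raise ValidationError("trace and labels cover different sample counts")
    return roc_auc_from_scores(scores, labeled.labels, k_grid)


def select_optimal(
    reports: Sequence[PerformanceReport],
    ped_min: float = 90.0,
    fpr_max: float = 5.0,
) -> dict[str, ModelSelection]:
    """Optimality filter: Ped > ped_min and FPR < fpr_max, then max AUC.

    Ties on AUC resolve to the smaller lambda. When no report survives the
    filter the best-AUC report is returned flagged provisional.
    """
    by_analyte: dict[str, list[PerformanceReport]] = {}
    for r in reports:
        by_analyte.setdefault(r.analyte, []).append(r)

    selections: dict[str, ModelSelection] = {}
    for analyte, rows in by_analyte.items():
        survivors = [
            r
            for r in rows
            if r.ped is not None
            and r.auc is not None
            and r.ped > ped_min
            and r.fpr < fpr_max
        ]
        pool = survivors if survivors else [r for r in rows if r.auc is not None]
        if not pool:
            selections[analyte] = ModelSelection(
                analyte, None, True, "no report carries an AUC"
            )
            continue
        best = min(pool, key=lambda r: (-r.auc, r.lam))
        if survivors:
            selections[analyte] = ModelSelection(analyte, best, False)
        else:
            selections[analyte] = ModelSelection(
                analyte, best, True, "no model meets criteria; best AUC reported as provisional"
            )
    return selections
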
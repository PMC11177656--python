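"""Domain types and file I/O for patient-result streams, risk registers and reports.

Conventions
-----------
* Timestamps are ISO-8601, timezone-naive, parsed with pandas.
* Result CSVs carry the header ``timestamp,analyte,value,instrument``.
* Risk-event CSVs carry the header ``cause,onset,closure,corrective``.
* Streams are kept sorted by timestamp; ties keep original file order.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TruncationMethod",
    "AnalyteConfig",
    "PatientResult",
    "ResultStream",
    "QualityRiskEvent",
    "PerformanceReport",
    "RejectRecord",
    "ValidationError",
    "load_config",
    "read_results_csv",
    "write_results_csv",
    "read_risk_events",
    "write_risk_events",
    "write_report_csv",
    "write_report_json",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_K_WARN",
    "DEFAULT_K_ACTION",
]

DEFAULT_LAMBDA_GRID = (0.02, 0.03, 0.05)
DEFAULT_K_WARN = 2.0
DEFAULT_K_ACTION = 3.0


class ValidationError(ValueError):
    """Raised when an input file or configuration violates its contract."""


class TruncationMethod(str, enum.Enum):
    BOXCOX_NORMALITY = "boxcox_normality"
    BIOLOGICAL_VARIATION = "biological_variation"
    FIXED = "fixed"


@dataclass(frozen=True)
class AnalyteConfig:
    """Per-analyte monitoring configuration.

    ``cvi`` / ``cvg`` are within-/between-subject biological variation in
    percent; either may be ``None`` when unavailable (downstream formulas
    degrade to the CVs that are present).
    """

    analyte_name: str
    units: str = ""
    cvi: Optional[float] = None
    cvg: Optional[float] = None
    reference_interval: Optional[tuple[float, float]] = None
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    truncation_method: TruncationMethod = TruncationMethod.BOXCOX_NORMALITY
    truncation_params: dict = field(default_factory=dict)
    k_warn: float = DEFAULT_K_WARN
    k_action: float = DEFAULT_K_ACTION
    rules_enabled: frozenset[str] = frozenset({"limit_chart"})

    def __post_init__(self) -> None:
        if not self.analyte_name:
            raise ValidationError("analyte_name must be non-empty")
        for lam in self.lambda_grid:
            if not (0.0 < lam < 1.0):
                raise ValidationError(
                    f"{self.analyte_name}: lambda {lam} outside the open interval (0, 1)"
                )
        for label, cv in (("cvi", self.cvi), ("cvg", self.cvg)):
            if cv is not None and cv < 0:
                raise ValidationError(f"{self.analyte_name}: {label}={cv} is negative")
        if self.k_warn <= 0 or self.k_action <= 0:
            raise ValidationError(f"{self.analyte_name}: limit multipliers must be positive")
        if self.k_warn >= self.k_action:
            raise ValidationError(
                f"{self.analyte_name}: k_warn={self.k_warn} must be below k_action={self.k_action}"
            )
        allowed_rules = {"limit_chart", "westgard"}
        if not set(self.rules_enabled) <= allowed_rules:
            raise ValidationError(
                f"{self.analyte_name}: unknown rules {set(self.rules_enabled) - allowed_rules}"
            )
        if self.truncation_method is TruncationMethod.FIXED:
            low = self.truncation_params.get("low")
            high = self.truncation_params.get("high")
            if low is None or high is None or not (low < high):
                raise ValidationError(
                    f"{self.analyte_name}: fixed truncation requires explicit low < high"
                )
        if self.reference_interval is not None:
            lo, hi = self.reference_interval
            if not lo < hi:
                raise ValidationError(
                    f"{self.analyte_name}: reference interval low must be below high"
                )


@dataclass
class PatientResult:
    """One observation x_t consumed by the moving-average recursion."""

    timestamp: pd.Timestamp
    value: float
    instrument_id: str = ""
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError(f"non-finite result value {self.value!r}")
        if self.excluded and not self.exclusion_reason:
            raise ValidationError("excluded result requires a non-empty reason")


@dataclass
class RejectRecord:
    """A CSV row that could not be parsed into a PatientResult."""

    row_number: int
    reason: str
    raw: dict


@dataclass
class ResultStream:
    """Time-ordered patient results for a single analyte."""

    analyte_name: str
    results: list[PatientResult] = field(default_factory=list)
    rejects: list[RejectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = [r.timestamp for r in self.results]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValidationError("result timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    @property
    def accepted(self) -> list[PatientResult]:
        return [r for r in self.results if not r.excluded]

    def accepted_values(self) -> np.ndarray:
        return np.asarray([r.value for r in self.results if not r.excluded], dtype=float)

    def accepted_timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([r.timestamp for r in self.results if not r.excluded])

    def values(self) -> np.ndarray:
        return np.asarray([r.value for r in self.results], dtype=float)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([r.timestamp for r in self.results])

    def copy(self) -> "ResultStream":
        return ResultStream(
            analyte_name=self.analyte_name,
            results=[dataclasses.replace(r) for r in self.results],
            rejects=list(self.rejects),
        )


@dataclass(frozen=True)
class QualityRiskEvent:
    """Ground-truth quality-risk window [onset, closure)."""

    cause: str
    onset: pd.Timestamp
    closure: pd.Timestamp
    corrective_measure: str = ""

    def __post_init__(self) -> None:
        if not self.onset < self.closure:
            raise ValidationError(
                f"risk event '{self.cause}': onset {self.onset} not before closure {self.closure}"
            )

    def contains(self, t: pd.Timestamp) -> bool:
        return self.onset <= t < self.closure


@dataclass
class PerformanceReport:
    """Evaluation metrics for one (analyte, truncation arm, lambda) model."""

    analyte: str
    arm: str  # "traditional" | "bv_heuristic"
    lam: float
    ped: Optional[float]  # percent; None when no events to detect
    fpr: float  # percent
    fnr: Optional[float]  # percent; 100 - ped
    anped: Optional[float]  # None when no event detected
    auc: Optional[float]
    n_samples: int = 0
    n_alarms: int = 0
    truncation_low: Optional[float] = None
    truncation_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ped is not None and self.fnr is not None:
            if abs(self.ped + self.fnr - 100.0) > 1e-6:
                raise ValidationError(
                    f"{self.analyte} lam={self.lam}: ped + fnr must equal 100"
                )
        if self.auc is not None and not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"{self.analyte} lam={self.lam}: auc outside [0, 1]")


# ---------------------------------------------------------------------------
# configuration loading


def _config_from_mapping(name: str, entry: dict) -> AnalyteConfig:
    ref = entry.get("reference_interval")
    if ref is not None:
        ref = (float(ref[0]), float(ref[1]))
    method = TruncationMethod(entry.get("truncation_method", "boxcox_normality"))
    rules = entry.get("rules_enabled", ["limit_chart"])
    return AnalyteConfig(
        analyte_name=name,
        units=str(entry.get("units", "")),
        cvi=None if entry.get("cvi") in (None, "", "/") else float(entry["cvi"]),
        cvg=None if entry.get("cvg") in (None, "", "/") else float(entry["cvg"]),
        reference_interval=ref,
        lambda_grid=tuple(float(l) for l in entry.get("lambda_grid", DEFAULT_LAMBDA_GRID)),
        truncation_method=method,
        truncation_params={k: float(v) for k, v in (entry.get("truncation_params") or {}).items()},
        k_warn=float(entry.get("k_warn", DEFAULT_K_WARN)),
        k_action=float(entry.get("k_action", DEFAULT_K_ACTION)),
        rules_enabled=frozenset(rules),
    )


def load_config(path: str | Path) -> list[AnalyteConfig]:
    """Load per-analyte configurations from a YAML/JSON document.

    The document maps analyte names to entries; defaults are filled for
    absent keys (``k_warn=2``, ``k_action=3``, the standard lambda grid).
    """
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config root must be a mapping of analyte -> entry")
    entries = doc.get("analytes", doc)
    configs = []
    for name, entry in entries.items():
        configs.append(_config_from_mapping(str(name), entry or {}))
    return configs


# ---------------------------------------------------------------------------
# result-stream CSV I/O

RESULT_COLUMNS = ["timestamp", "analyte", "value", "instrument"]


def read_results_csv(path: str | Path) -> ResultStream:
    """Read a ``timestamp,analyte,value,instrument`` CSV into a sorted stream.

    Rows with unparseable values or timestamps are collected as
    :class:`RejectRecord` entries rather than aborting the load. The stream
    is returned sorted by timestamp, stable among equal timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty result file", stacklevel=2)
        return ResultStream(analyte_name="", results=[])

    analytes = df["analyte"].unique()
    analyte_name = str(analytes[0]) if len(analytes) else ""
    if len(analytes) > 1:
        raise ValidationError(f"{path}: stream mixes analytes {sorted(analytes)}")

    results: list[tuple[pd.Timestamp, int, PatientResult]] = []
    rejects: list[RejectRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        raw = dict(zip(df.columns, row))
        try:
            value = float(raw["value"])
            if not math.isfinite(value):
                raise ValueError("non-finite value")
            ts = pd.Timestamp(raw["timestamp"])
            if pd.isna(ts):
                raise ValueError("unparseable timestamp")
        except (ValueError, TypeError) as exc:
            rejects.append(RejectRecord(row_number=i, reason=str(exc), raw=raw))
            continue
        results.append(
            (ts, i, PatientResult(timestamp=ts, value=value, instrument_id=raw["instrument"]))
        )
    results.sort(key=lambda t: (t[0], t[1]))  # stable on file order for ties
    return ResultStream(
        analyte_name=analyte_name, results=[r for _, _, r in results], rejects=rejects
    )


def write_results_csv(stream: ResultStream, path: str | Path) -> None:
    rows = [
        {
            "timestamp": r.timestamp.isoformat(),
            "analyte": stream.analyte_name,
            "value": repr(r.value),
            "instrument": r.instrument_id,
        }
        for r in stream.results
    ]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# risk-register CSV I/O

EVENT_COLUMNS = ["cause", "onset", "closure", "corrective"]


def read_risk_events(path: str | Path) -> list[QualityRiskEvent]:
    """Read a ``cause,onset,closure,corrective`` CSV, sorted by onset.

    Overlapping windows are permitted; a row whose onset is not strictly
    before its closure raises :class:`ValidationError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = dict(zip(df.columns, row))
        onset = pd.Timestamp(raw["onset"])
        closure = pd.Timestamp(raw["closure"])
        if pd.isna(onset) or pd.isna(closure):
            raise ValidationError(f"{path} row {i}: unparseable onset/closure")
        if not onset < closure:
            raise ValidationError(f"{path} row {i}: onset {onset} not before closure {closure}")
        events.append(
            QualityRiskEvent(
                cause=raw["cause"],
                onset=onset,
                closure=closure,
                corrective_measure=raw["corrective"],
            )
        )
    events.sort(key=lambda e: e.onset)
    return events


def write_risk_events(events: Sequence[QualityRiskEvent], path: str | Path) -> None:
    rows = [
        {
            "cause": e.cause,
            "onset": e.onset.isoformat(),
            "closure": e.closure.isoformat(),
            "corrective": e.corrective_measure,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# performance-report output

REPORT_COLUMNS = [
    "analyte",
    "arm",
    "lambda",
    "truncation_low",
    "truncation_high",
    "n",
    "n_alarms",
    "ped",
    "fpr",
    "fnr",
    "anped",
    "auc",
]


def _report_row(r: PerformanceReport) -> dict:
    return {
        "analyte": r.analyte,
        "arm": r.arm,
        "lambda": r.lam,
        "truncation_low": r.truncation_low,
        "truncation_high": r.truncation_high,
        "n": r.n_samples,
        "n_alarms": r.n_alarms,
        "ped": r.ped,
        "fpr": r.fpr,
        "fnr": r.fnr,
        "anped": "-" if r.anped is None else r.anped,
        "auc": r.auc,
    }


def write_report_csv(reports: Iterable[PerformanceReport], path: str | Path) -> None:
    pd.DataFrame([_report_row(r) for r in reports], columns=REPORT_COLUMNS).to_csv(
        path, index=False
    )


def write_report_json(reports: Iterable[PerformanceReport], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump([_report_row(r) for r in reports], fh, indent=2, default=str)
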
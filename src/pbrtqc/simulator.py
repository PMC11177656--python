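"""Synthetic patient-result streams with injected analytical-error events.

Streams are generated from a median plus within-subject, between-subject and
analytical CVs; the skewed family is a median-preserving lognormal, matching
the right skew typical of patient-result distributions. Errors (step bias,
drift, imprecision inflation) act on the measurand value before truncation,
so a large bias can push samples out of the truncation range — the failure
mode where truncation eats the error signal.

All randomness flows through explicit integer seeds; no global RNG state.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_model import PatientResult, QualityRiskEvent, ResultStream, ValidationError
from .evaluation import LabeledStream, label_stream

__all__ = [
    "ErrorKind",
    "StreamSpec",
    "ErrorSpec",
    "Scenario",
    "simulate_stream",
    "inject_error",
    "build_scenario",
    "load_scenario",
]

EPOCH = pd.Timestamp("2022-01-01")


class ErrorKind(str, enum.Enum):
    STEP_BIAS = "step_bias"
    DRIFT = "drift"
    IMPRECISION_INFLATION = "imprecision_inflation"


@dataclass(frozen=True)
class StreamSpec:
    """Generative parameters for one analyte stream; seed is mandatory."""

    median: float
    cvi: float
    cvg: float
    cva: float
    seed: int
    n_per_day: float = 100.0
    n_days: int = 30
    skew_target: str = "lognormal"  # "none" | "lognormal"
    outlier_fraction: float = 0.0
    analyte_name: str = "synthetic"
    start: pd.Timestamp = EPOCH

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValidationError("median must be positive")
        for label, cv in (("cvi", self.cvi), ("cvg", self.cvg), ("cva", self.cva)):
            if cv < 0 or not np.isfinite(cv):
                raise ValidationError(f"{label} must be a finite non-negative percent")
        if not (0.0 <= self.outlier_fraction <= 0.05):
            raise ValidationError("outlier_fraction must lie in [0, 0.05]")
        if self.n_per_day <= 0 or self.n_days <= 0:
            raise ValidationError("n_per_day and n_days must be positive")
        if self.skew_target not in ("none", "lognormal"):
            raise ValidationError(f"unknown skew_target {self.skew_target!r}")

    @property
    def total_cv(self) -> float:
        return float(np.sqrt(self.cvi**2 + self.cvg**2 + self.cva**2))


@dataclass(frozen=True)
class ErrorSpec:
    """A scheduled analytical error over [onset_day, closure_day).

    ``magnitude`` is in multiples of the training SD for step bias, SD per
    100 samples for drift, and is the SD multiplier for imprecision
    inflation.
    """

    kind: ErrorKind
    magnitude: float
    onset_day: float
    closure_day: float
    cause_label: str = ""

    def __post_init__(self) -> None:
        if not self.onset_day < self.closure_day:
            raise ValidationError("error onset_day must precede closure_day")
        if self.magnitude <= 0:
            raise ValidationError("error magnitude must be positive")


@dataclass
class Scenario:
    stream: ResultStream
    events: list[QualityRiskEvent]
    labels: LabeledStream
    clean_stream: ResultStream = None
    sd_train: float = 0.0


def _lognormal_sigma(cv_percent: float) -> float:
    c = cv_percent / 100.0
    return float(np.sqrt(np.log1p(c * c)))


def simulate_stream(spec: StreamSpec) -> ResultStream:
    """Generate a Poisson-arrival stream; bit-identical for equal specs.

    Subject means vary lognormally with CV ``cvg`` about the median and the
    per-result noise has CV ``sqrt(cvi^2 + cva^2)``; with ``skew_target
    "none"`` the same CVs enter as additive Gaussian components instead.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(rng.poisson(spec.n_per_day * spec.n_days))
    # Poisson process on [0, n_days): order statistics of uniforms
    t_days = np.sort(rng.uniform(0.0, spec.n_days, size=n))
    cv_within = float(np.hypot(spec.cvi, spec.cva))

    if spec.skew_target == "lognormal":
        sg = _lognormal_sigma(spec.cvg)
        sw = _lognormal_sigma(cv_within)
        subject = np.exp(rng.normal(0.0, sg, size=n)) if sg > 0 else np.ones(n)
        noise = np.exp(rng.normal(0.0, sw, size=n)) if sw > 0 else np.ones(n)
        values = spec.median * subject * noise
    else:
        subject = rng.normal(0.0, spec.cvg / 100.0, size=n) if spec.cvg > 0 else np.zeros(n)
        noise = rng.normal(0.0, cv_within / 100.0, size=n) if cv_within > 0 else np.zeros(n)
        values = spec.median * (1.0 + subject + noise)

    if spec.outlier_fraction > 0:
        is_outlier = rng.random(n) < spec.outlier_fraction
        values = np.where(
            is_outlier,
            rng.uniform(spec.median / 5.0, 5.0 * spec.median, size=n),
            values,
        )

    timestamps = spec.start + pd.to_timedelta(t_days, unit="D")
    results = [
        PatientResult(timestamp=ts, value=float(v), instrument_id="sim")
        for ts, v in zip(timestamps, values)
    ]
    return ResultStream(analyte_name=spec.analyte_name, results=results)


def inject_error(
    stream: ResultStream, spec: ErrorSpec, sd_train: float, start: Optional[pd.Timestamp] = None
) -> tuple[ResultStream, QualityRiskEvent]:
    """Apply one scheduled error; returns the modified stream and its event.

    Out-of-window values are untouched. The error window must lie inside the
    stream's time span.
    """
    if sd_train <= 0:
        raise ValidationError("sd_train must be positive")
    if len(stream) == 0:
        raise ValidationError("cannot inject into an empty stream")
    ts = stream.timestamps()
    t0 = start if start is not None else ts[0].normalize()
    onset = t0 + pd.Timedelta(days=float(spec.onset_day))
    closure = t0 + pd.Timedelta(days=float(spec.closure_day))
    span_end = ts[-1]
    if onset > span_end or closure <= ts[0]:
        raise ValidationError(
            f"error window [{onset}, {closure}) lies outside the stream span"
        )
    in_window = np.asarray((ts >= onset) & (ts < closure))
    values = stream.values()
    new_values = values.copy()

    if spec.kind is ErrorKind.STEP_BIAS:
        new_values[in_window] += spec.magnitude * sd_train
    elif spec.kind is ErrorKind.DRIFT:
        k = np.arange(int(np.sum(in_window)), dtype=float)  # samples since onset
        new_values[in_window] += spec.magnitude * sd_train * k / 100.0
    elif spec.kind is ErrorKind.IMPRECISION_INFLATION:
        baseline = float(np.mean(values[~in_window])) if np.any(~in_window) else float(
            np.mean(values)
        )
        new_values[in_window] = baseline + spec.magnitude * (values[in_window] - baseline)
    else:  # pragma: no cover
        raise ValidationError(f"unknown error kind {spec.kind}")

    results = [
        replace(r, value=float(v)) if hit else replace(r)
        for r, v, hit in zip(stream.results, new_values, in_window)
    ]
    event = QualityRiskEvent(
        cause=spec.cause_label or spec.kind.value,
        onset=onset,
        closure=closure,
        corrective_measure="simulated correction",
    )
    return (
        ResultStream(analyte_name=stream.analyte_name, results=results,
                     rejects=list(stream.rejects)),
        event,
    )


def build_scenario(
    spec: StreamSpec,
    errors: Sequence[ErrorSpec] = (),
    train_fraction: float = 6.0 / 11.0,
) -> Scenario:
    """Compose a stream, its ground-truth register, and consistent labels.

    ``sd_train`` for error magnitudes is the SD of the clean stream's first
    ``train_fraction`` of samples. Overlapping error windows of different
    kinds compose in declaration order (a warning is emitted).
    """
    clean = simulate_stream(spec)
    n_train = max(int(len(clean) * train_fraction), 2)
    sd_train = float(np.std(clean.values()[:n_train], ddof=1))
    if sd_train == 0.0:
        sd_train = max(1e-12, 0.01 * spec.median)

    for a, b in zip(errors, list(errors)[1:]):
        if a.closure_day > b.onset_day and a.kind != b.kind:
            warnings.warn(
                "overlapping error windows of different kinds; composing in declaration order",
                stacklevel=2,
            )

    stream = clean
    events: list[QualityRiskEvent] = []
    for espec in errors:
        stream, event = inject_error(stream, espec, sd_train, start=spec.start)
        events.append(event)
    labels = label_stream(stream, events)
    return Scenario(
        stream=stream, events=events, labels=labels, clean_stream=clean, sd_train=sd_train
    )


def load_scenario(path: str | Path, seed: Optional[int] = None) -> Scenario:
    """Build a scenario from a YAML/JSON document (see docs for the schema).

    A ``seed`` argument overrides the document's seed, letting callers drive
    replicates from the command line.
    """
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "stream" not in doc:
        raise ValidationError(f"{path}: scenario document must carry a 'stream' section")
    sdoc = dict(doc["stream"])
    if seed is not None:
        sdoc["seed"] = int(seed)
    if "seed" not in sdoc:
        raise ValidationError(f"{path}: stream seed is mandatory")
    if "start" in sdoc:
        sdoc["start"] = pd.Timestamp(sdoc["start"])
    spec = StreamSpec(**sdoc)
    errors = [
        ErrorSpec(
            kind=ErrorKind(e["kind"]),
            magnitude=float(e["magnitude"]),
            onset_day=float(e["onset_day"]),
            closure_day=float(e["closure_day"]),
            cause_label=str(e.get("cause_label", "")),
        )
        for e in doc.get("errors", [])
    ]
    train_fraction = float(doc.get("train_fraction", 6.0 / 11.0))
    return build_scenario(spec, errors, train_fraction=train_fraction)
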
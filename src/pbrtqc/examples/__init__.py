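"""Worked-example fixtures: a published-style benchmark table and risk register.

``WORKED_EXAMPLE_REPORTS`` transcribes a per-analyte model-comparison table
(two truncation arms x three weighting coefficients, with Ped/FPR/FNR/ANPed/
AUC) used throughout the docs and acceptance checks to exercise
:func:`pbrtqc.evaluation.select_optimal`. ``risk_register_path`` points at
the companion nine-event quality-risk register CSV.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from ..core_model import PerformanceReport, QualityRiskEvent

__all__ = [
    "WORKED_EXAMPLE_REPORTS",
    "WORKED_EXAMPLE_ANALYTES",
    "worked_example_reports",
    "risk_register_path",
    "count_calibration_related",
]

# analyte, arm, lambda, trunc_low, trunc_high, n, n_alarms, ped, fpr, fnr, anped, auc
_ROWS = [
    ("TT4", "bv_heuristic", 0.02, 78.0, 186.0, 1315, 336, 0.0, 0.0, 100.0, None, 0.911),
    ("TT4", "bv_heuristic", 0.03, 78.0, 186.0, 1315, 336, 80.95, 0.0, 19.05, 8, 0.913),
    ("TT4", "bv_heuristic", 0.05, 78.0, 186.0, 1315, 336, 92.26, 2.6, 7.74, 3, 0.921),
    ("TT4", "traditional", 0.02, 82.15, 200.19, 1431, 334, 0.0, 0.0, 100.0, None, 0.843),
    ("TT4", "traditional", 0.03, 82.15, 200.19, 1431, 334, 0.0, 0.0, 100.0, None, 0.839),
    ("TT4", "traditional", 0.05, 82.15, 200.19, 1431, 334, 69.16, 10.67, 30.84, 5, 0.834),
    ("AMH", "bv_heuristic", 0.02, 0.02, 2.96, 734, 314, 96.82, 0.0, 3.18, 2, 0.887),
    ("AMH", "bv_heuristic", 0.03, 0.02, 2.96, 734, 314, 66.56, 47.38, 33.44, 35, 0.837),
    ("AMH", "bv_heuristic", 0.05, 0.02, 2.96, 734, 314, 28.03, 19.52, 71.97, 40, 0.759),
    ("AMH", "traditional", 0.02, 0.02, 10.14, 1125, 501, 41.52, 15.54, 58.48, 68, 0.418),
    ("AMH", "traditional", 0.03, 0.02, 10.14, 1125, 501, 41.32, 0.96, 58.68, 71, 0.419),
    ("AMH", "traditional", 0.05, 0.02, 10.14, 1125, 501, 39.52, 35.42, 60.48, 80, 0.436),
    ("ALT", "bv_heuristic", 0.02, 10.0, 25.0, 11343, 1856, 96.98, 1.82, 3.02, 6, 0.916),
    ("ALT", "bv_heuristic", 0.03, 10.0, 25.0, 11343, 1856, 77.75, 1.88, 22.25, 8, 0.882),
    ("ALT", "bv_heuristic", 0.05, 10.0, 25.0, 11343, 1856, 72.14, 10.06, 27.86, 0, 0.834),
    ("ALT", "traditional", 0.02, 6.0, 29.0, 12284, 2185, 90.94, 15.05, 9.06, 0, 0.894),
    ("ALT", "traditional", 0.03, 6.0, 29.0, 12284, 2185, 32.72, 33.61, 67.28, 0, 0.859),
    ("ALT", "traditional", 0.05, 6.0, 29.0, 12284, 2185, 48.88, 37.82, 51.12, 0, 0.817),
    ("TC", "bv_heuristic", 0.02, 2.84, 5.87, 2697, 2143, 90.85, 0.0, 9.15, 24, 0.957),
    ("TC", "bv_heuristic", 0.03, 2.84, 5.87, 2697, 2143, 72.52, 0.0, 27.48, 32, 0.947),
    ("TC", "bv_heuristic", 0.05, 2.84, 5.87, 2697, 2143, 59.4, 9.03, 40.6, 44, 0.948),
    ("TC", "traditional", 0.02, 2.79, 6.4, 2929, 2345, 80.94, 22.09, 19.06, 0, 0.894),
    ("TC", "traditional", 0.03, 2.79, 6.4, 2929, 2345, 76.67, 30.65, 23.33, 0, 0.859),
    ("TC", "traditional", 0.05, 2.79, 6.4, 2929, 2345, 63.8, 41.61, 36.2, 0, 0.817),
    ("UREA", "bv_heuristic", 0.02, 3.5, 6.6, 3083, 246, 92.28, 0.0, 7.72, 5, 0.744),
    ("UREA", "bv_heuristic", 0.03, 3.5, 6.6, 3083, 246, 76.02, 4.76, 23.98, 0, 0.735),
    ("UREA", "bv_heuristic", 0.05, 3.5, 6.6, 3083, 246, 71.54, 12.34, 28.46, 0, 0.719),
    ("UREA", "traditional", 0.02, 2.3, 7.68, 3116, 210, 61.9, 77.7, 38.1, 0, 0.322),
    ("UREA", "traditional", 0.03, 2.3, 7.68, 3116, 210, 13.81, 35.07, 86.19, 0, 0.37),
    ("UREA", "traditional", 0.05, 2.3, 7.68, 3116, 210, 48.1, 30.35, 51.9, 0, 0.412),
    ("ALB", "bv_heuristic", 0.02, 43.0, 52.0, 10071, 717, 0.0, 0.0, 100.0, None, 0.723),
    ("ALB", "bv_heuristic", 0.03, 43.0, 52.0, 10071, 717, 0.0, 0.0, 100.0, None, 0.734),
    ("ALB", "bv_heuristic", 0.05, 43.0, 52.0, 10071, 717, 90.66, 0.0, 9.34, 12, 0.745),
    ("ALB", "traditional", 0.02, 41.9, 53.1, 11468, 717, 0.0, 13.5, 100.0, None, 0.715),
    ("ALB", "traditional", 0.03, 41.9, 53.1, 11468, 717, 69.18, 0.0, 30.82, 0, 0.726),
    ("ALB", "traditional", 0.05, 41.9, 53.1, 11468, 717, 43.51, 17.41, 56.49, 0, 0.727),
]

WORKED_EXAMPLE_REPORTS: list[PerformanceReport] = [
    PerformanceReport(
        analyte=a,
        arm=arm,
        lam=lam,
        ped=ped,
        fpr=fpr,
        fnr=fnr,
        anped=anped,
        auc=auc,
        n_samples=n,
        n_alarms=n_alarms,
        truncation_low=lo,
        truncation_high=hi,
    )
    for a, arm, lam, lo, hi, n, n_alarms, ped, fpr, fnr, anped, auc in _ROWS
]

WORKED_EXAMPLE_ANALYTES = ("TT4", "AMH", "ALT", "TC", "UREA", "ALB")


def worked_example_reports(analyte: Optional[str] = None) -> list[PerformanceReport]:
    """All worked-example rows, optionally filtered to one analyte."""
    if analyte is None:
        return list(WORKED_EXAMPLE_REPORTS)
    return [r for r in WORKED_EXAMPLE_REPORTS if r.analyte == analyte]


def risk_register_path() -> Path:
    """Path to the bundled nine-event risk-register CSV."""
    return Path(resources.files(__package__) / "risk_register.csv")


_CALIBRATION_RE = re.compile(r"calibrat", re.IGNORECASE)


def count_calibration_related(events: Sequence[QualityRiskEvent]) -> int:
    """Events whose cause or corrective measure mentions calibration."""
    return sum(
        1
        for e in events
        if _CALIBRATION_RE.search(e.cause) or _CALIBRATION_RE.search(e.corrective_measure)
    )
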
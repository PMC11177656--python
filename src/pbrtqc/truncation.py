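"""Truncation-range estimation and application.

Two estimators are provided:

* :func:`truncation_by_normality` — power-transform the training values to
  approximate normality (profile-likelihood Box-Cox fit), take a central
  ``mean +/- k_sigma * SD`` interval in transformed space, and back-transform.
* :func:`truncation_by_bv` — a documented heuristic centred on the median
  with half-width proportional to combined biological variation.

Values outside the chosen range are marked excluded, never dropped or
winsorized, so downstream consumers can account for them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .core_model import ResultStream, TruncationMethod, ValidationError

__all__ = [
    "BoxCoxFit",
    "TruncationRange",
    "ExclusionStats",
    "boxcox_transform",
    "boxcox_inverse",
    "fit_boxcox_lambda",
    "truncation_by_normality",
    "truncation_by_bv",
    "fixed_truncation",
    "apply_truncation",
]

BC_LAMBDA_BOUNDS = (-2.0, 2.0)
BC_GRID_STEP = 0.01


@dataclass(frozen=True)
class BoxCoxFit:
    """Maximum-likelihood power-transform fit.

    ``bc_lambda`` is the power exponent (unrelated to the EWMA weighting
    coefficient); ``shift`` is the additive offset that was applied to make
    the data positive before fitting (0 for already-positive data).
    """

    bc_lambda: float
    loglik: float
    shift: float = 0.0


@dataclass(frozen=True)
class TruncationRange:
    low: float
    high: float
    method: TruncationMethod
    retained_fraction: float
    bc_lambda: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"truncation low {self.low} must be below high {self.high}")

    def contains(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return (values >= self.low) & (values <= self.high)


@dataclass(frozen=True)
class ExclusionStats:
    n_total: int
    n_kept: int
    n_excluded: int


def _as_positive_array(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValidationError(f"{name}: empty input")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite entries")
    return arr


def boxcox_transform(values, bc_lambda: float) -> np.ndarray:
    """Power transform ``(x**l - 1)/l`` (``ln x`` at ``l = 0``).

    Continuous in the exponent at 0; requires strictly positive input.
    """
    arr = _as_positive_array(values)
    if np.any(arr <= 0):
        raise ValidationError("boxcox_transform requires strictly positive values")
    if bc_lambda == 0.0:
        return np.log(arr)
    # expm1 form stays accurate for exponents near zero
    return np.expm1(bc_lambda * np.log(arr)) / bc_lambda


def boxcox_inverse(y, bc_lambda: float) -> np.ndarray:
    """Inverse of :func:`boxcox_transform`; +/-inf where out of domain."""
    y = np.asarray(y, dtype=float)
    if bc_lambda == 0.0:
        return np.exp(y)
    base = 1.0 + bc_lambda * y
    out = np.full_like(y, np.nan, dtype=float)
    ok = base > 0
    out[ok] = np.exp(np.log1p(bc_lambda * y[ok]) / bc_lambda)
    # out-of-domain points map to the transform's range limit
    out[~ok] = np.inf if bc_lambda < 0 else (0.0 if bc_lambda > 0 else np.nan)
    return out


def shift_for_positivity(values: np.ndarray) -> float:
    """Additive offset making all values strictly positive (0 if already)."""
    lo = float(np.min(values))
    if lo > 0:
        return 0.0
    span = float(np.max(values) - lo)
    eps = 1e-6 * span if span > 0 else 1e-6
    return eps - lo


def fit_boxcox_lambda(values) -> BoxCoxFit:
    """Profile-likelihood Box-Cox exponent on a coarse grid plus refinement.

    Scans ``[-2, 2]`` at step 0.01 and polishes the best grid point with a
    bounded scalar optimizer, so the estimate can never be worse than the
    grid argmax.
    """
    arr = _as_positive_array(values)
    if np.unique(arr).size < 2:
        raise ValidationError("fit_boxcox_lambda: constant input has no normality optimum")
    shift = shift_for_positivity(arr)
    x = arr + shift

    lo, hi = BC_LAMBDA_BOUNDS
    grid = np.arange(lo, hi + BC_GRID_STEP / 2, BC_GRID_STEP)
    ll = np.array([stats.boxcox_llf(l, x) for l in grid])
    best = int(np.argmax(ll))

    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda l: -stats.boxcox_llf(l, x), bounds=(a, b), method="bounded"
    )
    bc_lambda = float(res.x)
    loglik = float(-res.fun)
    if loglik < ll[best]:  # bounded search can only improve on the grid point
        bc_lambda, loglik = float(grid[best]), float(ll[best])
    return BoxCoxFit(bc_lambda=bc_lambda, loglik=loglik, shift=shift)


def truncation_by_normality(values, k_sigma: float = 3.0) -> TruncationRange:
    """Central ``mean +/- k_sigma*SD`` interval in Box-Cox space, back-transformed.

    The bounds are intersected with the observed data range, so the interval
    never extends beyond values actually seen in training.
    """
    if k_sigma <= 0:
        raise ValidationError("k_sigma must be positive")
    arr = _as_positive_array(values)
    fit = fit_boxcox_lambda(arr)
    y = boxcox_transform(arr + fit.shift, fit.bc_lambda)
    mu, sd = float(np.mean(y)), float(np.std(y, ddof=1))
    bounds_t = np.array([mu - k_sigma * sd, mu + k_sigma * sd])
    bounds = boxcox_inverse(bounds_t, fit.bc_lambda) - fit.shift
    low = max(float(bounds[0]), float(np.min(arr)))
    high = min(float(bounds[1]), float(np.max(arr)))
    if not low < high:  # degenerate sd; fall back to the data range
        low, high = float(np.min(arr)), float(np.max(arr))
    retained = float(np.mean((arr >= low) & (arr <= high)))
    return TruncationRange(
        low=low,
        high=high,
        method=TruncationMethod.BOXCOX_NORMALITY,
        retained_fraction=retained,
        bc_lambda=fit.bc_lambda,
    )


def truncation_by_bv(
    values,
    cvi: Optional[float],
    cvg: Optional[float] = None,
    k_bv: float = 2.0,
) -> TruncationRange:
    """Median-centred interval scaled by combined biological variation.

    half_width = k_bv * median * sqrt(cvi^2 + cvg^2) / 100, with an absent
    cvg treated as 0. Bounds are clipped to the [0.5th, 99.5th] percentiles
    of the training values so the interval stays inside the observed bulk.
    """
    if cvi is None:
        raise ValidationError("truncation_by_bv requires cvi (within-subject variation)")
    if k_bv <= 0:
        raise ValidationError("k_bv must be positive")
    arr = _as_positive_array(values)
    center = float(np.median(arr))
    cv_total = float(np.hypot(cvi, cvg or 0.0))
    half_width = k_bv * center * cv_total / 100.0
    p_lo, p_hi = np.percentile(arr, [0.5, 99.5])
    low = max(center - half_width, float(p_lo))
    high = min(center + half_width, float(p_hi))
    if not low < high:
        low, high = float(p_lo), float(p_hi)
    retained = float(np.mean((arr >= low) & (arr <= high)))
    return TruncationRange(
        low=low,
        high=high,
        method=TruncationMethod.BIOLOGICAL_VARIATION,
        retained_fraction=retained,
    )


def fixed_truncation(values, low: float, high: float) -> TruncationRange:
    arr = _as_positive_array(values)
    retained = float(np.mean((arr >= low) & (arr <= high)))
    return TruncationRange(
        low=float(low), high=float(high), method=TruncationMethod.FIXED,
        retained_fraction=retained,
    )


def apply_truncation(
    stream: ResultStream, trange: TruncationRange
) -> tuple[ResultStream, ExclusionStats]:
    """Mark results outside ``[low, high]`` as excluded (reason "truncated").

    Order is preserved and values are never mutated; a new stream is
    returned, the input is untouched.
    """
    out_results = []
    n_excl = 0
    for r in stream.results:
        if not r.excluded and not (trange.low <= r.value <= trange.high):
            out_results.append(
                dataclasses.replace(r, excluded=True, exclusion_reason="truncated")
            )
            n_excl += 1
        else:
            out_results.append(dataclasses.replace(r))
            if r.excluded:
                n_excl += 1
    stats_ = ExclusionStats(
        n_total=len(out_results),
        n_kept=len(out_results) - n_excl,
        n_excluded=n_excl,
    )
    return (
        ResultStream(analyte_name=stream.analyte_name, results=out_results,
                     rejects=list(stream.rejects)),
        stats_,
    )
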
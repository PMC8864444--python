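"""Logistic dose-response fitting and hit selection.

Each (gene, drug, timepoint) similarity series is min-max scaled to [0, 1]
and fitted with the two-parameter logistic

    f(x) = 1 / (1 + exp(-k (x - x0))),   x = log10(inducer dose in nM)

by nonlinear least squares (forward-difference Jacobian, starting point
x0 = 2, k = 0); the uninduced point (dose 0) is placed one log10 unit below
the smallest positive dose.  Fit quality is the trace of the estimated
parameter covariance (lower is better).  Hits are comparisons whose quality
is in the best decile for their gene, whose maximum absolute similarity
reaches the positive-control benchmark, whose inflection lies within the
dosed range, and whose drug is not on the exclusion list; a negative fitted
slope predicts an antagonist, a positive slope an agonist.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .match import DoseResponseCurve

__all__ = [
    "LogisticFit",
    "HitRecord",
    "minmax_scale",
    "logistic",
    "dose_to_log10",
    "fit_logistic",
    "fit_curve",
    "rank_and_select_hits",
    "benchmark_from_positive_control",
]


def logistic(x, x0, k):
    return 1.0 / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0)))


@dataclasses.dataclass
class LogisticFit:
    x0: float                  # inflection, log10 nM
    k: float                   # steepness per log10 unit
    covariance: np.ndarray     # 2x2 estimated parameter covariance
    quality: float             # trace of covariance; +inf when unconverged
    converged: bool
    scaled_values: np.ndarray

    @property
    def slope_sign(self) -> str:
        return "negative" if self.k < 0 else "positive"


@dataclasses.dataclass
class HitRecord:
    gene: str
    drug: str
    timepoint: float
    quality_rank_percentile: float
    max_abs_similarity: float
    predicted_mode: str        # "agonist" | "antagonist"
    passed_filters: bool
    filter_reasons: list[str]


def minmax_scale(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Scale to [0, 1] by (v - min) / (max - min).

    Returns ``(scaled, degenerate)``; a constant series is degenerate and
    comes back as all 0.5 (the curve is then unfittable).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 points to scale")
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.full_like(v, 0.5), True
    return (v - lo) / (hi - lo), False


def dose_to_log10(doses: Sequence[float]) -> np.ndarray:
    """log10 dose with the uninduced point mapped one decade below the
    smallest positive dose."""
    d = np.asarray(doses, dtype=float)
    positive = d[d > 0]
    if positive.size == 0:
        raise ValueError("need at least one positive dose")
    floor = math.log10(positive.min()) - 1.0
    with np.errstate(divide="ignore"):
        x = np.where(d > 0, np.log10(np.where(d > 0, d, 1.0)), floor)
    return x


_UNCONVERGED_COV = np.full((2, 2), np.inf)


def fit_logistic(doses: Sequence[float], scaled: Sequence[float]) -> LogisticFit:
    """Least-squares logistic fit of scaled similarities against log10 dose."""
    y = np.asarray(scaled, dtype=float)
    x = dose_to_log10(doses)
    ok = np.isfinite(y)
    if ok.sum() < 4 or len(np.unique(x[ok])) < 4:
        return LogisticFit(np.nan, np.nan, _UNCONVERGED_COV, float("inf"), False, y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                logistic, x[ok], y[ok], p0=(2.0, 0.0), maxfev=10000
            )
    except (RuntimeError, ValueError):
        return LogisticFit(np.nan, np.nan, _UNCONVERGED_COV, float("inf"), False, y)
    if not np.all(np.isfinite(pcov)):
        return LogisticFit(float(popt[0]), float(popt[1]), _UNCONVERGED_COV,
                           float("inf"), False, y)
    quality = float(np.trace(pcov))
    return LogisticFit(float(popt[0]), float(popt[1]), pcov, quality, True, y)


def fit_curve(curve: DoseResponseCurve) -> LogisticFit:
    """Min-max scale a dose-response curve and fit the logistic."""
    if curve.unfittable:
        y = np.asarray(curve.similarities, dtype=float)
        return LogisticFit(np.nan, np.nan, _UNCONVERGED_COV, float("inf"), False, y)
    scaled, degenerate = minmax_scale(curve.similarities)
    if degenerate:
        return LogisticFit(np.nan, np.nan, _UNCONVERGED_COV, float("inf"), False,
                           scaled)
    return fit_logistic(curve.doses, scaled)


def benchmark_from_positive_control(
    curves: Sequence[DoseResponseCurve], control_pair: tuple[str, str]
) -> float:
    """Maximum absolute similarity of the positive-control (gene, drug) pair
    over all doses and timepoints; used as the hit benchmark."""
    gene, drug = control_pair
    maxima = [
        c.max_abs_similarity for c in curves if c.gene == gene and c.drug == drug
    ]
    if not maxima:
        raise ValueError(f"control pair ({gene}, {drug}) not found in curves")
    return float(max(maxima))


def rank_and_select_hits(
    fits: Sequence[tuple[DoseResponseCurve, LogisticFit]],
    benchmark_max_abs: float,
    percentile: float = 0.10,
    exclusion_list: Iterable[str] = (),
) -> list[HitRecord]:
    """Rank fit qualities per gene and apply the hit filters.

    Quality percentiles are computed over each gene's converged fits only
    (lowest quality = best); non-converged fits are never hits.
    """
    if not (0 <= benchmark_max_abs <= 1):
        raise ValueError("benchmark_max_abs must be in [0, 1]")
    excluded = set(exclusion_list)
    records: list[HitRecord] = []
    by_gene: dict[str, list[tuple[DoseResponseCurve, LogisticFit]]] = {}
    for curve, fit in fits:
        by_gene.setdefault(curve.gene, []).append((curve, fit))
    for gene, items in by_gene.items():
        converged = [(c, f) for c, f in items if f.converged]
        if not converged:
            warnings.warn(f"gene {gene}: no converged fits")
            continue
        qualities = np.array([f.quality for _, f in converged])
        ranks = qualities.argsort(kind="stable").argsort(kind="stable") + 1
        n = len(converged)
        lo = math.log10(min(d for d in converged[0][0].doses if d > 0)) - 1.0
        hi = math.log10(max(converged[0][0].doses))
        for (curve, fit), rank in zip(converged, ranks):
            reasons = []
            pct = rank / n
            if pct > percentile:
                reasons.append("quality_below_percentile")
            max_abs = curve.max_abs_similarity
            if max_abs < benchmark_max_abs:
                reasons.append("below_benchmark")
            if curve.drug in excluded:
                reasons.append("excluded_drug")
            if not (lo <= fit.x0 <= hi):
                reasons.append("inflection_out_of_bounds")
            records.append(
                HitRecord(
                    gene=gene,
                    drug=curve.drug,
                    timepoint=curve.timepoint,
                    quality_rank_percentile=pct,
                    max_abs_similarity=max_abs,
                    predicted_mode="antagonist" if fit.slope_sign == "negative"
                    else "agonist",
                    passed_filters=not reasons,
                    filter_reasons=reasons,
                )
            )
    return records
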
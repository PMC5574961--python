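"""Population statistics over per-cell fit results.

Summaries use medians (robust against the heavy-tailed, roughly lognormal
cell-to-cell spread of rate constants) with 5-95 percentile whiskers; fold
comparisons between conditions are ratios of medians; the concentration
dependence of k_f is tested by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import ArgumentError, DegenerateDataError
from .fitting import FitResult

__all__ = ["ConditionSummary", "RegressionResult", "summarize_condition",
           "fold_ratio", "concentration_regression"]


@dataclass(frozen=True)
class ConditionSummary:
    """Population statistics of fitted rate constants for one condition."""

    condition: str
    n_cells: int
    median_kf: float
    mean_kf: float
    sd_kf: float
    p5: float
    p95: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of rate constant versus dye concentration."""

    slope: float        # per s per µM
    intercept: float    # per s
    slope_se: float     # per s per µM
    n_points: int

    def to_dict(self) -> dict:
        return asdict(self)


def _rates(fits: Sequence[FitResult], which: str) -> np.ndarray:
    values = [getattr(f, which) for f in fits if f.converged]
    if any(v is None for v in values):
        raise ArgumentError(f"fit results lack {which}")
    return np.asarray(values, dtype=float)


def summarize_condition(fits: Sequence[FitResult], condition: str,
                        which: str = "k_f") -> ConditionSummary:
    """Summary over converged fits only; percentiles by linear interpolation."""
    rates = _rates(fits, which)
    if rates.size == 0:
        raise DegenerateDataError("no converged fits to summarize")
    return ConditionSummary(
        condition=condition,
        n_cells=int(rates.size),
        median_kf=float(np.median(rates)),
        mean_kf=float(np.mean(rates)),
        sd_kf=float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0,
        p5=float(np.percentile(rates, 5)),
        p95=float(np.percentile(rates, 95)),
    )


def fold_ratio(a: ConditionSummary, b: ConditionSummary) -> float:
    """Ratio of median rate constants, condition a over condition b."""
    if b.median_kf <= 0:
        raise ArgumentError("denominator median must be > 0")
    return a.median_kf / b.median_kf


def concentration_regression(points: Sequence[tuple[float, float]],
                             with_intercept: bool = True) -> RegressionResult:
    """OLS of rate constant on concentration.

    ``points`` are (concentration µM, rate per s) pairs; at least three
    distinct concentrations are required. With ``with_intercept=False`` the
    line is forced through the origin and the intercept reported as 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ArgumentError("need >= 3 (concentration, rate) pairs")
    conc, rate = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < (3 if with_intercept else 2):
        raise ArgumentError("need at least 3 distinct concentrations")
    x = sm.add_constant(conc) if with_intercept else conc[:, None]
    fit = sm.OLS(rate, x).fit()
    if with_intercept:
        intercept, slope = fit.params
        slope_se = fit.bse[1]
    else:
        slope = fit.params[0]
        intercept = 0.0
        slope_se = fit.bse[0]
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            slope_se=float(slope_se), n_points=int(pts.shape[0]))
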
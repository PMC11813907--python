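"""Prediction-accuracy metrics and the temperature/thermal-time correlation.

Metrics follow the standard definitions used throughout crop-model
evaluation, with predictions P_i and harvested masses H_i in grams:

    MAPE = 100/n * sum |P_i - H_i| / H_i                    [%]
    R^2  = 1 - sum (P_i - H_i)^2 / sum (H_i - Hbar)^2
    RMSE = sqrt( 1/n * sum (P_i - H_i)^2 )                  [g]

R^2 uses the observed-mass variance in the denominator, so a constant
predictor at the observed mean scores exactly 0 and R^2 may be negative
for a model worse than that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError, SchemaError

__all__ = ["EvalReport", "mape", "r_squared", "rmse", "evaluate", "temp_thermal_correlation"]


def _paired(pred: Sequence[float], obs: Sequence[float], min_n: int = 1):
    p = np.asarray(pred, dtype=float)
    h = np.asarray(obs, dtype=float)
    if p.shape != h.shape or p.ndim != 1:
        raise SchemaError(f"pred and obs must be equal-length 1-D, got {p.shape} vs {h.shape}")
    if p.size < min_n:
        raise SchemaError(f"need at least {min_n} pairs, got {p.size}")
    return p, h


def mape(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Mean absolute percentage error in percent."""
    p, h = _paired(pred, obs)
    if np.any(h == 0):
        raise DomainError("MAPE undefined when an observed mass is zero")
    return float(100.0 * np.mean(np.abs((p - h) / h)))


def r_squared(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Coefficient of determination of predictions against observations."""
    p, h = _paired(pred, obs, min_n=2)
    ss_tot = float(np.sum((h - h.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("observed masses have zero variance")
    return float(1.0 - np.sum((p - h) ** 2) / ss_tot)


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root mean squared error in grams."""
    p, h = _paired(pred, obs)
    return float(np.sqrt(np.mean((p - h) ** 2)))


@dataclass(frozen=True)
class EvalReport:
    """Accuracy of one fitted model on one held-out fruit set."""

    n: int
    mape: float  # percent
    r2: float
    rmse: float  # g

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("report needs at least one fruit")
        if self.mape < 0 or self.rmse < 0 or self.r2 > 1 + 1e-12:
            raise DomainError("metric out of range")


def evaluate(pred: Sequence[float], obs: Sequence[float]) -> EvalReport:
    """Bundle MAPE, R^2 and RMSE for one prediction set."""
    p, h = _paired(pred, obs, min_n=2)
    return EvalReport(n=p.size, mape=mape(p, h), r2=r_squared(p, h), rmse=rmse(p, h))


def temp_thermal_correlation(
    mean_temps: Sequence[float], thermal_times: Sequence[float]
) -> Tuple[float, float]:
    """Pearson correlation of growing-period mean temperature vs thermal time to harvest.

    Warm growing periods shorten the thermal time a fruit needs before
    harvest, so on real cohorts this correlation is negative.  Returns
    ``(r, p)`` with a two-sided t-distribution p-value.
    """
    x = np.asarray(mean_temps, dtype=float)
    y = np.asarray(thermal_times, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SchemaError("inputs must be equal-length 1-D")
    if x.size < 3:
        raise SchemaError("need at least 3 fruits")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in temperature or thermal time")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
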
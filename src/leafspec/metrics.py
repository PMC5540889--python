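"""Chemometric evaluation statistics: RMSE, RPD, MAPE, R2, RPD banding.

Conventions, fixed deliberately because mixing them moves RPD at the
second decimal for n = 60:

* RMSE uses the divisor N (not N-1).
* The SD in RPD = SD/RMSE is the sample standard deviation of the
  measured values with divisor N-1 (chemometrics convention).
* MAPE here is the mean absolute error divided by the mean of the
  measured values of the evaluated set, x100 — a set-mean-normalised
  error, not the classic per-observation percentage error.
* R2 defaults to the squared Pearson correlation between measured and
  predicted values; ``mode="ssr"`` gives 1 - SSres/SStot instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (zero mean / variance)."""


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D arrays of equal length")
    if y.size < 1:
        raise ValueError("need at least one observation")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error, divisor N."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y, yhat) -> float:
    """Ratio of performance to deviation: sample SD of y over RMSE.

    A perfect model (RMSE 0) yields ``inf`` — flagged, not a finite
    number.
    """
    y, yhat = _check_pair(y, yhat)
    if y.size < 2:
        raise ValueError("RPD needs at least two observations")
    err = rmse(y, yhat)
    sd = float(np.std(y, ddof=1))
    if err == 0:
        return math.inf
    return sd / err


def mape(y, yhat) -> float:
    """Mean absolute error over the mean of measured values, in percent."""
    y, yhat = _check_pair(y, yhat)
    ybar = float(np.mean(y))
    if ybar == 0:
        raise UndefinedStatisticError("MAPE undefined: mean of measured values is 0")
    return float(np.mean(np.abs(y - yhat)) / ybar * 100.0)


def r_squared(y, yhat, mode: str = "pearson") -> float:
    """Coefficient of determination between measured and predicted values.

    ``mode="pearson"`` (default): squared Pearson correlation.
    ``mode="ssr"``: 1 - SSres/SStot.
    """
    y, yhat = _check_pair(y, yhat)
    if np.std(y) == 0:
        raise UndefinedStatisticError("R2 undefined: measured values are constant")
    if mode == "pearson":
        if np.std(yhat) == 0:
            raise UndefinedStatisticError(
                "R2 undefined: predicted values are constant"
            )
        r = np.corrcoef(y, yhat)[0, 1]
        return float(r * r)
    if mode == "ssr":
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown R2 mode {mode!r}")


def classify_rpd(value: float) -> str:
    """Map an RPD value to its conventional model-quality band.

    < 1.5 -> "poor"; [1.5, 2.0] -> "fair/screening" (useful for
    qualitative screening); (2.0, 3.0] -> "good"; > 3.0 ->
    "quantitative" analysis. Band boundaries belong to the lower band.
    """
    if not value > 0:
        raise ValueError("RPD must be positive")
    if value < 1.5:
        return "poor"
    if value <= 2.0:
        return "fair/screening"
    if value <= 3.0:
        return "good"
    return "quantitative"


@dataclass
class EvalStats:
    """One evaluated prediction set: a trait in one phase."""

    trait: str
    phase: str  # "cross-validation" | "validation" | "training"
    n: int
    r2: float
    rmse: float
    rpd: float
    mape: float
    model_size: int | None = None

    @property
    def quality(self) -> str:
        return classify_rpd(self.rpd) if np.isfinite(self.rpd) else "perfect"


def evaluate(y, yhat, trait: str = "trait", phase: str = "validation",
             model_size: int | None = None, r2_mode: str = "pearson") -> EvalStats:
    """Compute the full statistic set for one prediction vector."""
    y, yhat = _check_pair(y, yhat)
    return EvalStats(
        trait=trait,
        phase=phase,
        n=y.size,
        r2=r_squared(y, yhat, mode=r2_mode),
        rmse=rmse(y, yhat),
        rpd=rpd(y, yhat),
        mape=mape(y, yhat),
        model_size=model_size,
    )
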
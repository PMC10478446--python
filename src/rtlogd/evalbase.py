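"""Regression metrics and the closed-form CALlogD baseline.

The metrics are the four used throughout logD benchmarking: mean absolute
error, root-mean-squared error, the coefficient of determination R^2
(computed against the mean of the *measured* vector, not squared Pearson),
and Spearman's rank correlation with average ranks for ties.

CALlogD estimates the octanol/buffer distribution coefficient at a given pH
from the neutral-species partition coefficient (logP) and the acid
dissociation constant of the single strongest ionizable site:

    logD(pH) = logP - log10(1 + 10^((pH - pKa) * delta))

with delta = +1 for acids and -1 for bases. The formula assumes only the
neutral species partitions into octanol, so logD <= logP always. An optional
two-term extension covers amphoteric molecules (one acidic and one basic
site); the strict monoprotic form is the default.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class Ionization(enum.Enum):
    """Dominant ionization behaviour of a molecule near the working pH."""

    ACID = "acid"
    BASE = "base"
    NEUTRAL = "neutral"
    AMPHOTERIC = "amphoteric"


@dataclass(frozen=True)
class CalLogDInput:
    logp: float
    ionization: Ionization
    pka: float | None = None
    pka_basic: float | None = None
    ph: float = 7.4

    def __post_init__(self) -> None:
        if not 0.0 < self.ph < 14.0:
            raise ValueError(f"pH must lie in (0, 14), got {self.ph}")


@dataclass(frozen=True)
class Metrics:
    mae: float
    rmse: float
    r2: float
    spearman: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "spearman": self.spearman,
            "n": self.n,
        }


def _as_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-d vectors of equal length")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("metric inputs must be finite")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error (1/n) sum |y_i - yhat_i|."""
    y, yhat = _as_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root-mean-squared error sqrt((1/n) sum (y_i - yhat_i)^2)."""
    y, yhat = _as_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot against mean(y).

    This is *not* squared Pearson: it can be negative for predictors worse
    than the constant-mean baseline.
    """
    y, yhat = _as_pair(y, yhat)
    if y.size < 2:
        raise ValueError("r2 requires at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined: measured vector has zero variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def spearman(y, yhat) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    y, yhat = _as_pair(y, yhat)
    if y.size < 2:
        raise ValueError("spearman requires at least two observations")
    rx = rankdata(y)  # average ranks for ties
    ry = rankdata(yhat)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("spearman undefined: constant vector")
    cov = float(np.mean((rx - rx.mean()) * (ry - ry.mean())))
    return cov / (sx * sy)


def all_metrics(y, yhat) -> Metrics:
    y, yhat = _as_pair(y, yhat)
    return Metrics(
        mae=mae(y, yhat),
        rmse=rmse(y, yhat),
        r2=r2(y, yhat),
        spearman=spearman(y, yhat),
        n=int(y.size),
    )


def cal_logd(inp: CalLogDInput) -> float:
    """Closed-form logD from logP and pKa via the ionized-fraction correction.

    Acids use delta = +1 (ionized above their pKa), bases delta = -1.
    Neutral molecules return logP unchanged. In amphoteric mode both an
    acidic and a basic site contribute:

        logD = logP - log10(1 + 10^(pH - pKa_acid) + 10^(pKa_base - pH))

    The correction term is always >= 0, so the result never exceeds logP.
    """
    logp, ph = float(inp.logp), float(inp.ph)
    if not math.isfinite(logp):
        raise ValueError("logp must be finite")
    if inp.ionization is Ionization.NEUTRAL:
        return logp
    if inp.ionization is Ionization.AMPHOTERIC:
        if inp.pka is None or inp.pka_basic is None:
            raise ValueError("amphoteric molecules need both an acidic and a basic pKa")
        term = 10.0 ** (ph - float(inp.pka)) + 10.0 ** (float(inp.pka_basic) - ph)
        return logp - math.log10(1.0 + term)
    if inp.pka is None:
        raise ValueError(f"{inp.ionization.value} molecule needs a pKa")
    delta = +1.0 if inp.ionization is Ionization.ACID else -1.0
    return logp - math.log10(1.0 + 10.0 ** ((ph - float(inp.pka)) * delta))


def evaluate_predictions(per_task: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict[str, Metrics]:
    """Metrics per task from {task: (measured, predicted)} vectors."""
    out = {}
    for task, (y, yhat) in per_task.items():
        if len(y) == 0:
            raise ValueError(f"no labeled molecules for task {task!r}")
        out[task] = all_metrics(y, yhat)
    return out
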
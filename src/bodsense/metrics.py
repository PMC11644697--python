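"""Prediction-quality metrics: RMSE, MAE, Pearson correlation.

All metrics are computed on original (inverse-scaled) units — g/m³ for
the BOD target. PCC uses population covariance/variance (consistent
numerator and denominator, so the n vs n−1 convention cancels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricReport", "rmse", "mae", "pcc", "evaluate"]


def _pair(y, yhat, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {y.size}")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error √(Σ(ŷ−y)²/N)."""
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute error Σ|ŷ−y|/N."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def pcc(y, yhat) -> float:
    """Pearson correlation Cov(Y,Ŷ)/√(Var(Y)·Var(Ŷ)).

    Undefined (raises) when either series has zero variance.
    """
    y, yhat = _pair(y, yhat, min_n=2)
    vy = np.var(y)
    vyh = np.var(yhat)
    if vy == 0 or vyh == 0:
        raise ValueError("PCC undefined: zero variance in a series")
    cov = np.mean((y - y.mean()) * (yhat - yhat.mean()))
    return float(cov / np.sqrt(vy * vyh))


@dataclass
class MetricReport:
    rmse: float  # g/m³
    mae: float   # g/m³
    pcc: float
    n: int

    def __post_init__(self) -> None:
        assert self.rmse >= 0 and self.mae >= 0
        # power-mean inequality; always true
        assert self.rmse >= self.mae - 1e-12
        assert abs(self.pcc) <= 1 + 1e-12


def evaluate(y, yhat) -> MetricReport:
    """All three metrics in one report."""
    y_, _ = _pair(y, yhat)
    return MetricReport(rmse=rmse(y, yhat), mae=mae(y, yhat),
                        pcc=pcc(y, yhat), n=y_.size)
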
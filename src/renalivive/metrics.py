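"""Prediction-accuracy statistics: fold errors, k-fold success fractions,
RMSE and the geometric mean fold error (GMFE = 10^mean|log10 FE|, >= 1,
symmetric in over- and under-prediction)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AccuracySummary", "fold_errors", "gmfe", "rmse", "within_fold",
           "summarize_accuracy"]


def fold_errors(predicted, observed) -> np.ndarray:
    """Elementwise predicted / observed."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed shapes differ")
    if np.any(observed <= 0):
        raise ValueError("observed values must be positive")
    if np.any(predicted <= 0):
        raise ValueError("predicted values must be positive")
    return predicted / observed


def gmfe(fe) -> float:
    """Geometric mean fold error of a set of fold errors."""
    fe = np.asarray(fe, dtype=float)
    if fe.size == 0:
        raise ValueError("no fold errors supplied")
    if np.any(fe <= 0):
        raise ValueError("fold errors must be positive")
    return float(10.0 ** np.mean(np.abs(np.log10(fe))))


def rmse(predicted, observed, scale: str = "linear") -> float:
    """Root-mean-square deviation on the linear or log10 scale."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size == 0:
        raise ValueError("no data supplied")
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed shapes differ")
    if scale == "linear":
        d = predicted - observed
    elif scale == "log10":
        if np.any(predicted <= 0) or np.any(observed <= 0):
            raise ValueError("log10 scale needs positive values")
        d = np.log10(predicted) - np.log10(observed)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return float(np.sqrt(np.mean(d * d)))


def within_fold(fe, k: float) -> float:
    """Fraction of fold errors inside the closed interval [1/k, k]."""
    fe = np.asarray(fe, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.mean((fe >= 1.0 / k) & (fe <= k)))


@dataclass
class AccuracySummary:
    n: int
    gmfe: float
    rmse: float
    frac_within_2fold: float
    frac_within_3fold: float
    fold_errors: dict = field(default_factory=dict)  # substrate -> FE


def summarize_accuracy(predicted: dict, observed: dict,
                       rmse_scale: str = "linear") -> AccuracySummary:
    """Accuracy summary over substrates present in both mappings."""
    common = sorted(set(predicted) & set(observed))
    if not common:
        raise ValueError("no substrates common to predictions and observations")
    p = np.array([predicted[s] for s in common])
    o = np.array([observed[s] for s in common])
    fe = fold_errors(p, o)
    return AccuracySummary(
        n=len(common),
        gmfe=gmfe(fe),
        rmse=rmse(p, o, scale=rmse_scale),
        frac_within_2fold=within_fold(fe, 2),
        frac_within_3fold=within_fold(fe, 3),
        fold_errors=dict(zip(common, fe.tolist())),
    )
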
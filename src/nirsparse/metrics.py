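"""Evaluation quantities for calibration and variable selection.

- ``mse``: mean squared prediction error.
- ``rpe``: relative prediction error, MSE divided by the noise variance
  sigma^2 (so a perfect recovery of the noiseless signal scores ~0 and a
  fit no better than predicting the signal-free mean scores well above 1).
- ``selection_counts``: C / IC — how many predictors of the true support
  were selected, and how many selected predictors are not in it.  A
  predictor counts as "selected" iff its coefficient is *exactly* nonzero:
  both estimators here produce hard zeros, so no epsilon is involved.
- ``aggregate``: mean and sample SD (n-1 denominator) over replications.
- ``grouping_bound``: the upper bound on the coefficient gap of two
  correlated predictors under the elastic net,
  ``(1 + lambda2) ||y||_2 sqrt(2 (1 - rho)) / lambda2``, valid whenever the
  two (corrected) coefficients share a sign.  As rho -> 1 the bound
  collapses, which is the grouping effect: strongly correlated wavelengths
  get near-identical coefficients and move in and out of the model
  together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import CoefficientVector

__all__ = [
    "SelectionTruth",
    "ReplicationSummary",
    "mse",
    "rpe",
    "selection_counts",
    "aggregate",
    "grouping_bound",
]


@dataclass
class SelectionTruth:
    """The true support of a simulated sparse model (0-based indices)."""

    q: int
    true_support: np.ndarray

    def __post_init__(self) -> None:
        self.true_support = np.asarray(self.true_support, dtype=int).ravel()
        if self.true_support.shape[0] != self.q:
            raise ValueError("true_support size must equal q")


def mse(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error ``(1/n) sum (yhat_i - y_i)^2``."""
    y_true = np.asarray(y_true, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_hat.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y_hat - y_true) ** 2))


def rpe(y_true: np.ndarray, y_hat: np.ndarray, sigma2: float) -> float:
    """Relative prediction error: MSE divided by the noise variance."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return mse(y_true, y_hat) / sigma2


def selection_counts(
    coef: CoefficientVector | np.ndarray, truth: SelectionTruth
) -> tuple[int, int]:
    """(C, IC): correctly and incorrectly selected predictor counts.

    ``coef`` is a coefficient vector (selection = exact nonzero) or an
    index array of the active set.
    """
    if isinstance(coef, CoefficientVector):
        active = coef.active_set
    else:
        arr = np.asarray(coef)
        if arr.ndim == 1 and np.issubdtype(arr.dtype, np.integer):
            active = arr  # already an index set
        else:
            active = np.flatnonzero(arr)
    active_set = set(int(j) for j in active)
    true_set = set(int(j) for j in truth.true_support)
    c = len(active_set & true_set)
    ic = len(active_set - true_set)
    return c, ic


@dataclass
class ReplicationSummary:
    """Per-replication metric records with their mean/SD aggregates."""

    records: pd.DataFrame
    mean: pd.Series = field(init=False)
    sd: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        num = self.records.select_dtypes(include=[np.number])
        self.mean = num.mean()
        self.sd = num.std(ddof=1)

    def table(self) -> pd.DataFrame:
        """Two-row MEAN / SD table, one column per metric."""
        return pd.DataFrame({"MEAN": self.mean, "SD": self.sd}).T

    def __len__(self) -> int:
        return len(self.records)


def aggregate(records: Iterable[Mapping] | pd.DataFrame) -> ReplicationSummary:
    """Aggregate per-replication records into mean and sample SD (ddof=1)."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if len(df) == 0:
        raise ValueError("no records to aggregate")
    return ReplicationSummary(records=df.reset_index(drop=True))


def grouping_bound(y: np.ndarray, lambda2: float, rho: float) -> float:
    """Upper bound on |b_i - b_j| for same-signed corrected coefficients.

    For standardized predictors with sample correlation ``rho`` and ridge
    penalty ``lambda2 > 0``:
    ``(1 + lambda2) * ||y||_2 * sqrt(2 (1 - rho)) / lambda2``.
    """
    if lambda2 <= 0:
        raise ValueError("the bound requires lambda2 > 0")
    y = np.asarray(y, float).ravel()
    return float((1.0 + lambda2) / lambda2 * np.linalg.norm(y) * np.sqrt(2.0 * (1.0 - rho)))
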
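"""Data containers, column standardization, and CSV I/O for spectra regression.

A calibration problem is a pair ``(X, y)``: an ``(n, p)`` matrix of
absorbance (or any numeric) readings whose columns are wavelengths in
strictly increasing order, and a length-``n`` response on its original
scale.  All solvers in this package work internally on the *standardized*
scale: every predictor column is centered and rescaled to unit Euclidean
length (not unit variance), and the response is centered.  The unit-length
convention matters because the elastic net's ``(1 + lambda2)`` correction
factor assumes it.

:class:`StandardizationState` records the centering/scaling applied to a
training set so that new spectra can be pushed through the same transform
and fitted coefficients can be mapped back to the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraDataset",
    "StandardizationState",
    "CoefficientVector",
    "standardize",
    "standardize_arrays",
    "destandardize",
    "load_dataset",
    "save_dataset",
]


@dataclass
class SpectraDataset:
    """An ``(n, p)`` predictor matrix with its response vector.

    Parameters
    ----------
    X : array_like, shape (n, p)
        Rows are samples, columns are predictors (wavelengths).
    y : array_like, shape (n,)
        Response on its original scale.
    wavelengths : array_like, shape (p,), optional
        Wavelength axis in nm; must be strictly increasing.
    names : sequence of str, optional
        Labels for the predictors (defaults to the wavelengths when absent).
    """

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray | None = None
    names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got n={n}")
        if p < 1:
            raise ValueError("need at least 1 predictor")
        if self.y.shape[0] != n:
            raise ValueError(
                f"response length {self.y.shape[0]} does not match n={n}"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite entries")
        if not np.isfinite(self.y).all():
            raise ValueError("y contains non-finite entries")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
            if self.wavelengths.shape[0] != p:
                raise ValueError("wavelengths length does not match p")
            if np.any(np.diff(self.wavelengths) <= 0):
                raise ValueError("wavelengths must be strictly increasing")
        if self.names is not None and len(self.names) != p:
            raise ValueError("names length does not match p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def labels(self) -> list[str]:
        """Predictor labels: explicit names, else wavelengths, else indices."""
        if self.names is not None:
            return list(self.names)
        if self.wavelengths is not None:
            return [format(w, "g") for w in self.wavelengths]
        return [str(j) for j in range(self.p)]

    def subset(self, rows: np.ndarray) -> "SpectraDataset":
        """Row-subset view (copy) keeping the wavelength axis."""
        return SpectraDataset(
            X=self.X[rows],
            y=self.y[rows],
            wavelengths=self.wavelengths,
            names=self.names,
        )


@dataclass
class StandardizationState:
    """Centering and unit-length scaling fitted on a training set."""

    y_mean: float
    x_means: np.ndarray
    x_norms: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.x_means.shape[0]:
            raise ValueError(
                f"X has {X.shape[-1]} columns, state expects "
                f"{self.x_means.shape[0]}"
            )
        return (X - self.x_means) / self.x_norms

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) - self.y_mean


@dataclass
class CoefficientVector:
    """Coefficients on the standardized predictor scale.

    ``intercept`` lives on the original response scale; for purely
    standardized-scale fits it is 0 and the training response mean is added
    back at prediction time.  ``active_set`` is derived from exact nonzeros:
    both estimators in this package produce hard zeros, so no epsilon
    threshold is applied.
    """

    beta: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()

    @property
    def active_set(self) -> np.ndarray:
        return np.flatnonzero(self.beta)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.beta))


def standardize_arrays(
    X: np.ndarray, y: np.ndarray, labels: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, StandardizationState]:
    """Center ``y`` and rescale each column of ``X`` to zero mean, unit L2 norm.

    Raises
    ------
    ValueError
        If any entry is non-finite or any column is constant (a constant
        column has zero length after centering and cannot be scaled; it is
        rejected rather than dropped so wavelength indexing stays intact).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in X or y")
    x_means = X.mean(axis=0)
    Xc = X - x_means
    x_norms = np.linalg.norm(Xc, axis=0)
    scale = np.maximum(np.abs(x_means), 1.0)
    bad = np.flatnonzero(x_norms <= 1e-10 * scale)
    if bad.size:
        j = int(bad[0])
        label = labels[j] if labels is not None else str(j)
        raise ValueError(
            f"predictor column {label!r} (index {j}) is constant and cannot "
            "be standardized to unit length"
        )
    y_mean = float(y.mean())
    state = StandardizationState(y_mean=y_mean, x_means=x_means, x_norms=x_norms)
    return Xc / x_norms, y - y_mean, state


def standardize(
    data: SpectraDataset,
) -> tuple[np.ndarray, np.ndarray, StandardizationState]:
    """Standardize a dataset; see :func:`standardize_arrays`."""
    return standardize_arrays(data.X, data.y, labels=data.labels())


def destandardize(
    coef: CoefficientVector, state: StandardizationState
) -> tuple[np.ndarray, float]:
    """Map standardized-scale coefficients to the original predictor scale.

    Returns ``(beta_orig, intercept)`` such that
    ``X_orig @ beta_orig + intercept`` equals
    ``X_std @ coef.beta + y_mean + coef.intercept`` for any ``X_orig``
    standardized with ``state``.
    """
    if coef.beta.shape[0] != state.x_means.shape[0]:
        raise ValueError(
            f"coefficient length {coef.beta.shape[0]} does not match "
            f"state dimension {state.x_means.shape[0]}"
        )
    beta_orig = coef.beta / state.x_norms
    intercept = state.y_mean + coef.intercept - float(state.x_means @ beta_orig)
    return beta_orig, intercept


# ---------------------------------------------------------------------------
# CSV I/O.  First row: wavelength labels (numeric strings); optional first
# column of sample IDs; remaining cells numeric.  The response comes either
# from a separate single-column CSV or from a named column of the same file.
# ---------------------------------------------------------------------------


def _is_numeric_label(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def load_dataset(
    x_path: str | Path,
    y_path: str | Path | None = None,
    y_column: str | None = None,
) -> SpectraDataset:
    """Read spectra (and response) from CSV.

    Exactly one of ``y_path`` (separate single-column CSV) or ``y_column``
    (name of a column inside the spectra CSV) must be given.
    """
    if (y_path is None) == (y_column is None):
        raise ValueError("give exactly one of y_path or y_column")
    df = pd.read_csv(x_path)
    # A leading non-numeric column holds sample IDs, not data.
    if df.shape[1] and not _is_numeric_label(df.columns[0]):
        first = df.columns[0]
        if y_column is None or first != y_column:
            if not pd.api.types.is_numeric_dtype(df[first]) or first.lower() in (
                "id",
                "sample",
                "sample_id",
            ):
                df = df.set_index(first)
    if y_column is not None:
        if y_column not in df.columns:
            raise ValueError(f"response column {y_column!r} not found")
        y = df[y_column].to_numpy(dtype=float)
        df = df.drop(columns=[y_column])
    else:
        ydf = pd.read_csv(y_path)
        if ydf.shape[1] != 1:
            raise ValueError("response CSV must have exactly one column")
        y = ydf.iloc[:, 0].to_numpy(dtype=float)
    labels = [str(c) for c in df.columns]
    wavelengths = None
    if labels and all(_is_numeric_label(c) for c in labels):
        wl = np.asarray([float(c) for c in labels])
        if np.all(np.diff(wl) > 0):
            wavelengths = wl
    return SpectraDataset(
        X=df.to_numpy(dtype=float), y=y, wavelengths=wavelengths, names=labels
    )


def save_dataset(
    data: SpectraDataset, x_path: str | Path, y_path: str | Path
) -> None:
    """Write spectra and response as two CSV files (wavelengths as header)."""
    pd.DataFrame(data.X, columns=data.labels()).to_csv(x_path, index=False)
    pd.DataFrame({"y": data.y}).to_csv(y_path, index=False)
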
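"""Grid tuning by tenfold cross-validated MSE, plus holdout-set tuning.

The tuning criterion is the tenfold cross-validated mean squared
prediction error

    MSECV = (1/n) sum_v sum_{i in fold v} (y_i - yhat_i^{(-v)})^2,

where each fold's predictions come from a model fit *without* that fold
(standardization included — the centering/scaling is recomputed on every
training split).  One shared fold assignment is used for the entire grid
so the surface is comparable across grid points.

Default grids follow common practice for these estimators: 100 equally
spaced L1-norm fractions ``s`` on [0, 1] crossed with a small ridge
candidate set for the elastic net; 100 equally spaced thresholds ``eta``
on [0, 0.99] crossed with component counts K = 1..15 (1500 points) for
sparse PLS.  Ties on the CV surface are broken toward the sparser model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import enet as _enet
from ._kernels import pls1_beta
from .data import SpectraDataset, standardize_arrays
from .enet import DEFAULT_LAMBDA2_GRID

__all__ = [
    "TuningGrid",
    "CVResult",
    "kfold_split",
    "msecv",
    "tune",
    "holdout_tune",
    "DEFAULT_S_GRID",
    "DEFAULT_ETA_GRID",
    "DEFAULT_K_GRID",
]

#: 100 equally spaced L1-norm fractions on [0, 1].
DEFAULT_S_GRID = tuple(np.linspace(0.0, 1.0, 100))
#: 100 equally spaced thresholds on [0, 0.99] (eta = 1 would zero every
#: direction, so the grid stops just short of it).
DEFAULT_ETA_GRID = tuple(np.linspace(0.0, 0.99, 100))
#: Component counts 1..15.
DEFAULT_K_GRID = tuple(range(1, 16))


@dataclass
class TuningGrid:
    """A tuning grid for one method ("enet" or "spls")."""

    method: str
    s_grid: np.ndarray | None = None
    lambda2_grid: np.ndarray | None = None
    eta_grid: np.ndarray | None = None
    K_grid: np.ndarray | None = None

    @classmethod
    def enet(cls, s_grid=None, lambda2_grid=None) -> "TuningGrid":
        s = np.asarray(DEFAULT_S_GRID if s_grid is None else s_grid, float)
        l2 = np.asarray(
            DEFAULT_LAMBDA2_GRID if lambda2_grid is None else lambda2_grid, float
        )
        if s.size == 0 or l2.size == 0:
            raise ValueError("grids must be non-empty")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("s values must lie in [0, 1]")
        return cls(method="enet", s_grid=np.sort(s), lambda2_grid=l2)

    @classmethod
    def spls(cls, eta_grid=None, K_grid=None) -> "TuningGrid":
        eta = np.asarray(DEFAULT_ETA_GRID if eta_grid is None else eta_grid, float)
        K = np.asarray(DEFAULT_K_GRID if K_grid is None else K_grid, int)
        if eta.size == 0 or K.size == 0:
            raise ValueError("grids must be non-empty")
        if np.any((eta < 0) | (eta >= 1)):
            raise ValueError("eta values must lie in [0, 1)")
        if np.any(K < 1):
            raise ValueError("K values must be >= 1")
        return cls(method="spls", eta_grid=np.sort(eta), K_grid=np.sort(K))

    @property
    def shape(self) -> tuple[int, int]:
        if self.method == "enet":
            return len(self.s_grid), len(self.lambda2_grid)
        return len(self.eta_grid), len(self.K_grid)


@dataclass
class CVResult:
    """A tuned grid: the MSE surface, the chosen point, and the folds used.

    ``msecv_surface`` has one row per sparsity value (s or eta) and one
    column per second parameter (lambda2 or K).  ``best`` maps parameter
    names to the chosen values; ``best_index`` gives its grid coordinates.
    ``folds`` is None for holdout tuning.
    """

    grid: TuningGrid
    msecv_surface: np.ndarray
    best: dict
    best_index: tuple[int, int]
    folds: np.ndarray | None = None
    seed: int | None = None

    @property
    def best_msecv(self) -> float:
        return float(self.msecv_surface[self.best_index])


def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random partition of ``range(n)`` into ``k`` folds of near-equal size.

    Returns an integer label array of length ``n``; deterministic for a
    given seed.  Fold sizes differ by at most one.
    """
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for v, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = v
    return labels


def msecv(
    data: SpectraDataset,
    fit_procedure: Callable[[SpectraDataset], Callable[[np.ndarray], np.ndarray]],
    folds: np.ndarray,
) -> float:
    """Cross-validated mean squared prediction error of a fitting procedure.

    ``fit_procedure(train)`` must return a prediction callable mapping an
    original-scale X matrix to predicted responses.  Each fold's model is
    fit without that fold; the criterion is the grand mean of the held-out
    squared errors.
    """
    folds = np.asarray(folds)
    n = data.n
    if folds.shape[0] != n:
        raise ValueError("fold labels must have length n")
    sse = 0.0
    for v in np.unique(folds):
        hold = folds == v
        if (~hold).sum() < 2:
            raise ValueError("a fold leaves fewer than 2 training samples")
        predictor = fit_procedure(data.subset(~hold))
        yhat = np.asarray(predictor(data.X[hold]), float)
        sse += float(((data.y[hold] - yhat) ** 2).sum())
    return sse / n


# ---------------------------------------------------------------------------
# Fast surface evaluation (shared by CV and holdout tuning)
# ---------------------------------------------------------------------------


def _enet_sse_surface(Xtr, ytr, Xval, yval, s_grid, lambda2_grid):
    """Validation SSE for every (s, lambda2); rows = s, cols = lambda2."""
    Xs, ys, state = standardize_arrays(Xtr, ytr)
    Xval_s = state.transform(Xval)
    sse = np.full((len(s_grid), len(lambda2_grid)), np.inf)
    for j, l2 in enumerate(lambda2_grid):
        B_naive, _ = _enet._path_matrix(Xs, ys, float(l2), np.asarray(s_grid))
        pred = Xval_s @ ((1.0 + l2) * B_naive).T + state.y_mean
        sse[:, j] = ((pred - yval[:, None]) ** 2).sum(axis=0)
    return sse


def _spls_sse_surface(Xtr, ytr, Xval, yval, eta_grid, K_grid):
    """Validation SSE for every (eta, K); rows = eta, cols = K.

    For a fixed eta the SPLS fits are nested in K, so one sweep up to
    max(K) yields the whole column.
    """
    Xs, ys, state = standardize_arrays(Xtr, ytr)
    Xval_s = state.transform(Xval)
    n, p = Xs.shape
    K_grid = np.asarray(K_grid, int)
    K_max = int(K_grid.max())
    sse = np.full((len(eta_grid), K_max), np.inf)
    yscale = max(float(np.linalg.norm(ys)), 1.0)
    for i, eta in enumerate(eta_grid):
        active = np.zeros(p, dtype=bool)
        resid = ys.copy()
        last_sse = np.inf
        for k in range(1, K_max + 1):
            z = Xs.T @ resid
            zmax = float(np.max(np.abs(z)))
            if zmax <= 1e-12 * yscale:
                sse[i, k - 1 :] = last_sse
                break
            active |= np.abs(z) - eta * zmax > 0.0
            idx = np.flatnonzero(active)
            kk = min(k, idx.size, n - 1)
            beta_a, _ = pls1_beta(np.ascontiguousarray(Xs[:, idx]), ys, kk, 1e-12)
            pred = Xval_s[:, idx] @ beta_a + state.y_mean
            last_sse = float(((pred - yval) ** 2).sum())
            sse[i, k - 1] = last_sse
            resid = ys - Xs[:, idx] @ beta_a
    return sse[:, K_grid - 1]


def _select_best(surface: np.ndarray, grid: TuningGrid) -> tuple[int, int]:
    """Arg-min of the surface with ties broken toward the sparser model.

    Elastic net: smaller ``s`` first, then larger ``lambda2``.  SPLS:
    larger ``eta`` first, then smaller ``K``.
    """
    n_r, n_c = surface.shape
    if grid.method == "enet":
        row_order = np.arange(n_r)  # s ascending
        col_order = np.arange(n_c)[::-1]  # lambda2 descending
    else:
        row_order = np.arange(n_r)[::-1]  # eta descending
        col_order = np.arange(n_c)  # K ascending
    reordered = surface[np.ix_(row_order, col_order)]
    flat = int(np.argmin(reordered))  # first occurrence wins
    r, c = divmod(flat, n_c)
    return int(row_order[r]), int(col_order[c])


def _best_dict(grid: TuningGrid, idx: tuple[int, int]) -> dict:
    if grid.method == "enet":
        return {
            "s": float(grid.s_grid[idx[0]]),
            "lambda2": float(grid.lambda2_grid[idx[1]]),
        }
    return {"eta": float(grid.eta_grid[idx[0]]), "K": int(grid.K_grid[idx[1]])}


def tune(
    data: SpectraDataset,
    grid: TuningGrid,
    seed: int = 0,
    n_folds: int = 10,
) -> CVResult:
    """Tenfold-CV tuning over the full grid with one shared fold assignment.

    Returns the MSECV surface and the arg-min grid point; ties are broken
    toward sparser models.  Grid points whose fits fail are recorded as
    +inf; tuning only fails if every point does.
    """
    folds = kfold_split(data.n, n_folds, seed)
    sse_total = np.zeros(grid.shape)
    for v in range(n_folds):
        hold = folds == v
        Xtr, ytr = data.X[~hold], data.y[~hold]
        Xval, yval = data.X[hold], data.y[hold]
        try:
            if grid.method == "enet":
                sse_total += _enet_sse_surface(
                    Xtr, ytr, Xval, yval, grid.s_grid, grid.lambda2_grid
                )
            else:
                sse_total += _spls_sse_surface(
                    Xtr, ytr, Xval, yval, grid.eta_grid, grid.K_grid
                )
        except (np.linalg.LinAlgError, _enet.ConvergenceError):
            sse_total += np.inf
    surface = sse_total / data.n
    if not np.isfinite(surface).any():
        raise RuntimeError("every grid point failed to fit")
    idx = _select_best(surface, grid)
    return CVResult(
        grid=grid,
        msecv_surface=surface,
        best=_best_dict(grid, idx),
        best_index=idx,
        folds=folds,
        seed=seed,
    )


def holdout_tune(
    train: SpectraDataset,
    validation: SpectraDataset,
    grid: TuningGrid,
) -> CVResult:
    """Pick the grid point minimizing MSE on a held-out validation set.

    Models are fit on ``train`` only (standardization included); the
    surface holds validation mean squared errors.
    """
    if validation.p != train.p:
        raise ValueError("train and validation have different predictor counts")
    if grid.method == "enet":
        sse = _enet_sse_surface(
            train.X, train.y, validation.X, validation.y, grid.s_grid, grid.lambda2_grid
        )
    else:
        sse = _spls_sse_surface(
            train.X, train.y, validation.X, validation.y, grid.eta_grid, grid.K_grid
        )
    surface = sse / validation.n
    idx = _select_best(surface, grid)
    return CVResult(
        grid=grid,
        msecv_surface=surface,
        best=_best_dict(grid, idx),
        best_index=idx,
        folds=None,
        seed=None,
    )
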
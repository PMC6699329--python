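"""Replication protocol for real spectra, correlation profiling, and plots.

``replicate_real`` runs the random-split replication protocol used to
benchmark calibration methods on measured NIR data: repeatedly split the
samples into train/test, tune on the training split by tenfold MSECV,
refit, and record train MSE, the CV criterion at the chosen point, test
MSE, and the number of selected wavelengths.  The full matrix of
original-scale coefficient vectors (one column per replication) is also
returned so coefficient *paths* across replications can be plotted — on
NIR spectra these paths are segmentally zero or nonzero, i.e. whole
wavelength intervals enter or leave the model together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SpectraDataset
from .enet import ElasticNet
from .metrics import ReplicationSummary, aggregate, mse
from .model_selection import TuningGrid
from .spls import SPLS

__all__ = [
    "ReplicationProtocol",
    "replicate_real",
    "correlation_profile",
    "active_runs",
    "plot_coefficient_paths",
]


@dataclass
class ReplicationProtocol:
    """Random-split replication settings for one dataset and method."""

    n_train: int
    n_test: int
    method: str = "enet"
    reps: int = 100
    seed: int = 0
    n_folds: int = 10
    grid: TuningGrid | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.method not in ("enet", "spls"):
            raise ValueError("method must be 'enet' or 'spls'")


def replicate_real(
    dataset: SpectraDataset, protocol: ReplicationProtocol, log_path=None
) -> tuple[ReplicationSummary, np.ndarray]:
    """Run the random-split replication protocol on a measured dataset.

    Returns ``(summary, coef_paths)`` where ``coef_paths`` is the
    ``(p, reps)`` matrix of original-scale coefficient vectors.
    ``train_msecv`` is the cross-validation criterion value at the chosen
    grid point; ``train_mse`` is the refit model's error on the training
    split.
    """
    n = dataset.n
    if protocol.n_train + protocol.n_test != n:
        raise ValueError(
            f"split {protocol.n_train}+{protocol.n_test} does not match n={n}"
        )
    grid = protocol.grid
    if grid is None:
        grid = TuningGrid.enet() if protocol.method == "enet" else TuningGrid.spls()
    records = []
    coef_paths = np.zeros((dataset.p, protocol.reps))
    for r in range(protocol.reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(protocol.seed), spawn_key=(r,))
        )
        perm = rng.permutation(n)
        train = dataset.subset(perm[: protocol.n_train])
        test = dataset.subset(perm[protocol.n_train :])
        cv_seed = int(rng.integers(2**31))
        if protocol.method == "enet":
            res = ElasticNet.from_dataset(train).fit_cv(
                s_grid=grid.s_grid,
                lambda2_grid=grid.lambda2_grid,
                n_folds=protocol.n_folds,
                seed=cv_seed,
            )
        else:
            res = SPLS.from_dataset(train).fit_cv(
                eta_grid=grid.eta_grid,
                K_grid=grid.K_grid,
                n_folds=protocol.n_folds,
                seed=cv_seed,
            )
        coef_paths[:, r] = res.params
        rec = {
            "rep": r,
            "train_mse": mse(train.y, res.predict(train.X)),
            "train_msecv": res.cv.best_msecv,
            "test_mse": mse(test.y, res.predict(test.X)),
            "num_selected": res.n_selected,
        }
        records.append(rec)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps({"best": res.cv.best, "cv_seed": cv_seed, **rec}) + "\n")
    summary = aggregate(pd.DataFrame(records).drop(columns=["rep"]))
    return summary, coef_paths


def correlation_profile(
    X: SpectraDataset | np.ndarray, thresholds: Sequence[float]
) -> dict[float, float]:
    """Fraction of predictor pairs whose |correlation| exceeds each threshold.

    The denominator is the p(p-1)/2 off-diagonal pairs.  On NIR spectra
    most pairs clear even very high thresholds, which is why interval-level
    (grouped) selection is the natural behaviour there.
    """
    if isinstance(X, SpectraDataset):
        X = X.X
    X = np.asarray(X, float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 predictors")
    corr = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(p, k=1)
    absr = np.abs(corr[iu])
    return {float(t): float(np.mean(absr > t)) for t in thresholds}


def active_runs(beta: np.ndarray) -> int:
    """Number of contiguous runs of nonzero coefficients along the axis.

    A small run count on ordered wavelengths means whole intervals were
    selected rather than scattered single wavelengths.
    """
    nz = (np.asarray(beta).ravel() != 0).astype(int)
    rises = np.diff(np.concatenate(([0], nz))) == 1
    return int(rises.sum())


def plot_coefficient_paths(
    coef_paths: np.ndarray,
    wavelengths: np.ndarray | None = None,
    ax=None,
    mean_ax=None,
):
    """Plot per-replication coefficient paths and their mean.

    ``coef_paths`` is (p, reps).  Returns the axes used.  Matplotlib is
    imported lazily so headless pipelines never touch it.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    coef_paths = np.asarray(coef_paths, float)
    x = (
        np.asarray(wavelengths, float)
        if wavelengths is not None
        else np.arange(coef_paths.shape[0])
    )
    if ax is None:
        _, (ax, mean_ax) = plt.subplots(1, 2, figsize=(10, 4))
    ax.plot(x, coef_paths, lw=0.4, alpha=0.4, color="steelblue")
    ax.set_xlabel("wavelength" if wavelengths is not None else "predictor index")
    ax.set_ylabel("coefficient")
    ax.set_title("coefficient paths across replications")
    if mean_ax is not None:
        mean_ax.plot(x, coef_paths.mean(axis=1), color="firebrick")
        mean_ax.set_xlabel(ax.get_xlabel())
        mean_ax.set_title("mean coefficients")
    return ax, mean_ax
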
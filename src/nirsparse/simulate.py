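"""Synthetic benchmark designs and the replication drivers.

Two designs, chosen to stress the two things a wavelength selector must
handle:

* **AR(1) design** ("example 1"): n i.i.d. Gaussian rows with covariance
  Sigma_ij = rho^|i-j| — adjacent predictors are more correlated than
  distant ones, mimicking the smooth correlation decay along an NIR
  wavelength axis.  The response is ``y = X beta + eps`` with
  ``beta = (3, ..., 3, 0, ..., 0)`` (q threes) and ``eps ~ N(0, sigma^2 I)``,
  ``sigma = 8``.  Performance is scored by RPE and the C / IC selection
  counts against the first q indices.

* **Latent-group design** ("example 2"): three independent latent factors
  ``v_i ~ N(0, 5^2)`` (vectors of length n = 240) drive three predictor
  groups — columns 1-6 copy v1, 7-13 copy v2, 14-30 copy v3, each plus
  unit Gaussian noise — while the response is ``y = v1 + v2 + eps``.
  Groups one and two are informative, group three is a decoy; within-group
  population correlation is 25/26 and Var(y) = 51.  Each replication is
  split 120/60/60 into train / validation / test; parameters are tuned on
  the validation split and scored by test-set MSE plus C / IC against
  support {1..13}.

``run_table1`` / ``run_table2`` replicate the full generate-tune-fit-score
pipeline and aggregate the per-replication metrics.  Per-replication seeds
are spawned from the master seed by a fixed counter scheme, so any single
replication can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SpectraDataset
from .enet import ElasticNet
from .metrics import ReplicationSummary, SelectionTruth, aggregate, mse, rpe, selection_counts
from .model_selection import TuningGrid
from .spls import SPLS

__all__ = [
    "Example1Config",
    "Example2Config",
    "EX2_GROUPS",
    "gen_ar1_design",
    "gen_example1",
    "gen_example2",
    "run_table1",
    "run_table2",
    "summary_frame",
]

#: Column slices of the three predictor groups in the latent-group design.
EX2_GROUPS = (slice(0, 6), slice(6, 13), slice(13, 30))


@dataclass(frozen=True)
class Example1Config:
    """AR(1) sparse-regression design: n samples, p predictors, q signals."""

    n: int
    p: int
    q: int
    rho: float
    sigma: float = 8.0
    beta_value: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.q <= self.p:
            raise ValueError("q must lie in [0, p]")

    @property
    def label(self) -> str:
        return f"{self.n}/{self.p}/{self.q}, rho={self.rho:g}"


@dataclass(frozen=True)
class Example2Config:
    """Latent-group design; the structure is fixed, only the seed varies."""

    seed: int = 0
    n: int = 240
    p: int = 30
    latent_sd: float = 5.0
    n_train: int = 120
    n_val: int = 60
    n_test: int = 60

    def __post_init__(self) -> None:
        if self.n_train + self.n_val + self.n_test != self.n:
            raise ValueError("split sizes must partition the n samples")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _child_seed(master: int, *key: int) -> int:
    """Deterministic per-replication seed from a master seed and counters."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0])


def gen_ar1_design(n: int, p: int, rho: float, seed=0) -> np.ndarray:
    """n i.i.d. rows from N(0, Sigma), Sigma_ij = rho^|i-j| (via Cholesky)."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = _as_rng(seed)
    idx = np.arange(p)
    sigma = rho ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(sigma)
    return rng.standard_normal((n, p)) @ L.T


def gen_example1(cfg: Example1Config) -> tuple[SpectraDataset, SelectionTruth]:
    """Draw one AR(1) dataset: y = X beta + sigma * eps, beta = q threes."""
    rng = np.random.default_rng(cfg.seed)
    X = gen_ar1_design(cfg.n, cfg.p, cfg.rho, rng)
    beta = np.zeros(cfg.p)
    beta[: cfg.q] = cfg.beta_value
    y = X @ beta + cfg.sigma * rng.standard_normal(cfg.n)
    truth = SelectionTruth(q=cfg.q, true_support=np.arange(cfg.q))
    return SpectraDataset(X=X, y=y), truth


def gen_example2(
    cfg: Example2Config,
) -> tuple[SpectraDataset, SelectionTruth, np.ndarray]:
    """Draw one latent-group dataset plus train/validation/test labels.

    Rows are i.i.d., so the split is assigned by position: the first 120
    samples train, the next 60 validate, the last 60 test.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n, cfg.p
    v = cfg.latent_sd * rng.standard_normal((3, n))
    y = v[0] + v[1] + rng.standard_normal(n)
    X = np.empty((n, p))
    for g, sl in enumerate(EX2_GROUPS):
        width = sl.stop - sl.start
        X[:, sl] = v[g][:, None] + rng.standard_normal((n, width))
    truth = SelectionTruth(q=13, true_support=np.arange(13))
    labels = np.array(
        ["train"] * cfg.n_train + ["val"] * cfg.n_val + ["test"] * cfg.n_test
    )
    return SpectraDataset(X=X, y=y), truth, labels


# ---------------------------------------------------------------------------
# Replication drivers
# ---------------------------------------------------------------------------

#: The six (n, p, q) combinations of the AR(1) study; crossed with
#: rho in {0.5, 0.7, 0.9} they give the 18 benchmark configurations.
TABLE1_NPQ = ((100, 25, 6), (200, 37, 12), (400, 55, 18),
              (100, 120, 6), (100, 300, 15), (100, 800, 35))

#: Ridge candidates used by the benchmark protocol.  The comparison runs
#: the elastic net with a large ridge penalty — the regime that activates
#: the grouping effect and approaches the UST closed form — so only the
#: magnitude of "large" is searched, not the LASSO end.
BENCH_LAMBDA2_GRID: tuple[float, ...] = (10.0, 100.0, 1000.0)


def _method_grid(method: str, grid: TuningGrid | None) -> TuningGrid:
    if grid is not None:
        if grid.method != method:
            raise ValueError(f"grid is for {grid.method!r}, expected {method!r}")
        return grid
    if method == "enet":
        return TuningGrid.enet(lambda2_grid=BENCH_LAMBDA2_GRID)
    return TuningGrid.spls()


def _log_record(log_path, record: dict) -> None:
    if log_path is None:
        return
    with open(log_path, "a") as fh:
        fh.write(json.dumps(record) + "\n")


def run_table1(
    configs: Sequence[Example1Config] | None = None,
    reps: int = 100,
    seed: int = 0,
    methods: Sequence[str] = ("enet", "spls"),
    enet_grid: TuningGrid | None = None,
    spls_grid: TuningGrid | None = None,
    n_folds: int = 10,
    rpe_on: str = "signal",
    log_path=None,
) -> dict[tuple[str, str], ReplicationSummary]:
    """AR(1) benchmark: generate, tune by tenfold MSECV, fit, score.

    For each configuration and replication, both estimators are tuned on
    the simulated dataset by tenfold cross-validation, refit at the chosen
    grid point, and scored by RPE plus the C / IC selection counts.

    ``rpe_on`` chooses what the predictions are compared against:
    ``"signal"`` (default) scores the estimation error against the
    noiseless mean ``X beta`` on the modeled design — the calibration
    accuracy of the fitted function itself, which can approach 0 for a
    good estimator; ``"fit"`` scores against the observed noisy responses;
    ``"fresh"`` scores against an independent draw of the same
    configuration.  Returns ``{(config_label, method): ReplicationSummary}``.
    """
    if reps < 2:
        raise ValueError("need at least 2 replications")
    if rpe_on not in ("signal", "fit", "fresh"):
        raise ValueError("rpe_on must be 'signal', 'fit' or 'fresh'")
    if configs is None:
        configs = [Example1Config(100, 25, 6, rho=0.5)]
    grids = {"enet": _method_grid("enet", enet_grid),
             "spls": _method_grid("spls", spls_grid)}
    records: dict[tuple[str, str], list[dict]] = {
        (cfg.label, m): [] for cfg in configs for m in methods
    }
    for ci, cfg in enumerate(configs):
        for r in range(reps):
            data_seed = _child_seed(seed, ci, r, 0)
            cv_seed = _child_seed(seed, ci, r, 1)
            data, truth = gen_example1(replace(cfg, seed=data_seed))
            if rpe_on == "fresh":
                test_data, _ = gen_example1(
                    replace(cfg, seed=_child_seed(seed, ci, r, 2))
                )
            for method in methods:
                grid = grids[method]
                if method == "enet":
                    model = ElasticNet.from_dataset(data)
                    res = model.fit_cv(
                        s_grid=grid.s_grid,
                        lambda2_grid=grid.lambda2_grid,
                        n_folds=n_folds,
                        seed=cv_seed,
                    )
                else:
                    model = SPLS.from_dataset(data)
                    res = model.fit_cv(
                        eta_grid=grid.eta_grid,
                        K_grid=grid.K_grid,
                        n_folds=n_folds,
                        seed=cv_seed,
                    )
                if rpe_on == "fresh":
                    target, Xeval = test_data.y, test_data.X
                elif rpe_on == "signal":
                    target = cfg.beta_value * data.X[:, : cfg.q].sum(axis=1)
                    Xeval = data.X
                else:
                    target, Xeval = data.y, data.X
                value = rpe(target, res.predict(Xeval), cfg.sigma**2)
                c, ic = selection_counts(res.coef, truth)
                rec = {
                    "rep": r,
                    "rpe": value,
                    "C": c,
                    "IC": ic,
                    "num_selected": c + ic,
                }
                records[(cfg.label, method)].append(rec)
                _log_record(
                    log_path,
                    {"config": cfg.label, "method": method,
                     "data_seed": data_seed, "cv_seed": cv_seed,
                     "best": res.cv.best, **rec},
                )
    return {
        key: aggregate(pd.DataFrame(recs).drop(columns=["rep"]))
        for key, recs in records.items()
    }


def run_table2(
    reps: int = 100,
    seed: int = 0,
    methods: Sequence[str] = ("enet", "spls"),
    enet_grid: TuningGrid | None = None,
    spls_grid: TuningGrid | None = None,
    eval_on: str = "test",
    log_path=None,
) -> dict[str, ReplicationSummary]:
    """Latent-group benchmark: holdout-tune, fit on train, score on test.

    Per replication: generate the 240-sample dataset, tune on the 60
    validation samples (models fit on the 120 training samples at every
    grid point), and record MSE on the ``eval_on`` split (default the 60
    test samples) plus C / IC against support {1..13}.
    Returns ``{method: ReplicationSummary}``.
    """
    if reps < 2:
        raise ValueError("need at least 2 replications")
    if eval_on not in ("train", "val", "test"):
        raise ValueError("eval_on must be 'train', 'val' or 'test'")
    grids = {"enet": _method_grid("enet", enet_grid),
             "spls": _method_grid("spls", spls_grid)}
    records: dict[str, list[dict]] = {m: [] for m in methods}
    for r in range(reps):
        data_seed = _child_seed(seed, r)
        data, truth, labels = gen_example2(Example2Config(seed=data_seed))
        train = data.subset(labels == "train")
        val = data.subset(labels == "val")
        evald = data.subset(labels == eval_on)
        for method in methods:
            grid = grids[method]
            if method == "enet":
                res = ElasticNet.from_dataset(train).fit_holdout(
                    val, s_grid=grid.s_grid, lambda2_grid=grid.lambda2_grid
                )
            else:
                res = SPLS.from_dataset(train).fit_holdout(
                    val, eta_grid=grid.eta_grid, K_grid=grid.K_grid
                )
            value = mse(evald.y, res.predict(evald.X))
            c, ic = selection_counts(res.coef, truth)
            rec = {"rep": r, "mse": value, "C": c, "IC": ic,
                   "num_selected": c + ic}
            records[method].append(rec)
            _log_record(
                log_path,
                {"method": method, "data_seed": data_seed,
                 "best": res.cv.best, **rec},
            )
    return {
        m: aggregate(pd.DataFrame(recs).drop(columns=["rep"]))
        for m, recs in records.items()
    }


def summary_frame(results: dict) -> pd.DataFrame:
    """Flatten driver output into one tidy mean/SD table (CSV-friendly).

    Rows are (configuration, method) — or just method — and columns hold
    the per-metric MEAN and SD.
    """
    rows = []
    for key, summ in results.items():
        if isinstance(key, tuple):
            head = {"config": key[0], "method": key[1]}
        else:
            head = {"method": key}
        row = dict(head)
        for metric in summ.mean.index:
            row[f"{metric}_mean"] = summ.mean[metric]
            row[f"{metric}_sd"] = summ.sd[metric]
        rows.append(row)
    return pd.DataFrame(rows)
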
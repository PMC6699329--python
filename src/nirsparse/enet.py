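"""Elastic net for spectra calibration.

The estimator solves the doubly penalized least squares problem on
standardized predictors (zero mean, unit L2 length),

    b_naive = argmin_b ||y - X b||^2 + lambda2 ||b||^2 + lambda1 ||b||_1,

and reports the *corrected* estimate ``(1 + lambda2) * b_naive``, which
undoes the extra shrinkage introduced by the ridge term.  Setting
``lambda2 = 0`` recovers the LASSO exactly; letting ``lambda2 -> inf``
collapses the estimator onto univariate soft thresholding (UST), the
closed form ``b_j = soft(x_j' y, lambda1 / 2)``.

The L1 penalty can be parameterized either by ``lambda1`` directly or by
the fraction ``s`` in [0, 1] of the L1 norm attained at the least-penalized
end of the path at the same ``lambda2`` — the usual tuning scale, since it
is bounded regardless of the data.

The solver is cyclic coordinate descent with soft-threshold updates, which
is exact for this separable penalty; convergence is declared when the
largest coefficient change in a sweep drops below ``1e-8``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import enet_cd
from .data import CoefficientVector, SpectraDataset, destandardize, standardize

__all__ = [
    "EnetSpec",
    "EnetFit",
    "ConvergenceError",
    "soft_threshold",
    "enet_objective",
    "enet_naive_solve",
    "enet_solve",
    "ust_solution",
    "lambda1_max",
    "enet_path",
    "ElasticNet",
    "ElasticNetResults",
    "DEFAULT_LAMBDA2_GRID",
]

#: Ridge candidates spanning the LASSO regime through the near-UST regime.
DEFAULT_LAMBDA2_GRID: tuple[float, ...] = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)

_MAX_SWEEPS = 100_000
_CD_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Coordinate descent did not converge; carries the last objective."""

    def __init__(self, message: str, objective: float):
        super().__init__(f"{message} (last objective {objective:.6g})")
        self.objective = objective


@dataclass
class EnetSpec:
    """Elastic net penalty specification.

    Exactly one of ``s`` (L1-norm fraction in [0, 1]) or ``lambda1``
    (absolute L1 penalty) drives sparsity; ``lambda2 >= 0`` is the ridge
    penalty.
    """

    lambda2: float = 0.0
    s: float | None = None
    lambda1: float | None = None

    def __post_init__(self) -> None:
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be >= 0")
        if (self.s is None) == (self.lambda1 is None):
            raise ValueError("give exactly one of s or lambda1")
        if self.s is not None and not 0.0 <= self.s <= 1.0:
            raise ValueError("s must lie in [0, 1]")
        if self.lambda1 is not None and self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")


@dataclass
class EnetFit:
    """A fitted elastic net on the standardized scale.

    ``coef`` holds the corrected coefficients ``(1 + lambda2) * beta_naive``;
    ``objective`` is the penalized loss evaluated at the naive solution.
    ``lambda1`` is the resolved L1 penalty (computed from ``s`` when the fit
    was requested by fraction), and ``s_attained`` the L1-norm fraction the
    naive solution actually reached.
    """

    spec: EnetSpec
    coef: CoefficientVector
    beta_naive: np.ndarray
    objective: float
    lambda1: float
    s_attained: float | None = None


def soft_threshold(z: float | np.ndarray, t: float) -> float | np.ndarray:
    """``sign(z) * max(|z| - t, 0)`` for scalar or array ``z``; ``t >= 0``."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def enet_objective(
    Xs: np.ndarray, ys: np.ndarray, beta: np.ndarray, lambda1: float, lambda2: float
) -> float:
    """Naive elastic net loss ``||y - Xb||^2 + l2 ||b||^2 + l1 ||b||_1``."""
    r = ys - Xs @ beta
    return float(
        r @ r + lambda2 * (beta @ beta) + lambda1 * np.abs(beta).sum()
    )


def _validate_penalties(Xs: np.ndarray, lambda1: float, lambda2: float) -> None:
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be >= 0")
    n, p = Xs.shape
    if p >= n and lambda1 == 0.0 and lambda2 == 0.0:
        raise ValueError(
            "lambda1 and lambda2 cannot both be 0 when p >= n (the "
            "unpenalized problem is ill-posed)"
        )


def _cd_solve(
    G: np.ndarray,
    Xty: np.ndarray,
    lambda1: float,
    lambda2: float,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    beta = np.zeros(Xty.shape[0]) if beta0 is None else beta0.astype(float).copy()
    _, converged = enet_cd(G, Xty, lambda1, lambda2, beta, _MAX_SWEEPS, _CD_TOL)
    if not converged:
        raise ConvergenceError(
            f"coordinate descent did not converge within {_MAX_SWEEPS} sweeps",
            objective=float("nan"),
        )
    return beta


def enet_naive_solve(
    Xs: np.ndarray,
    ys: np.ndarray,
    lambda1: float,
    lambda2: float,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize the naive objective by cyclic coordinate descent.

    ``Xs`` must be standardized (zero-mean, unit-length columns) and ``ys``
    centered.  ``beta0`` provides an optional warm start.
    """
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float).ravel()
    _validate_penalties(Xs, lambda1, lambda2)
    G = Xs.T @ Xs
    Xty = Xs.T @ ys
    try:
        return _cd_solve(G, Xty, lambda1, lambda2, beta0)
    except ConvergenceError:
        beta = np.zeros(Xs.shape[1]) if beta0 is None else beta0.copy()
        enet_cd(G, Xty, lambda1, lambda2, beta, _MAX_SWEEPS, _CD_TOL)
        raise ConvergenceError(
            "coordinate descent did not converge",
            objective=enet_objective(Xs, ys, beta, lambda1, lambda2),
        ) from None


def ust_solution(Xs: np.ndarray, ys: np.ndarray, lambda1: float) -> np.ndarray:
    """Univariate soft thresholding: ``b_j = soft(x_j' y, lambda1 / 2)``.

    This is the closed-form limit of the corrected elastic net as
    ``lambda2 -> inf``; no iteration is involved.
    """
    Xty = np.asarray(Xs, float).T @ np.asarray(ys, float).ravel()
    return soft_threshold(Xty, lambda1 / 2.0)


def lambda1_max(Xs: np.ndarray, ys: np.ndarray) -> float:
    """Smallest L1 penalty at which the naive solution is identically zero."""
    return 2.0 * float(np.max(np.abs(Xs.T @ ys), initial=0.0))


def _lambda1_grid(
    l1max: float, lambda2: float, n: int, p: int, n_lambda1: int
) -> np.ndarray:
    """Descending L1 grid from the all-zero threshold to the path's end.

    The terminal point is lambda1 = 0 when that problem is well posed
    (ridge penalty active, or full column rank); otherwise the
    least-penalized end is taken at ``l1max * 1e-3``.
    """
    if l1max == 0.0:
        return np.array([0.0])
    grid = np.geomspace(l1max, l1max * 1e-3, n_lambda1)
    terminal = 0.0 if (lambda2 > 0.0 or p <= n) else l1max * 1e-3
    if terminal < grid[-1]:
        grid = np.append(grid, terminal)
    return grid


def _naive_path(
    Xs: np.ndarray, ys: np.ndarray, lambda2: float, n_lambda1: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started naive solutions along a descending lambda1 grid.

    Returns ``(lambda1s, betas)`` with ``betas[i]`` the naive solution at
    ``lambda1s[i]``.
    """
    n, p = Xs.shape
    G = Xs.T @ Xs
    Xty = Xs.T @ ys
    l1max = 2.0 * float(np.max(np.abs(Xty), initial=0.0))
    lambda1s = _lambda1_grid(l1max, lambda2, n, p, n_lambda1)
    betas = np.zeros((lambda1s.shape[0], p))
    beta = np.zeros(p)
    for i, l1 in enumerate(lambda1s):
        enet_cd(G, Xty, l1, lambda2, beta, _MAX_SWEEPS, _CD_TOL)
        betas[i] = beta
    return lambda1s, betas


def _interp_at_fraction(
    lambda1s: np.ndarray, betas: np.ndarray, norms_mono: np.ndarray, s: float
) -> tuple[np.ndarray, float]:
    """Linear interpolation of the path to the target L1-norm fraction.

    The naive path is piecewise linear in ``lambda1`` between support
    changes, so interpolating between adjacent grid solutions — with the
    interpolation weight chosen on the L1 norm itself — lands on (very
    nearly) the exact solution whose norm is ``s`` times the terminal norm.
    Returns ``(beta, lambda1)``.
    """
    terminal = norms_mono[-1]
    target = s * terminal
    if target <= 0.0 or terminal == 0.0:
        return np.zeros(betas.shape[1]), float(lambda1s[0])
    if s >= 1.0:
        return betas[-1].copy(), float(lambda1s[-1])
    i = int(np.searchsorted(norms_mono, target, side="left"))
    i = min(max(i, 1), len(norms_mono) - 1)
    n_a, n_b = norms_mono[i - 1], norms_mono[i]
    t = 0.0 if n_b == n_a else (target - n_a) / (n_b - n_a)
    beta = betas[i - 1] + t * (betas[i] - betas[i - 1])
    l1 = lambda1s[i - 1] + t * (lambda1s[i] - lambda1s[i - 1])
    return beta, float(l1)


def _path_matrix(
    Xs: np.ndarray,
    ys: np.ndarray,
    lambda2: float,
    s_grid: np.ndarray,
    n_lambda1: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Naive coefficient matrix, one row per ``s``; returns ``(B, lambda1s)``.

    Fast interpolated variant used by the tuning loops; :func:`enet_path`
    wraps the same machinery with optional bisection refinement.
    """
    lambda1s, betas = _naive_path(Xs, ys, lambda2, n_lambda1)
    norms = np.abs(betas).sum(axis=1)
    norms_mono = np.maximum.accumulate(norms)
    B = np.zeros((len(s_grid), Xs.shape[1]))
    l1_out = np.zeros(len(s_grid))
    for i, s in enumerate(s_grid):
        B[i], l1_out[i] = _interp_at_fraction(lambda1s, betas, norms_mono, s)
    return B, l1_out


def _refine_to_fraction(
    Xs: np.ndarray,
    ys: np.ndarray,
    lambda2: float,
    target: float,
    lo: float,
    hi: float,
    beta0: np.ndarray,
    tol: float,
) -> tuple[np.ndarray, float]:
    """Bisection on lambda1 in [lo, hi] so the naive L1 norm hits ``target``."""
    G = Xs.T @ Xs
    Xty = Xs.T @ ys
    beta = beta0.copy()
    l1 = 0.5 * (lo + hi)
    for _ in range(100):
        l1 = 0.5 * (lo + hi)
        enet_cd(G, Xty, l1, lambda2, beta, _MAX_SWEEPS, _CD_TOL)
        norm = float(np.abs(beta).sum())
        if abs(norm - target) <= tol or hi - lo <= 1e-14 * max(hi, 1.0):
            break
        if norm > target:
            lo = l1  # too little penalty -> norm too big -> raise lambda1
        else:
            hi = l1
    return beta, l1


def enet_path(
    Xs: np.ndarray,
    ys: np.ndarray,
    lambda2: float,
    s_grid: Sequence[float],
    n_lambda1: int = 100,
    refine: bool = True,
) -> list[EnetFit]:
    """Elastic net fits along a grid of L1-norm fractions ``s`` in [0, 1].

    ``s = 0`` is the all-zero model; ``s = 1`` is the least-penalized end of
    the path at this ``lambda2``.  With ``refine=True`` each interior ``s``
    is sharpened by bisection on ``lambda1`` until the naive L1 norm matches
    ``s`` times the terminal norm (to ~1e-9 of the terminal norm); with
    ``refine=False`` the piecewise-linear path interpolation is used as is.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any((s_grid < 0) | (s_grid > 1)):
        raise ValueError("s values must lie in [0, 1]")
    if np.any(np.diff(s_grid) < 0):
        raise ValueError("s_grid must be sorted ascending")
    Xs = np.asarray(Xs, float)
    ys = np.asarray(ys, float).ravel()
    lambda1s, betas = _naive_path(Xs, ys, lambda2, n_lambda1)
    norms = np.abs(betas).sum(axis=1)
    norms_mono = np.maximum.accumulate(norms)
    terminal = float(norms_mono[-1])
    fits = []
    for s in s_grid:
        beta, l1 = _interp_at_fraction(lambda1s, betas, norms_mono, float(s))
        if refine and 0.0 < s < 1.0 and terminal > 0.0:
            target = s * terminal
            i = int(np.searchsorted(norms_mono, target, side="left"))
            i = min(max(i, 1), len(norms_mono) - 1)
            beta, l1 = _refine_to_fraction(
                Xs,
                ys,
                lambda2,
                target,
                lo=lambda1s[i],
                hi=lambda1s[i - 1],
                beta0=beta,
                tol=1e-9 * max(terminal, 1.0),
            )
        attained = float(np.abs(beta).sum() / terminal) if terminal > 0 else 0.0
        corrected = (1.0 + lambda2) * beta
        fits.append(
            EnetFit(
                spec=EnetSpec(lambda2=lambda2, s=float(s)),
                coef=CoefficientVector(beta=corrected),
                beta_naive=beta,
                objective=enet_objective(Xs, ys, beta, l1, lambda2),
                lambda1=l1,
                s_attained=attained,
            )
        )
    return fits


def enet_solve(Xs: np.ndarray, ys: np.ndarray, spec: EnetSpec) -> EnetFit:
    """Fit the elastic net at one penalty specification.

    The returned coefficients are the corrected estimate
    ``(1 + lambda2) * beta_naive``; the active set is that of the naive
    solution (the correction is a positive rescaling).
    """
    Xs = np.asarray(Xs, float)
    ys = np.asarray(ys, float).ravel()
    if spec.lambda1 is not None:
        beta = enet_naive_solve(Xs, ys, spec.lambda1, spec.lambda2)
        return EnetFit(
            spec=spec,
            coef=CoefficientVector(beta=(1.0 + spec.lambda2) * beta),
            beta_naive=beta,
            objective=enet_objective(Xs, ys, beta, spec.lambda1, spec.lambda2),
            lambda1=spec.lambda1,
        )
    (fit,) = enet_path(Xs, ys, spec.lambda2, [spec.s], refine=True)
    fit.spec = spec
    return fit


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------


class ElasticNet:
    """Elastic net calibration model for a spectra regression problem.

    Parameters
    ----------
    endog : array_like, shape (n,)
        Response on its original scale.
    exog : array_like, shape (n, p)
        Predictor (spectra) matrix; columns are wavelengths.
    wavelengths, names : optional
        Passed through to :class:`~nirsparse.data.SpectraDataset`.

    Standardization (zero mean, unit column length; centered response) is
    fitted once at construction; all penalized fits run on that scale and
    results are reported back on the original scale.
    """

    def __init__(self, endog, exog, wavelengths=None, names=None):
        self.data = SpectraDataset(
            X=exog, y=endog, wavelengths=wavelengths, names=names
        )
        self.Xs, self.ys, self.state = standardize(self.data)

    @classmethod
    def from_dataset(cls, data: SpectraDataset) -> "ElasticNet":
        return cls(data.y, data.X, wavelengths=data.wavelengths, names=data.names)

    @classmethod
    def from_dataframe(cls, df, response: str) -> "ElasticNet":
        """Build from a DataFrame whose ``response`` column is the target."""
        y = df[response].to_numpy(dtype=float)
        Xdf = df.drop(columns=[response])
        return cls(y, Xdf.to_numpy(dtype=float), names=[str(c) for c in Xdf.columns])

    def fit(
        self,
        lambda2: float = 0.0,
        s: float | None = None,
        lambda1: float | None = None,
    ) -> "ElasticNetResults":
        """Fit at a single penalty point (defaults to unpenalized L1)."""
        if s is None and lambda1 is None:
            lambda1 = 0.0
        spec = EnetSpec(lambda2=lambda2, s=s, lambda1=lambda1)
        fit = enet_solve(self.Xs, self.ys, spec)
        return ElasticNetResults(self, fit)

    def fit_cv(
        self,
        s_grid=None,
        lambda2_grid=None,
        n_folds: int = 10,
        seed: int = 0,
    ) -> "ElasticNetResults":
        """Tune (s, lambda2) by tenfold cross-validated MSE, then refit."""
        from .model_selection import TuningGrid, tune

        grid = TuningGrid.enet(s_grid=s_grid, lambda2_grid=lambda2_grid)
        cv = tune(self.data, grid, seed=seed, n_folds=n_folds)
        res = self.fit(lambda2=cv.best["lambda2"], s=cv.best["s"])
        res.cv = cv
        return res

    def fit_holdout(
        self,
        validation: SpectraDataset,
        s_grid=None,
        lambda2_grid=None,
    ) -> "ElasticNetResults":
        """Tune (s, lambda2) against a held-out validation set, then refit."""
        from .model_selection import TuningGrid, holdout_tune

        grid = TuningGrid.enet(s_grid=s_grid, lambda2_grid=lambda2_grid)
        cv = holdout_tune(self.data, validation, grid)
        res = self.fit(lambda2=cv.best["lambda2"], s=cv.best["s"])
        res.cv = cv
        return res


class ElasticNetResults:
    """Fitted elastic net with original-scale coefficients and diagnostics."""

    def __init__(self, model: ElasticNet, fit: EnetFit):
        self.model = model
        self.fit_ = fit
        self.coef = fit.coef
        self.params, self.intercept = destandardize(fit.coef, model.state)
        self.cv = None

    @property
    def active_set(self) -> np.ndarray:
        return self.coef.active_set

    @property
    def n_selected(self) -> int:
        return self.coef.n_selected

    @property
    def selected_labels(self) -> list[str]:
        labels = self.model.data.labels()
        return [labels[j] for j in self.active_set]

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.data.X if exog is None else np.asarray(exog, float)
        if X.shape[-1] != self.params.shape[0]:
            raise ValueError("exog column count does not match training data")
        return X @ self.params + self.intercept

    def summary(self) -> str:
        f = self.fit_
        spec = f.spec
        lines = [
            "            Elastic Net Calibration Results",
            "=" * 56,
            f"No. samples:        {self.model.data.n:<10d}"
            f"No. predictors:     {self.model.data.p}",
            f"lambda2:            {spec.lambda2:<10g}"
            f"lambda1:            {f.lambda1:.6g}",
        ]
        if spec.s is not None:
            lines.append(
                f"s (L1 fraction):    {spec.s:<10.4g}"
                f"s attained:         {f.s_attained:.4f}"
            )
        lines += [
            f"Selected:           {self.n_selected} of {self.model.data.p} predictors",
            f"Naive objective:    {f.objective:.6g}",
            f"Intercept:          {self.intercept:.6g}",
            "-" * 56,
            f"{'predictor':>12s}  {'coef (original scale)':>22s}",
        ]
        labels = self.model.data.labels()
        active = self.active_set
        shown = active[:20]
        for j in shown:
            lines.append(f"{labels[j]:>12s}  {self.params[j]:>22.6g}")
        if len(active) > len(shown):
            lines.append(f"{'...':>12s}  ({len(active) - len(shown)} more)")
        lines.append("=" * 56)
        return "\n".join(lines)
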
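"""PLS1 (NIPALS) and sparse partial least squares for spectra calibration.

PLS1 builds ``K`` latent components t = Xw by the NIPALS recursion: each
weight vector is the (normalized) covariance between the deflated
predictors and the deflated response, and both X and y are deflated by the
extracted score.  The regression coefficients mapping the original
standardized X to fitted y are ``W (P'W)^{-1} q``.

Sparse PLS replaces the dense weight vector by a soft-thresholded one —
every entry whose magnitude falls below ``eta`` times the largest magnitude
is zeroed — and grows a cumulative active set A across components.  After
each component the model is *refit* by plain PLS1 on the columns in A, and
the response residual from that refit drives the next direction.  Because
the threshold is relative, strongly correlated predictor blocks (whose
covariances with the residual are nearly equal) enter or leave A together,
which is what makes the method select wavelength *intervals* on NIR
spectra.

Only the univariate-response case is implemented, in the large-ridge (UST)
regime of the general sparse-direction objective: with one response the
direction surrogate has the closed soft-threshold form, so the alternating
optimization (and its kappa parameter, carried in the spec but inert)
never runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import pls1_beta
from .data import (
    CoefficientVector,
    SpectraDataset,
    StandardizationState,
    destandardize,
    standardize,
)

__all__ = [
    "PLSModel",
    "SPLSSpec",
    "SPLSFit",
    "pls1_nipals",
    "spls_direction",
    "spls_fit",
    "predict",
    "SPLS",
    "PLS1",
    "SPLSResults",
]

_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS1 model: weights, scores, loadings and coefficients.

    ``K`` is the number of components actually extracted; ``early_stop``
    flags that the requested number could not be reached because the
    residual covariance vanished.
    """

    K: int
    weights: np.ndarray  # (p, K)
    scores: np.ndarray  # (n, K)
    loadings: np.ndarray  # (p, K)
    q: np.ndarray  # (K,)
    coef: CoefficientVector
    early_stop: bool = False

    def fitted(self, Xs: np.ndarray) -> np.ndarray:
        return Xs @ self.coef.beta


@dataclass
class SPLSSpec:
    """SPLS tuning parameters.

    ``eta`` in [0, 1) is the relative soft threshold on direction vectors;
    ``K`` the number of latent components; ``kappa`` is kept for
    compatibility with the general multi-response objective but has no
    effect in the univariate UST regime implemented here.
    """

    eta: float
    K: int
    kappa: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta < 1.0:
            raise ValueError("eta must lie in [0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 < self.kappa <= 0.5:
            raise ValueError("kappa must lie in (0, 0.5]")


@dataclass
class SPLSFit:
    """A fitted SPLS model on the standardized scale."""

    spec: SPLSSpec
    coef: CoefficientVector
    active_set: np.ndarray
    directions: list[np.ndarray] = field(default_factory=list)
    components_used: int = 0
    early_stop: bool = False


def pls1_nipals(Xs: np.ndarray, ys: np.ndarray, K: int) -> PLSModel:
    """PLS1 regression by NIPALS with ``K`` latent components.

    ``Xs`` standardized, ``ys`` centered.  Score vectors are mutually
    orthogonal; if the residual covariance vector vanishes before ``K``
    components are extracted, the achieved components are returned with
    ``early_stop=True``.
    """
    Xs = np.asarray(Xs, float)
    ys = np.asarray(ys, float).ravel()
    n, p = Xs.shape
    if not 1 <= K <= min(n - 1, p):
        raise ValueError(f"K must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    Xd = Xs.copy()
    yd = ys.copy()
    W = np.zeros((p, K))
    T = np.zeros((n, K))
    P = np.zeros((p, K))
    q = np.zeros(K)
    k_used = 0
    for k in range(K):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _TOL:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _TOL**2:
            break
        pk = Xd.T @ t / tt
        qk = float(t @ yd) / tt
        Xd -= np.outer(t, pk)
        yd -= qk * t
        W[:, k], T[:, k], P[:, k], q[k] = w, t, pk, qk
        k_used = k + 1
    if k_used == 0:
        beta = np.zeros(p)
    else:
        A = P[:, :k_used].T @ W[:, :k_used]
        beta = W[:, :k_used] @ np.linalg.solve(A, q[:k_used])
    return PLSModel(
        K=k_used,
        weights=W[:, :k_used],
        scores=T[:, :k_used],
        loadings=P[:, :k_used],
        q=q[:k_used],
        coef=CoefficientVector(beta=beta),
        early_stop=k_used < K,
    )


def spls_direction(z: np.ndarray, eta: float) -> np.ndarray:
    """Soft-threshold a covariance vector at ``eta * max|z_j|``, unit-normalize.

    Every component with ``|z_j| <= eta * max|z|`` is zeroed; the largest
    component always survives for ``eta < 1``.  The sign is fixed so the
    largest-magnitude surviving entry is positive (NIPALS signs are
    otherwise arbitrary).
    """
    if not 0.0 <= eta < 1.0:
        raise ValueError("eta must lie in [0, 1)")
    z = np.asarray(z, float).ravel()
    zmax = float(np.max(np.abs(z), initial=0.0))
    if zmax <= 0.0:
        raise ValueError("direction vector is identically zero")
    w = np.sign(z) * np.maximum(np.abs(z) - eta * zmax, 0.0)
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w = -w
    return w / np.linalg.norm(w)


def spls_fit(Xs: np.ndarray, ys: np.ndarray, spec: SPLSSpec) -> SPLSFit:
    """Fit SPLS with ``spec.K`` components at threshold ``spec.eta``.

    Per component k: (i) covariance z = X'(current residual); (ii) sparse
    direction by relative soft threshold; (iii) cumulate its support into A;
    (iv) refit PLS1 with k components on the columns in A; (v) residual =
    y - fitted.  The final coefficient vector is supported on A.
    """
    Xs = np.asarray(Xs, float)
    ys = np.asarray(ys, float).ravel()
    n, p = Xs.shape
    active = np.zeros(p, dtype=bool)
    beta = np.zeros(p)
    resid = ys.copy()
    directions: list[np.ndarray] = []
    early = False
    k_used = 0
    yscale = max(float(np.linalg.norm(ys)), 1.0)
    for k in range(1, spec.K + 1):
        z = Xs.T @ resid
        if float(np.max(np.abs(z), initial=0.0)) <= 1e-12 * yscale:
            early = True
            break
        w = np.zeros(p)
        direction = spls_direction(z, spec.eta)
        w[:] = direction
        directions.append(direction)
        active |= direction != 0.0
        idx = np.flatnonzero(active)
        kk = min(k, idx.size, n - 1)
        beta_a, used = pls1_beta(np.ascontiguousarray(Xs[:, idx]), ys, kk, _TOL)
        beta = np.zeros(p)
        beta[idx] = beta_a
        resid = ys - Xs[:, idx] @ beta_a
        k_used = k
    return SPLSFit(
        spec=spec,
        coef=CoefficientVector(beta=beta),
        active_set=np.flatnonzero(active),
        directions=directions,
        components_used=k_used,
        early_stop=early,
    )


def predict(fit, Xnew: np.ndarray, state: StandardizationState | None = None) -> np.ndarray:
    """Predict the response for new spectra from any fitted object.

    ``fit`` may be a :class:`PLSModel`, :class:`SPLSFit` or
    :class:`~nirsparse.enet.EnetFit` — anything carrying a ``coef``
    attribute on the standardized scale.  When ``state`` is given, ``Xnew``
    is standardized with the *training* transform and the training response
    mean is added back; when omitted, ``Xnew`` is assumed already
    standardized.
    """
    coef: CoefficientVector = fit.coef
    Xnew = np.asarray(Xnew, float)
    if Xnew.shape[-1] != coef.beta.shape[0]:
        raise ValueError(
            f"Xnew has {Xnew.shape[-1]} columns, fit expects {coef.beta.shape[0]}"
        )
    if state is None:
        return Xnew @ coef.beta + coef.intercept
    beta_orig, intercept = destandardize(coef, state)
    return Xnew @ beta_orig + intercept


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------


class _SparseModelBase:
    def __init__(self, endog, exog, wavelengths=None, names=None):
        self.data = SpectraDataset(
            X=exog, y=endog, wavelengths=wavelengths, names=names
        )
        self.Xs, self.ys, self.state = standardize(self.data)

    @classmethod
    def from_dataset(cls, data: SpectraDataset):
        return cls(data.y, data.X, wavelengths=data.wavelengths, names=data.names)


class PLS1(_SparseModelBase):
    """Dense PLS1 regression model (NIPALS)."""

    def fit(self, K: int) -> "SPLSResults":
        model = pls1_nipals(self.Xs, self.ys, K)
        return SPLSResults(self, model)


class SPLS(_SparseModelBase):
    """Sparse PLS calibration model with threshold ``eta`` and ``K`` components."""

    def fit(self, eta: float, K: int, kappa: float = 0.5) -> "SPLSResults":
        fit = spls_fit(self.Xs, self.ys, SPLSSpec(eta=eta, K=K, kappa=kappa))
        return SPLSResults(self, fit)

    def fit_cv(
        self, eta_grid=None, K_grid=None, n_folds: int = 10, seed: int = 0
    ) -> "SPLSResults":
        """Tune (eta, K) by tenfold cross-validated MSE, then refit."""
        from .model_selection import TuningGrid, tune

        grid = TuningGrid.spls(eta_grid=eta_grid, K_grid=K_grid)
        cv = tune(self.data, grid, seed=seed, n_folds=n_folds)
        res = self.fit(eta=cv.best["eta"], K=cv.best["K"])
        res.cv = cv
        return res

    def fit_holdout(
        self, validation: SpectraDataset, eta_grid=None, K_grid=None
    ) -> "SPLSResults":
        """Tune (eta, K) against a held-out validation set, then refit."""
        from .model_selection import TuningGrid, holdout_tune

        grid = TuningGrid.spls(eta_grid=eta_grid, K_grid=K_grid)
        cv = holdout_tune(self.data, validation, grid)
        res = self.fit(eta=cv.best["eta"], K=cv.best["K"])
        res.cv = cv
        return res


class SPLSResults:
    """Fitted (sparse) PLS with original-scale coefficients."""

    def __init__(self, model: _SparseModelBase, fit):
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
        head = (
            "            Sparse PLS Calibration Results"
            if isinstance(f, SPLSFit)
            else "               PLS1 Regression Results"
        )
        lines = [head, "=" * 56]
        lines.append(
            f"No. samples:        {self.model.data.n:<10d}"
            f"No. predictors:     {self.model.data.p}"
        )
        if isinstance(f, SPLSFit):
            lines.append(
                f"eta:                {f.spec.eta:<10.4g}"
                f"K (components):     {f.spec.K}"
            )
            lines.append(f"Components used:    {f.components_used}")
        else:
            lines.append(f"K (components):     {f.K}")
        lines += [
            f"Selected:           {self.n_selected} of {self.model.data.p} predictors",
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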
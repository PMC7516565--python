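"""L1-penalized empirical-risk minimization and unpenalized refits.

The screening stage solves, on standardized predictors,

    min_b  R_n(b) + lam * ||b~||_1          (intercept b0 unpenalized)

with a single solver for all three losses: FISTA (accelerated proximal
gradient) with backtracking line search and adaptive restart, stopped on the
KKT residual. A whole decreasing lambda grid is fitted with warm starts.
The selection stage refits each candidate support without penalty
(`refit_erm`): exact least squares for the quadratic loss, iteration-capped
L-BFGS with the analytic gradient otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .losses import (
    Dataset,
    LossSpec,
    empirical_risk,
    pointwise_dloss,
    pointwise_loss,
    risk_gradient,
)

__all__ = [
    "LassoFit",
    "LassoPath",
    "CVResult",
    "RefitResult",
    "intercept_only_fit",
    "lambda_grid",
    "fit_lasso",
    "fit_lasso_path",
    "cv_select_lambda",
    "refit_erm",
]


@dataclass
class LassoFit:
    """Solution of one penalized problem (standardized predictor scale)."""

    lam: float
    intercept: float
    coef: np.ndarray
    converged: bool
    n_iter: int
    kkt_residual: float

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(np.flatnonzero(self.coef))


@dataclass
class LassoPath:
    """Per-lambda solutions along a strictly decreasing grid."""

    lambdas: np.ndarray
    intercepts: np.ndarray
    coefficients: np.ndarray  # (m, p), standardized scale
    converged: np.ndarray
    loss: LossSpec

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or np.any(np.diff(lam) >= 0):
            raise ValueError("lambdas must be strictly decreasing")

    def __len__(self) -> int:
        return self.lambdas.shape[0]

    @property
    def supports(self) -> list[tuple[int, ...]]:
        return [tuple(np.flatnonzero(c)) for c in self.coefficients]

    def fit_at(self, i: int) -> LassoFit:
        return LassoFit(
            lam=float(self.lambdas[i]),
            intercept=float(self.intercepts[i]),
            coef=self.coefficients[i].copy(),
            converged=bool(self.converged[i]),
            n_iter=-1,
            kkt_residual=np.nan,
        )


def intercept_only_fit(data: Dataset, loss: LossSpec) -> float:
    """Minimizer of R_n over intercept-only models.

    Closed forms: mean(y) for quadratic, logit(mean(y)) for logistic
    (clipped away from 0/1 for degenerate responses); a 1-D bounded
    minimization for huber (Huber location estimate of y).
    """
    ybar = float(data.y.mean())
    if loss.name == "quadratic":
        return ybar
    if loss.name == "logistic":
        eps = 1.0 / (2.0 * data.n)
        q = min(max(ybar, eps), 1.0 - eps)
        return float(np.log(q / (1.0 - q)))
    res = optimize.minimize_scalar(
        lambda b0: float(pointwise_loss(np.full(data.n, b0), data.y, loss).mean()),
        bounds=(data.y.min() - 1.0, data.y.max() + 1.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def lambda_grid(
    data: Dataset, loss: LossSpec, m: int = 20, ratio: float = 0.01
) -> np.ndarray:
    """Log-equispaced decreasing grid from lambda_max down to ratio*lambda_max.

    lambda_max is the sup-norm of the predictor block of the risk gradient at
    the intercept-only fit — by the KKT conditions the smallest penalty at
    which the all-zero coefficient vector is optimal.
    """
    if m < 2:
        raise ValueError("lambda grid needs m >= 2")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if not data.standardized:
        raise ValueError("lambda_grid expects a standardized dataset")
    b0 = intercept_only_fit(data, loss)
    beta = np.zeros(data.p + 1)
    beta[0] = b0
    lam_max = float(np.max(np.abs(risk_gradient(beta, data, loss)[1:])))
    if lam_max <= 0:
        lam_max = 1e-12
    return np.geomspace(lam_max, ratio * lam_max, m)


def _objective(
    intercept: float, coef: np.ndarray, data: Dataset, loss: LossSpec, lam: float
) -> float:
    s = intercept + data.X @ coef
    return float(pointwise_loss(s, data.y, loss).mean()) + lam * float(
        np.abs(coef).sum()
    )


def _kkt_residual(
    intercept: float, coef: np.ndarray, data: Dataset, loss: LossSpec, lam: float
) -> float:
    beta = np.concatenate(([intercept], coef))
    g = risk_gradient(beta, data, loss)
    r = abs(g[0])
    gc = g[1:]
    nz = coef != 0
    if np.any(nz):
        r = max(r, float(np.max(np.abs(gc[nz] + lam * np.sign(coef[nz])))))
    if np.any(~nz):
        r = max(r, float(np.max(np.maximum(np.abs(gc[~nz]) - lam, 0.0))))
    return r


def fit_lasso(
    data: Dataset,
    loss: LossSpec,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    warm_start: tuple[float, np.ndarray] | None = None,
) -> LassoFit:
    """Solve min R_n(b) + lam*||b~||_1 by FISTA with backtracking.

    The intercept is never thresholded. Convergence is declared when the
    KKT residual drops below ``tol``; running out of iterations sets
    ``converged=False`` on the result (with a warning) rather than raising.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not data.standardized:
        raise ValueError("fit_lasso expects a standardized dataset")
    X, y = data.X, data.y
    n, p = X.shape

    if warm_start is not None:
        b = np.concatenate(([warm_start[0]], np.asarray(warm_start[1], dtype=float)))
    else:
        b = np.zeros(p + 1)
        b[0] = intercept_only_fit(data, loss)

    def smooth(beta: np.ndarray) -> float:
        return float(pointwise_loss(beta[0] + X @ beta[1:], y, loss).mean())

    def smooth_grad(beta: np.ndarray) -> np.ndarray:
        g = pointwise_dloss(beta[0] + X @ beta[1:], y, loss)
        out = np.empty(p + 1)
        out[0] = g.mean()
        out[1:] = X.T @ g / n
        return out

    def prox(beta: np.ndarray, t: float) -> np.ndarray:
        out = beta.copy()
        out[1:] = np.sign(beta[1:]) * np.maximum(np.abs(beta[1:]) - t * lam, 0.0)
        return out

    t = 1.0  # step size, adapted by backtracking
    z = b.copy()
    momentum = 1.0
    kkt = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        fz = smooth(z)
        gz = smooth_grad(z)
        while True:
            b_new = prox(z - t * gz, t)
            diff = b_new - z
            if smooth(b_new) <= fz + gz @ diff + (diff @ diff) / (2.0 * t) + 1e-15:
                break
            t *= 0.5
            if t < 1e-14:
                b_new = z
                break
        mom_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * momentum * momentum))
        # adaptive restart: drop momentum when it points uphill
        if (z - b_new) @ (b_new - b) > 0:
            momentum = mom_new = 1.0
            z = b_new.copy()
        else:
            z = b_new + ((momentum - 1.0) / mom_new) * (b_new - b)
        b = b_new
        momentum = mom_new
        if it % 10 == 0 or it == max_iter:
            kkt = _kkt_residual(b[0], b[1:], data, loss, lam)
            if kkt <= tol:
                break

    converged = kkt <= tol
    if not converged:
        warnings.warn(
            f"fit_lasso did not reach KKT tolerance {tol:g} in {max_iter} "
            f"iterations (residual {kkt:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    coef = b[1:].copy()
    coef[np.abs(coef) < 1e-12] = 0.0
    return LassoFit(
        lam=float(lam),
        intercept=float(b[0]),
        coef=coef,
        converged=converged,
        n_iter=it,
        kkt_residual=float(kkt),
    )


def fit_lasso_path(
    data: Dataset,
    loss: LossSpec,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> LassoPath:
    """Fit `fit_lasso` along a decreasing grid with warm starts."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.ndim != 1 or lambdas.size < 1:
        raise ValueError("lambdas must be a non-empty 1-D array")
    if lambdas.size > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambdas must be strictly decreasing")
    p = data.p
    m = lambdas.size
    intercepts = np.empty(m)
    coefs = np.empty((m, p))
    ok = np.empty(m, dtype=bool)
    warm = None
    for i, lam in enumerate(lambdas):
        fit = fit_lasso(data, loss, lam, tol=tol, max_iter=max_iter, warm_start=warm)
        intercepts[i] = fit.intercept
        coefs[i] = fit.coef
        ok[i] = fit.converged
        warm = (fit.intercept, fit.coef)
    if m == 1:
        return LassoPath(lambdas, intercepts, coefs, ok, loss)
    return LassoPath(lambdas, intercepts, coefs, ok, loss)


@dataclass
class CVResult:
    """K-fold cross-validation curve over a lambda grid."""

    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lam_selected: float
    rule: str
    fold_assignment: np.ndarray
    flags: list[str] = field(default_factory=list)


def _make_folds(y: np.ndarray, K: int, seed: int, stratify: bool) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    assign = np.empty(n, dtype=int)
    if stratify:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            assign[idx] = np.arange(idx.size) % K
    else:
        perm = rng.permutation(n)
        # contiguous blocks of the permutation
        bounds = np.linspace(0, n, K + 1).astype(int)
        for k in range(K):
            assign[perm[bounds[k] : bounds[k + 1]]] = k
    return assign


def cv_select_lambda(
    data: Dataset,
    loss: LossSpec,
    lambdas: np.ndarray,
    K: int = 10,
    rule: str = "1se",
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> CVResult:
    """Choose lambda by K-fold CV of held-out empirical risk.

    ``rule="min"`` takes the risk-minimizing lambda (largest on ties);
    ``rule="1se"`` takes the largest lambda whose CV risk is within one
    standard error of the minimum. Folds are a seeded partition, stratified
    by the response under logistic loss.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    if K < 2:
        raise ValueError("need K >= 2 folds")
    if K > data.n:
        raise ValueError("cannot have more folds than observations")
    lambdas = np.asarray(lambdas, dtype=float)
    assign = _make_folds(data.y, K, seed, stratify=(loss.name == "logistic"))
    m = lambdas.size
    fold_risk = np.empty((K, m))
    flags: list[str] = []
    for k in range(K):
        train = assign != k
        test = ~train
        dtr = Dataset(data.X[train], data.y[train], standardized=data.standardized,
                      column_means=data.column_means, column_scales=data.column_scales,
                      feature_names=list(data.feature_names))
        Xte, yte = data.X[test], data.y[test]
        if loss.name == "logistic" and np.unique(dtr.y).size < 2:
            # degenerate training response: intercept-only fallback
            flags.append(f"fold {k}: single-class training response; intercept-only fit")
            b0 = intercept_only_fit(dtr, loss)
            s = np.full(Xte.shape[0], b0)
            fold_risk[k, :] = float(pointwise_loss(s, yte, loss).mean())
            continue
        path = fit_lasso_path(dtr, loss, lambdas, tol=tol, max_iter=max_iter)
        for i in range(m):
            s = path.intercepts[i] + Xte @ path.coefficients[i]
            fold_risk[k, i] = float(pointwise_loss(s, yte, loss).mean())
    cv_mean = fold_risk.mean(axis=0)
    cv_se = fold_risk.std(axis=0, ddof=1) / np.sqrt(K)
    i_min = int(np.argmin(cv_mean))
    if rule == "min":
        i_sel = i_min
    else:
        ok = cv_mean <= cv_mean[i_min] + cv_se[i_min]
        i_sel = int(np.flatnonzero(ok)[0])  # lambdas decreasing: first = largest
    return CVResult(
        lambdas=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lam_selected=float(lambdas[i_sel]),
        rule=rule,
        fold_assignment=assign,
        flags=flags,
    )


@dataclass
class RefitResult:
    """Unpenalized ERM restricted to a support (plus intercept)."""

    support: tuple[int, ...]
    intercept: float
    coef: np.ndarray  # length p, zeros off support
    risk: float
    converged: bool


def refit_erm(
    data: Dataset,
    support,
    loss: LossSpec,
    max_iter: int = 500,
    grad_tol: float = 1e-6,
) -> RefitResult:
    """Minimize R_n over vectors supported on ``support`` (intercept free).

    Quadratic loss uses the normal equations (exact); logistic and huber use
    L-BFGS-B with the analytic gradient. Under perfect logistic separation
    the likelihood has no finite minimizer: the iteration cap acts as the
    regularizer and the achieved risk is reported with ``converged=False``.
    """
    support = tuple(sorted(int(j) for j in set(support)))
    if any(j < 0 or j >= data.p for j in support):
        raise ValueError("support indices out of range")
    if len(support) >= data.n:
        raise ValueError(
            f"support size {len(support)} >= n = {data.n}: ERM not identified"
        )
    p = data.p
    coef = np.zeros(p)
    idx = np.array(support, dtype=int)

    if loss.name == "quadratic":
        A = np.column_stack([np.ones(data.n), data.X[:, idx]]) if idx.size else np.ones(
            (data.n, 1)
        )
        sol, *_ = np.linalg.lstsq(A, data.y, rcond=None)
        intercept = float(sol[0])
        if idx.size:
            coef[idx] = sol[1:]
        beta = np.concatenate(([intercept], coef))
        return RefitResult(
            support, intercept, coef, empirical_risk(beta, data, loss), True
        )

    Xs = data.X[:, idx]
    y = data.y
    n = data.n

    def fun(b: np.ndarray):
        s = b[0] + (Xs @ b[1:] if idx.size else 0.0)
        val = float(pointwise_loss(s, y, loss).mean())
        g = pointwise_dloss(s, y, loss)
        grad = np.empty(b.size)
        grad[0] = g.mean()
        if idx.size:
            grad[1:] = Xs.T @ g / n
        return val, grad

    x0 = np.zeros(idx.size + 1)
    x0[0] = intercept_only_fit(data, loss)
    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    intercept = float(res.x[0])
    if idx.size:
        coef[idx] = res.x[1:]
    converged = bool(np.max(np.abs(res.jac)) <= grad_tol)
    if loss.name == "logistic" and res.fun < 1e-6:
        # risk ~ 0 is only approached as ||beta|| -> inf: perfect separation,
        # so the iteration cap acted as the regularizer
        converged = False
    return RefitResult(support, intercept, coef, float(res.fun), converged)
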
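"""Pointwise losses, datasets, empirical risk and its gradient.

Binary regression with a general convex loss: an observation ``(x, y)`` with
``y in {0, 1}`` contributes ``rho(b' x, y)`` to the empirical risk

    R_n(b) = (1/n) * sum_i rho(b' X_i, Y_i).

Three losses are supported:

* ``logistic`` — the negative Bernoulli log-likelihood of a logit fit,
  ``rho(s, y) = -y*s + log(1 + exp(s))``; 1-Lipschitz in ``s``.
* ``quadratic`` — ``rho(s, y) = (y - s)^2 / 2``; the response is treated as
  numeric (linear-probability fit); not Lipschitz.
* ``huber`` — the Huber function of the residual ``r = y - s`` with knee
  ``delta`` (default 0.1): ``r^2/2`` for ``|r| <= delta``, else
  ``delta*(|r| - delta/2)``; ``delta``-Lipschitz in ``s``.

The model vector convention everywhere in this package is ``b = (b0, b~)``
with the intercept first and never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossSpec",
    "Dataset",
    "loss_value",
    "empirical_risk",
    "risk_gradient",
    "pointwise_loss",
    "pointwise_dloss",
]

_LOSS_NAMES = ("logistic", "quadratic", "huber")


@dataclass(frozen=True)
class LossSpec:
    """A pointwise loss ``rho(s, y)`` with its Lipschitz metadata.

    Parameters
    ----------
    name : {"logistic", "quadratic", "huber"}
    huber_delta : float
        Knee of the Huber loss; only meaningful for ``name="huber"``.
    """

    name: str
    huber_delta: float = 0.1

    def __post_init__(self) -> None:
        if self.name not in _LOSS_NAMES:
            raise ValueError(f"unknown loss {self.name!r}; expected one of {_LOSS_NAMES}")
        if self.name == "huber" and not self.huber_delta > 0:
            raise ValueError("huber_delta must be positive")

    @property
    def lipschitz_constant(self):
        """Lipschitz constant of ``s -> rho(s, y)``: 1, delta, or "unbounded"."""
        if self.name == "logistic":
            return 1.0
        if self.name == "huber":
            return self.huber_delta
        return "unbounded"


@dataclass
class Dataset:
    """A design matrix and binary response, optionally column-standardized.

    ``X`` has shape (n, p) and carries no intercept column; ``y`` is in
    {0, 1} (interpreted as numeric under quadratic/huber loss).
    ``column_means``/``column_scales`` record the affine map applied when
    ``standardize()`` produced this dataset, so coefficients fitted on the
    standardized scale can be mapped back to the original one.
    """

    X: np.ndarray
    y: np.ndarray
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_scales: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        n, p = self.X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        if self.y.shape[0] != n:
            raise ValueError(f"X has {n} rows but y has {self.y.shape[0]} entries")
        if not self.feature_names:
            self.feature_names = [f"x{j + 1}" for j in range(p)]
        elif len(self.feature_names) != p:
            raise ValueError("feature_names length must equal the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def standardize(self) -> "Dataset":
        """Return a copy whose columns have sample mean 0 and SD 1.

        A constant column cannot be standardized and raises ``ValueError``.
        Already-standardized datasets are returned unchanged.
        """
        if self.standardized:
            return self
        means = self.X.mean(axis=0)
        scales = self.X.std(axis=0, ddof=0)
        if np.any(scales <= 0):
            bad = [self.feature_names[j] for j in np.flatnonzero(scales <= 0)]
            raise ValueError(f"constant column(s) cannot be standardized: {bad}")
        Xs = (self.X - means) / scales
        return Dataset(
            Xs,
            self.y.copy(),
            standardized=True,
            column_means=means,
            column_scales=scales,
            feature_names=list(self.feature_names),
        )

    def coef_to_original_scale(
        self, intercept: float, coef: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Map (intercept, coefficients) fitted on this standardized dataset
        back to the raw predictor scale."""
        if not self.standardized:
            return float(intercept), np.asarray(coef, dtype=float)
        coef = np.asarray(coef, dtype=float)
        coef_orig = coef / self.column_scales
        b0 = float(intercept - np.dot(coef_orig, self.column_means))
        return b0, coef_orig


def _check_binary(y: np.ndarray) -> None:
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("logistic loss requires y in {0, 1}")


def pointwise_loss(s: np.ndarray, y: np.ndarray, loss: LossSpec) -> np.ndarray:
    """Vectorized ``rho(s, y)``; overflow-safe for the logistic loss."""
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    if loss.name == "logistic":
        _check_binary(y)
        # -y*s + log(1+e^s) = log1p(e^{-|s|}) + max(s,0) - y*s
        return np.log1p(np.exp(-np.abs(s))) + np.maximum(s, 0.0) - y * s
    if loss.name == "quadratic":
        return 0.5 * (y - s) ** 2
    r = np.abs(y - s)
    d = loss.huber_delta
    return np.where(r <= d, 0.5 * r * r, d * (r - 0.5 * d))


def pointwise_dloss(s: np.ndarray, y: np.ndarray, loss: LossSpec) -> np.ndarray:
    """Vectorized derivative of ``rho`` in its first argument."""
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    if loss.name == "logistic":
        from scipy.special import expit

        return expit(s) - y
    if loss.name == "quadratic":
        return s - y
    # Huber: d/ds [ H_delta(y - s) ] = -clip(y - s, -delta, delta)
    d = loss.huber_delta
    return -np.clip(y - s, -d, d)


def loss_value(s: float, y: float, loss: LossSpec) -> float:
    """Scalar loss ``rho(s, y)``; see module docstring for the three forms."""
    return float(pointwise_loss(np.asarray(s), np.asarray(y), loss))


def _linear_predictor(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != X.shape[1] + 1:
        raise ValueError(
            f"beta has length {beta.shape[0]}, expected p+1 = {X.shape[1] + 1} "
            "(intercept first)"
        )
    return beta[0] + X @ beta[1:]


def empirical_risk(beta: np.ndarray, data: Dataset, loss: LossSpec) -> float:
    """``R_n(b)``: mean pointwise loss at linear predictor ``b0 + X b~``."""
    s = _linear_predictor(beta, data.X)
    return float(pointwise_loss(s, data.y, loss).mean())


def risk_gradient(beta: np.ndarray, data: Dataset, loss: LossSpec) -> np.ndarray:
    """Gradient of ``empirical_risk`` at ``beta`` (length p+1, intercept first)."""
    s = _linear_predictor(beta, data.X)
    g = pointwise_dloss(s, data.y, loss)
    n = data.n
    out = np.empty(beta.shape[0])
    out[0] = g.mean()
    out[1:] = data.X.T @ g / n
    return out
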
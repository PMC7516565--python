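"""Synthetic benchmark models M1 and M2 with known ground truth.

Both models draw a latent Gaussian vector Z ~ N_p(0, Sigma) with AR(1)
correlation Sigma[i, j] = rho^|i-j| and generate a binary response through
the cubed-logit link

    P(Y = 1 | X = x) = q_L((x_1 + x_2)^3),     q_L(u) = 1 / (1 + e^{-u}).

* **M1** augments the design with the monomials of (X1, X2) up to degree 3:
  X3 = X1^2, X4 = X2^2, X5 = X1 X2, X6 = X1^2 X2, X7 = X1 X2^2, X8 = X1^3,
  X9 = X2^3, and Xj = Z_{j-7} for j = 10..p. Since
  (x1 + x2)^3 = 3 x6 + 3 x7 + x8 + x9, the logistic model is *correctly
  specified* on this design, with active set {6, 7, 8, 9} and projection
  coefficients (3, 3, 1, 1).
* **M2** keeps the raw Gaussian predictors, so the logistic fit is
  *misspecified*; because Gaussian designs satisfy the linear regressions
  condition, the population logistic projection is collinear with the
  generating direction: beta* = eta * (1, 1, 0, ..., 0) for some eta > 0,
  hence the scoring target is the support {1, 2} with direction (1, 1).

Predictor labels in documentation and reports are 1-based (x1..xp); the
index sets stored on :class:`SimTruth` are 0-based column positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .losses import Dataset

__all__ = ["SimConfig", "SimTruth", "make_sigma", "response_prob", "simulate_m1", "simulate_m2", "simulate"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated dataset."""

    model: str  # "M1" or "M2"
    n: int
    p: int
    rho: float
    seed: int

    def __post_init__(self) -> None:
        if self.model not in ("M1", "M2"):
            raise ValueError("model must be 'M1' or 'M2'")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.model == "M1" and self.p < 10:
            raise ValueError("M1 requires p >= 10")
        if self.model == "M2" and self.p < 2:
            raise ValueError("M2 requires p >= 2")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset (0-based index sets).

    ``active_set_projection``/``beta_projection`` are the scoring target:
    the support and coefficients of the population risk minimizer of the
    logistic fit. For M2 only the direction of ``beta_projection`` is
    identified (eta > 0 unknown).
    """

    active_set_generating: tuple[int, ...]
    beta_generating: np.ndarray
    active_set_projection: tuple[int, ...]
    beta_projection: np.ndarray
    correctly_specified: bool

    @property
    def projection_labels(self) -> list[str]:
        return [f"x{j + 1}" for j in self.active_set_projection]

    def beta_projection_full(self, p: int) -> np.ndarray:
        """The projection coefficients embedded in a length-p vector."""
        out = np.zeros(p)
        out[list(self.active_set_projection)] = self.beta_projection
        return out


def make_sigma(p: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix Sigma[i, j] = rho^|i-j| (positive definite)."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def response_prob(u) -> np.ndarray | float:
    """The cubed-logit response q_L(u^3), overflow-safe."""
    u = np.asarray(u, dtype=float)
    out = expit(u**3)
    return float(out) if out.ndim == 0 else out


def _draw_gaussian(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    if rho == 0.0:
        return rng.standard_normal((n, p))
    L = np.linalg.cholesky(make_sigma(p, rho))
    return rng.standard_normal((n, p)) @ L.T


def simulate_m1(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Correctly specified monomial design (see module docstring)."""
    if cfg.model != "M1":
        raise ValueError("config is not for model M1")
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n, cfg.p
    Z = _draw_gaussian(n, p, cfg.rho, rng)
    X = np.empty((n, p))
    z1, z2 = Z[:, 0], Z[:, 1]
    X[:, 0] = z1
    X[:, 1] = z2
    X[:, 2] = z1**2
    X[:, 3] = z2**2
    X[:, 4] = z1 * z2
    X[:, 5] = z1**2 * z2
    X[:, 6] = z1 * z2**2
    X[:, 7] = z1**3
    X[:, 8] = z2**3
    if p > 9:
        X[:, 9:] = Z[:, 2 : p - 7]
    prob = response_prob(z1 + z2)
    y = (rng.random(n) < prob).astype(float)
    truth = SimTruth(
        active_set_generating=(0, 1),
        beta_generating=np.array([1.0, 1.0]),
        active_set_projection=(5, 6, 7, 8),
        beta_projection=np.array([3.0, 3.0, 1.0, 1.0]),
        correctly_specified=True,
    )
    return Dataset(X, y), truth


def simulate_m2(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Misspecified raw-Gaussian design (see module docstring)."""
    if cfg.model != "M2":
        raise ValueError("config is not for model M2")
    rng = np.random.default_rng(cfg.seed)
    X = _draw_gaussian(cfg.n, cfg.p, cfg.rho, rng)
    prob = response_prob(X[:, 0] + X[:, 1])
    y = (rng.random(cfg.n) < prob).astype(float)
    truth = SimTruth(
        active_set_generating=(0, 1),
        beta_generating=np.array([1.0, 1.0]),
        active_set_projection=(0, 1),
        beta_projection=np.array([1.0, 1.0]),
        correctly_specified=False,
    )
    return Dataset(X, y), truth


def simulate(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Dispatch on ``cfg.model``."""
    return simulate_m1(cfg) if cfg.model == "M1" else simulate_m2(cfg)
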
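"""Theory diagnostics: the restricted-eigenvalue cone and Lasso separation.

The Lasso error vector Delta = beta_hat_L - beta* concentrates, for a
well-chosen penalty, in the cone

    C_eps = { Delta : ||Delta_{s*^c}||_1 <= (3 + eps) ||Delta_{s*}||_1 },

and the analysis requires the restricted minimal eigenvalue

    kappa_H(eps) = inf_{Delta in C_eps \\ {0}}  Delta' H Delta / Delta' Delta

of a nonnegative-definite curvature matrix H to stay away from zero. The
infimum over the cone is a nonconvex program; `restricted_eigenvalue`
reports an *upper bound*, found by evaluating the Rayleigh quotient over a
deliberate candidate set (cone-boundary rays, projected bottom
eigenvectors, random cone samples) and polishing the best candidates with
sign-constrained local descent.

`separation_holds` checks the finite-sample separation predicate
max_{i not in s*} |b_i| <= min_{i in s*} |b_i|, which guarantees that s*
lies on the magnitude-ordered nested chain built from b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ConeSpec",
    "KappaEstimate",
    "in_cone",
    "restricted_eigenvalue",
    "separation_holds",
]


@dataclass(frozen=True)
class ConeSpec:
    """The cone C_eps around a designated support (0-based indices)."""

    true_support: tuple[int, ...]
    epsilon: float
    dimension: int

    def __post_init__(self) -> None:
        if not self.true_support:
            raise ValueError("true_support must be nonempty")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if any(j < 0 or j >= self.dimension for j in self.true_support):
            raise ValueError("support indices out of range")

    @property
    def constant(self) -> float:
        return 3.0 + self.epsilon

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        on = np.zeros(self.dimension, dtype=bool)
        on[list(self.true_support)] = True
        return on, ~on


def in_cone(delta: np.ndarray, cone: ConeSpec, rtol: float = 1e-12) -> bool:
    """True iff ||delta off support||_1 <= (3+eps) * ||delta on support||_1."""
    delta = np.asarray(delta, dtype=float)
    if delta.shape[0] != cone.dimension:
        raise ValueError("delta has wrong dimension")
    on, off = cone.masks()
    lhs = np.abs(delta[off]).sum()
    rhs = cone.constant * np.abs(delta[on]).sum()
    return bool(lhs <= rhs * (1.0 + rtol) + 1e-300)


def _project_into_cone(delta: np.ndarray, cone: ConeSpec) -> np.ndarray:
    """Shrink the off-support block onto the cone boundary if outside."""
    on, off = cone.masks()
    out = delta.copy()
    lhs = np.abs(out[off]).sum()
    rhs = cone.constant * np.abs(out[on]).sum()
    if lhs > rhs:
        out[off] *= 0.0 if lhs == 0 else rhs / lhs
    return out


def _rayleigh(H: np.ndarray, v: np.ndarray) -> float:
    nv = v @ v
    return float(v @ H @ v / nv) if nv > 0 else np.inf


@dataclass
class KappaEstimate:
    """Upper-bound estimate of kappa_H(eps) with its attaining direction."""

    value: float
    direction: np.ndarray

    def __float__(self) -> float:
        return self.value


def _candidate_directions(
    H: np.ndarray, cone: ConeSpec, n_samples: int, rng: np.random.Generator
) -> list[np.ndarray]:
    p = cone.dimension
    on, off = cone.masks()
    cands: list[np.ndarray] = []
    # bottom eigenvectors, projected into the cone
    w, V = np.linalg.eigh(H)
    for i in range(min(3, p)):
        cands.append(_project_into_cone(V[:, i], cone))
    # pure on-support directions (always feasible), incl. per-coordinate
    for j in cone.true_support:
        e = np.zeros(p)
        e[j] = 1.0
        cands.append(e)
    # boundary rays: all mass allowed off-support concentrated on one coord
    on_patterns = [np.ones(on.sum())]
    if p <= 2000:
        vb = V[:, 0][on]
        if np.linalg.norm(vb) > 0:
            on_patterns.append(np.sign(vb) + (vb == 0))
    for pat in on_patterns:
        base = np.zeros(p)
        base[on] = pat / np.abs(pat).sum() if np.abs(pat).sum() else pat
        budget = cone.constant * np.abs(base[on]).sum()
        for j in np.flatnonzero(off):
            for sgn in (1.0, -1.0):
                d = base.copy()
                d[j] = sgn * budget
                cands.append(d)
    # random cone samples
    for _ in range(n_samples):
        d = rng.standard_normal(p)
        cands.append(_project_into_cone(d, cone))
    return cands


def _polish(H: np.ndarray, cone: ConeSpec, x0: np.ndarray) -> np.ndarray:
    """Sign-constrained local descent of the Rayleigh quotient in the cone.

    The orthant of the starting point is frozen so the l1 constraint becomes
    linear; SLSQP then minimizes x'Hx on the unit sphere inside the cone
    slice. A failed polish just returns the starting point.
    """
    p = cone.dimension
    on, off = cone.masks()
    sgn = np.sign(x0)
    sgn[sgn == 0] = 1.0
    c_lin = np.where(on, cone.constant * sgn, -sgn)

    cons = [
        {"type": "eq", "fun": lambda x: x @ x - 1.0, "jac": lambda x: 2.0 * x},
        {"type": "ineq", "fun": lambda x: c_lin @ x, "jac": lambda x: c_lin},
        {"type": "ineq", "fun": lambda x: sgn * x, "jac": lambda x: np.diag(sgn)},
    ]
    x0n = x0 / np.linalg.norm(x0)
    try:
        res = optimize.minimize(
            lambda x: float(x @ H @ x),
            x0n,
            jac=lambda x: 2.0 * (H @ x),
            method="SLSQP",
            constraints=cons,
            options={"maxiter": 200, "ftol": 1e-14},
        )
    except Exception:
        return x0n
    x = res.x
    nx = np.linalg.norm(x)
    if nx == 0 or not in_cone(x, cone, rtol=1e-8):
        return x0n
    return x / nx


def restricted_eigenvalue(
    H: np.ndarray,
    cone: ConeSpec,
    n_samples: int = 500,
    seed: int = 0,
) -> KappaEstimate:
    """Upper-bound estimate of the restricted eigenvalue kappa_H(eps).

    The search is seeded and scale-equivariant: H is normalized by its
    spectral norm before the search, so kappa(c*H) = c * kappa(H) exactly
    on the same seed. Valid only as an upper bound of the true infimum.
    """
    H = np.asarray(H, dtype=float)
    p = cone.dimension
    if H.shape != (p, p):
        raise ValueError("H must be p x p")
    if p > 50:
        raise ValueError("diagnostic limited to p <= 50")
    if np.max(np.abs(H - H.T)) > 1e-10:
        raise ValueError("H must be symmetric")
    w = np.linalg.eigvalsh(H)
    if w[0] < -1e-8:
        raise ValueError("H must be nonnegative definite")
    scale = float(np.linalg.norm(H, 2))
    if scale == 0.0:
        return KappaEstimate(0.0, np.zeros(p))
    Hn = H / scale
    rng = np.random.default_rng(seed)
    cands = _candidate_directions(Hn, cone, n_samples, rng)
    vals = [( _rayleigh(Hn, d), i) for i, d in enumerate(cands)]
    vals.sort(key=lambda t: t[0])
    best_val, best_dir = vals[0][0], cands[vals[0][1]]
    for val, i in vals[:5]:
        x = _polish(Hn, cone, cands[i])
        v = _rayleigh(Hn, x)
        if v < best_val:
            best_val, best_dir = v, x
    best_val = max(best_val, 0.0)
    return KappaEstimate(best_val * scale, best_dir / np.linalg.norm(best_dir))


def separation_holds(beta_L: np.ndarray, s_star) -> bool:
    """max off-support |coef| <= min on-support |coef| (0-based indices)."""
    beta_L = np.asarray(beta_L, dtype=float)
    s = sorted(int(j) for j in set(s_star))
    if not s:
        raise ValueError("s_star must be nonempty")
    if len(s) >= beta_L.shape[0]:
        raise ValueError("s_star must be a proper subset of the coordinates")
    if any(j < 0 or j >= beta_L.shape[0] for j in s):
        raise ValueError("support indices out of range")
    on = np.zeros(beta_L.shape[0], dtype=bool)
    on[s] = True
    return bool(np.max(np.abs(beta_L[~on])) <= np.min(np.abs(beta_L[on])))
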
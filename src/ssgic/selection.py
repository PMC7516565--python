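"""Nested-family construction and GIC minimization: SS, SSnet, SSCV, LFT.

The two-stage selector screens with the Lasso, orders the surviving
predictors by coefficient magnitude into a nested chain

    {}  ⊂ {j1} ⊂ {j1, j2} ⊂ ... ⊂ {j1, ..., jk},   |b_j1| >= ... >= |b_jk| > 0,

and picks the chain member minimizing the Generalized Information Criterion

    GIC(w) = n * R_n(beta_hat(w)) + a_n * (|w| + 1),

where beta_hat(w) is the unpenalized ERM refit on w and a_n is the penalty
weight (2 for AIC, log n for BIC, log n + 2 d log p for EBIC(d),
log(log n) * log p for the Lasso-plugin LFT criterion). The "+1" counts the
always-present intercept; set ``count_intercept=False`` for the bare |w|
convention — selection is unaffected because the offset is common to all
candidates on a fixed dataset.

SSnet unions the chains of a whole lambda grid (dropping any lambda whose
support exceeds n, where the Lasso solution is not unique); SSCV picks one
lambda by 10-fold CV with the one-standard-error rule; LFT skips the refit
and scores the Lasso fits themselves over the grid.

All support index sets are 0-based column positions of the design matrix;
reports use the 1-based column names (x1, x2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .losses import Dataset, LossSpec, empirical_risk
from .penalized import (
    LassoPath,
    RefitResult,
    cv_select_lambda,
    fit_lasso,
    fit_lasso_path,
    lambda_grid,
    refit_erm,
)

__all__ = [
    "GICPenalty",
    "NestedFamily",
    "SelectionResult",
    "order_support",
    "build_nested_family",
    "build_union_family",
    "penalty_value",
    "gic",
    "ss_select",
    "ssnet_select",
    "sscv_select",
    "lft_select",
    "exhaustive_gic",
    "parse_penalty",
]

_PENALTY_NAMES = ("aic", "bic", "ebic", "lft")


@dataclass(frozen=True)
class GICPenalty:
    """GIC penalty weight a_n; ``d`` applies to EBIC only."""

    name: str
    d: float = 1.0
    count_intercept: bool = True

    def __post_init__(self) -> None:
        if self.name not in _PENALTY_NAMES:
            raise ValueError(f"unknown penalty {self.name!r}")
        if self.name == "ebic" and not self.d > 0:
            raise ValueError("EBIC requires d > 0")

    @property
    def label(self) -> str:
        if self.name == "ebic":
            d = self.d
            return f"ebic{d:g}"
        return self.name


def parse_penalty(spec) -> GICPenalty:
    """Accept a GICPenalty or a string like 'aic', 'bic', 'ebic', 'ebic1'."""
    if isinstance(spec, GICPenalty):
        return spec
    s = str(spec).lower()
    if s.startswith("ebic"):
        d = float(s[4:]) if len(s) > 4 else 1.0
        return GICPenalty("ebic", d=d)
    return GICPenalty(s)


def penalty_value(pen: GICPenalty, n: int, p: int) -> float:
    """The weight a_n multiplying model size in GIC."""
    if n < 2:
        raise ValueError("need n >= 2")
    if p < 1:
        raise ValueError("need p >= 1")
    if pen.name == "aic":
        return 2.0
    if pen.name == "bic":
        return float(np.log(n))
    if pen.name == "ebic":
        return float(np.log(n) + 2.0 * pen.d * np.log(p))
    return float(np.log(np.log(n)) * np.log(p))


def order_support(coefficients: np.ndarray) -> list[int]:
    """Nonzero coefficient indices sorted by |value| descending.

    Ties break toward the smaller index; an all-zero vector gives [].
    """
    c = np.asarray(coefficients, dtype=float)
    nz = np.flatnonzero(c)
    return sorted(nz.tolist(), key=lambda j: (-abs(c[j]), j))


def build_nested_family(ordered: list[int]) -> list[tuple[int, ...]]:
    """The chain [{}, {j1}, {j1,j2}, ...] from an ordered index list."""
    if len(set(ordered)) != len(ordered):
        raise ValueError("ordered index list contains duplicates")
    chain: list[tuple[int, ...]] = [()]
    for k in range(1, len(ordered) + 1):
        chain.append(tuple(sorted(ordered[:k])))
    return chain


@dataclass
class NestedFamily:
    """Chains of supports from a Lasso path and their deduplicated union."""

    families: list[list[tuple[int, ...]]]
    merged: list[tuple[int, ...]]
    source_lambdas: list[float]
    size_cap: int
    dropped_lambdas: list[float] = field(default_factory=list)


def build_union_family(path: LassoPath, size_cap: int | None, n: int) -> NestedFamily:
    """Union the per-lambda chains of a path (SSnet's family M).

    A lambda whose support exceeds n contributes nothing (Lasso/ML solutions
    not unique there); supports larger than ``size_cap`` (default n) are
    removed; the empty model is always a member.
    """
    if size_cap is None:
        size_cap = n
    families = []
    source = []
    dropped = []
    merged: dict[tuple[int, ...], None] = {(): None}
    for i in range(len(path)):
        ordered = order_support(path.coefficients[i])
        if len(ordered) > n:
            dropped.append(float(path.lambdas[i]))
            continue
        chain = build_nested_family(ordered)
        families.append(chain)
        source.append(float(path.lambdas[i]))
        for w in chain:
            if 0 < len(w) <= size_cap:
                merged.setdefault(w, None)
    return NestedFamily(
        families=families,
        merged=list(merged.keys()),
        source_lambdas=source,
        size_cap=size_cap,
        dropped_lambdas=dropped,
    )


def gic(
    data: Dataset, support, loss: LossSpec, pen: GICPenalty
) -> tuple[float, RefitResult]:
    """GIC value and the underlying unpenalized refit for one support."""
    refit = refit_erm(data, support, loss)
    size = len(refit.support) + (1 if pen.count_intercept else 0)
    a_n = penalty_value(pen, data.n, data.p)
    return data.n * refit.risk + a_n * size, refit


@dataclass
class SelectionResult:
    """Outcome of a GIC-based selector.

    ``selected_support`` holds 0-based column indices; ``coef``/``intercept``
    are on the original predictor scale, ``coef_std``/``intercept_std`` on
    the standardized scale the screening ran on. ``gic_trace`` records, per
    candidate support, the scaled risk, penalty term, and criterion value.
    """

    procedure: str
    selected_support: tuple[int, ...]
    intercept: float
    coef: np.ndarray
    intercept_std: float
    coef_std: np.ndarray
    gic_trace: list[dict]
    penalty: GICPenalty | None
    loss: LossSpec
    lam: float | None = None
    family: list[tuple[int, ...]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def selected_names(self) -> list[str]:
        return [f"x{j + 1}" for j in self.selected_support]


def _minimize_gic(
    data: Dataset,
    candidates: list[tuple[int, ...]],
    loss: LossSpec,
    pen: GICPenalty,
) -> tuple[tuple[int, ...], RefitResult, list[dict], list[str]]:
    """GIC over a candidate list; ties break to smaller |w|, then lexicographic."""
    a_n = penalty_value(pen, data.n, data.p)
    trace = []
    notes: list[str] = []
    cache: dict[tuple[int, ...], RefitResult] = {}
    best_key = None
    best = None
    for w in candidates:
        w = tuple(sorted(w))
        if w in cache:
            continue
        refit = refit_erm(data, w, loss)
        cache[w] = refit
        size = len(w) + (1 if pen.count_intercept else 0)
        value = data.n * refit.risk + a_n * size
        trace.append(
            {
                "support": w,
                "n_risk": data.n * refit.risk,
                "penalty": a_n * size,
                "gic": value,
                "converged": refit.converged,
            }
        )
        if not refit.converged:
            notes.append(f"refit on {w} did not converge (capped iterations)")
        key = (value, len(w), w)
        if best_key is None or key < best_key:
            best_key, best = key, w
    return best, cache[best], trace, notes


def _package_result(
    procedure: str,
    data_std: Dataset,
    winner: tuple[int, ...],
    refit: RefitResult,
    trace: list[dict],
    notes: list[str],
    pen: GICPenalty | None,
    loss: LossSpec,
    lam: float | None,
    family: list[tuple[int, ...]],
) -> SelectionResult:
    b0, coef = data_std.coef_to_original_scale(refit.intercept, refit.coef)
    return SelectionResult(
        procedure=procedure,
        selected_support=winner,
        intercept=b0,
        coef=coef,
        intercept_std=refit.intercept,
        coef_std=refit.coef.copy(),
        gic_trace=trace,
        penalty=pen,
        loss=loss,
        lam=lam,
        family=family,
        warnings=notes,
        converged=refit.converged,
    )


def ss_select(
    data: Dataset,
    loss: LossSpec,
    lam: float,
    pen: GICPenalty,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> SelectionResult:
    """Single-lambda screening + GIC selection over the nested chain."""
    data_std = data.standardize()
    pen = parse_penalty(pen)
    fit = fit_lasso(data_std, loss, lam, tol=tol, max_iter=max_iter)
    chain = build_nested_family(order_support(fit.coef))
    winner, refit, trace, notes = _minimize_gic(data_std, chain, loss, pen)
    if not fit.converged:
        notes.append("lasso fit did not converge")
    return _package_result(
        "ss", data_std, winner, refit, trace, notes, pen, loss, lam, chain
    )


def ssnet_select(
    data: Dataset,
    loss: LossSpec,
    pen: GICPenalty,
    lambdas: np.ndarray | None = None,
    m: int = 20,
    ratio: float = 0.01,
    size_cap: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> SelectionResult:
    """Multi-lambda screening: GIC over the union of all nested chains."""
    data_std = data.standardize()
    pen = parse_penalty(pen)
    if lambdas is None:
        lambdas = lambda_grid(data_std, loss, m=m, ratio=ratio)
    path = fit_lasso_path(data_std, loss, lambdas, tol=tol, max_iter=max_iter)
    fam = build_union_family(path, size_cap, data_std.n)
    winner, refit, trace, notes = _minimize_gic(data_std, fam.merged, loss, pen)
    if not np.all(path.converged):
        notes.append("some path fits did not converge")
    if fam.dropped_lambdas:
        notes.append(
            f"dropped {len(fam.dropped_lambdas)} lambda(s) with support > n"
        )
    return _package_result(
        "ssnet", data_std, winner, refit, trace, notes, pen, loss, None, fam.merged
    )


def sscv_select(
    data: Dataset,
    loss: LossSpec,
    pen: GICPenalty,
    lambdas: np.ndarray | None = None,
    m: int = 20,
    ratio: float = 0.01,
    K: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> SelectionResult:
    """CV-chosen lambda (1SE rule), then single-lambda SS at that lambda."""
    data_std = data.standardize()
    pen = parse_penalty(pen)
    if lambdas is None:
        lambdas = lambda_grid(data_std, loss, m=m, ratio=ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 1:
        lam = float(lambdas[0])
        cv_flags: list[str] = []
    else:
        cv = cv_select_lambda(
            data_std, loss, lambdas, K=K, rule="1se", seed=seed, tol=tol,
            max_iter=max_iter,
        )
        lam = cv.lam_selected
        cv_flags = cv.flags
    res = ss_select(data_std, loss, lam, pen, tol=tol, max_iter=max_iter)
    res.procedure = "sscv"
    res.warnings = cv_flags + res.warnings
    return res


def lft_select(
    data: Dataset,
    loss: LossSpec,
    lambdas: np.ndarray | None = None,
    m: int = 20,
    ratio: float = 0.01,
    count_intercept: bool = True,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> SelectionResult:
    """Lasso-plugin GIC over the lambda grid (no refit).

    Scores n*R_n at the Lasso solution itself plus
    log(log n) * log p * (|support| + 1) and returns the support of the
    winning lambda with its Lasso coefficients.
    """
    data_std = data.standardize()
    if data_std.n < 3:
        raise ValueError("LFT penalty needs n >= 3")
    if lambdas is None:
        lambdas = lambda_grid(data_std, loss, m=m, ratio=ratio)
    path = fit_lasso_path(data_std, loss, lambdas, tol=tol, max_iter=max_iter)
    pen = GICPenalty("lft", count_intercept=count_intercept)
    a_n = penalty_value(pen, data_std.n, data_std.p)
    n = data_std.n
    trace = []
    best = None
    best_key = None
    for i in range(len(path)):
        supp = tuple(np.flatnonzero(path.coefficients[i]).tolist())
        if len(supp) > n:
            continue
        beta = np.concatenate(([path.intercepts[i]], path.coefficients[i]))
        nrisk = n * empirical_risk(beta, data_std, loss)
        size = len(supp) + (1 if count_intercept else 0)
        value = nrisk + a_n * size
        trace.append(
            {
                "support": supp,
                "lambda": float(path.lambdas[i]),
                "n_risk": nrisk,
                "penalty": a_n * size,
                "gic": value,
            }
        )
        key = (value, len(supp), supp)
        if best_key is None or key < best_key:
            best_key, best = key, i
    if best is None:
        raise ValueError("no admissible lambda: every support exceeded n")
    i = best
    supp = tuple(np.flatnonzero(path.coefficients[i]).tolist())
    b0, coef = data_std.coef_to_original_scale(
        float(path.intercepts[i]), path.coefficients[i]
    )
    notes = [] if np.all(path.converged) else ["some path fits did not converge"]
    return SelectionResult(
        procedure="lft",
        selected_support=supp,
        intercept=b0,
        coef=coef,
        intercept_std=float(path.intercepts[i]),
        coef_std=path.coefficients[i].copy(),
        gic_trace=trace,
        penalty=pen,
        loss=loss,
        lam=float(path.lambdas[i]),
        family=[t["support"] for t in trace],
        warnings=notes,
        converged=bool(path.converged[i]),
    )


def exhaustive_gic(
    data: Dataset,
    loss: LossSpec,
    pen: GICPenalty,
    kmax: int,
) -> SelectionResult:
    """Brute-force GIC over all subsets of size <= kmax (small-p oracle)."""
    if data.p > 15 or kmax > 6:
        raise ValueError("exhaustive search limited to p <= 15, kmax <= 6")
    data_std = data.standardize()
    pen = parse_penalty(pen)
    candidates = [
        tuple(w)
        for k in range(kmax + 1)
        for w in combinations(range(data_std.p), k)
    ]
    winner, refit, trace, notes = _minimize_gic(data_std, candidates, loss, pen)
    return _package_result(
        "exhaustive", data_std, winner, refit, trace, notes, pen, loss, None,
        candidates,
    )
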
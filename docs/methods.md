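# Methods

## Model and estimand

We observe i.i.d. pairs (Xᵢ, Yᵢ) ∈ ℝᵖ × {0, 1} and fit linear-index models
b = (b₀, b̃) through a convex pointwise loss ρ(s, y):

* logistic: ρ(s, y) = −ys + log(1 + eˢ) (negative Bernoulli log-likelihood);
* quadratic: ρ(s, y) = (y − s)²/2 (linear-probability fit, y numeric);
* Huber: the Huber function of r = y − s with knee δ (default 0.1),
  r²/2 for |r| ≤ δ and δ(|r| − δ/2) beyond.

The estimand is the support s* of the pseudo-true vector
β\* = argmin_b E ρ(bᵀX, Y). No assumption is made that the response function
is the one matching the loss: when it is not, β\* is the risk projection.
For Gaussian (more generally elliptical) designs the linear-regressions
condition E(X | βᵀX) affine in βᵀX forces β\* = ηβ for some scalar η, so the
projection support still identifies the truly active predictors. The
logistic and Huber losses are Lipschitz in s (constants 1 and δ), which is
what the consistency theory for the two-stage selector leans on; the
quadratic loss is implemented and tested but carries no such guarantee, a
distinction the API records in `LossSpec.lipschitz_constant`.

## The selectors

**SS** (single λ): fit the ℓ1-penalized empirical risk minimizer at λ,
order the nonzero coefficients by |value| (ties to the smaller index), form
the nested chain ∅ ⊂ {j₁} ⊂ …, refit each member without penalty, and pick
the minimizer of GIC(w) = n·R_n(β̂(w)) + a_n(|w|+1).

**SSnet**: the same over a log-spaced grid λ₁ > … > λ_m (m = 20, dynamic
range 100), taking the union of all chains plus ∅, after dropping any λ
whose support exceeds n (the penalized and refit problems are not unique
there) and any member larger than `size_cap` (default n). Refits are cached
by support across the merged family.

**SSCV**: λ chosen by K-fold cross-validation (K = 10) of held-out mean
risk with the one-standard-error rule — the largest λ whose CV risk is
within one SE of the minimum — then SS at that λ. Folds are a seeded
partition, stratified by the response under logistic loss so single-class
folds essentially cannot arise; if a training fold is still single-class,
an intercept-only fit (clipped class proportion) stands in and the result
is flagged.

**LFT**: over the same grid, score the Lasso fit itself (no refit) with
n·R_n(β̂_L(λ)) + log(log n)·log p·(|supp|+1) and return the support of the
winning λ.

GIC ties break toward the smaller model, then the lexicographically
smallest support — parsimony first, determinism always. The model-size term
counts the always-present intercept (+1) for every procedure;
`count_intercept=False` gives the bare |w| convention, which shifts all
candidates by a constant on a fixed dataset and so never changes the
selection. Whether the LFT source convention counts the intercept is not
documented anywhere we could find; the +1 is used for internal consistency.

An exhaustive GIC search over all subsets with |w| ≤ kmax (guarded to
p ≤ 15, kmax ≤ 6) is provided as a small-p oracle; the test suite uses it
to verify that the chain-restricted search loses nothing whenever the Lasso
separates the exhaustive winner.

## Numerical choices

* **Penalized solver**: one code path for all three losses — FISTA
  (accelerated proximal gradient) with backtracking line search and
  gradient-based adaptive restart; the intercept is never thresholded.
  Convergence is declared on the KKT residual (tol 1e−7, max 10⁴
  iterations); non-convergence is carried as a warning on the result, never
  an exception. Warm starts along the grid; reproducibility comes from
  solver determinism, not seeds. The λ-grid anchor λ₁ is the sup-norm of
  the predictor-block gradient at the intercept-only fit — by the KKT
  conditions the smallest λ with an empty support.
* **Refits**: quadratic loss by the normal equations (exact); logistic and
  Huber by L-BFGS-B with the analytic gradient, capped at 500 iterations.
  Under perfect logistic separation no finite minimizer exists; the cap
  acts as the regularizer, and an achieved risk below 1e−6 (attainable
  only along a diverging coefficient path) flags the refit as
  non-converged while still reporting the finite risk GIC needs.
* **Scales**: screening runs on column-standardized predictors (mean 0,
  SD 1; a constant column is an error); refit coefficients are reported on
  both the standardized and the original scale via the recorded affine map.
* **CV folds**: K may equal n (leave-one-out); only K > n is rejected.
* **Restricted eigenvalue**: κ_H(ε) = inf over the cone
  ‖Δ_{s*ᶜ}‖₁ ≤ (3+ε)‖Δ_{s*}‖₁ of the Rayleigh quotient of H is a nonconvex
  program; the estimator reports an *upper bound*: the best of (i) bottom
  eigenvectors of H projected into the cone, (ii) boundary rays putting the
  full allowed off-support mass on one coordinate, (iii) seeded random cone
  samples, refined by sign-constrained SLSQP descent on the unit sphere.
  H is normalized by its spectral norm before the search, making the
  estimate exactly scale-equivariant. For p = 2 a dense boundary scan in
  the tests provides an independent near-exact oracle (e.g. H = diag(1, 0),
  s* = {1}, ε = 1 gives 1/17). The default ε is 1; which H to diagnose is
  application-dependent — the CLI uses the empirical second-moment matrix
  as a convenience, stated as such.

## The benchmark generators

`simulate_m1` / `simulate_m2` draw Z ~ N_p(0, Σ) with AR(1) correlation
Σᵢⱼ = ρ^|i−j| (Cholesky factorization; a per-replicate seeded Generator
stream makes every replicate independently reproducible) and a response
P(Y=1|x) = q_L((x₁+x₂)³). Defaults in the replicated study are the
conditions the benchmark defines: n = 500, p = 150,
ρ ∈ {−0.9 + 0.15k}. M1 appends the monomials of (X₁, X₂) up to degree 3,
so the cubed link expands exactly as 3x₆ + 3x₇ + x₈ + x₉ — the logistic
model is correctly specified with projection coefficients (3, 3, 1, 1) on
{6, 7, 8, 9} — at the price of strong built-in dependence
(Corr(X₁, X₈) = E Z⁴/√(E Z⁶) = 3/√15 ≈ 0.7746). M2 keeps the raw Gaussian
columns, making the logistic fit misspecified with target support {1, 2}
and direction (1, 1) (η unidentified).

What the generators deliberately do not emulate: non-Gaussian or
heavy-tailed designs, dependent observations, link functions other than the
cubed logit. Passing tests therefore demonstrate correctness of the
machinery and finite-sample behavior *under these conditions*, not
robustness of the selectors to arbitrary real data.

## Metrics

Per study cell, L replicates are scored by Pinc (s* appears in the
candidate family), Pequal (selected = s*), Psupset (selected ⊇ s*), and
ANGLE — the mean arccos |cos ∠(β̃\*, β̂)| with intercepts excluded and a
zero norm on either side counting as a right angle. In M1 the reference
vector for ANGLE is the projection (3, 3, 1, 1) on {6,…,9}, not the
generating (1, 1) on {1, 2}; in M2 collinearity makes (1, 1) on {1, 2} the
scale-free choice. Replicates whose refit hit the iteration cap contribute
their achieved coefficients and are flagged. Failed replicates are dropped
with a warning; a cell losing more than 10% is marked invalid.

## Problem sizes in the shipped tests

The replicated claims are exercised at reduced scale, chosen once as the
smallest sizes at which the qualitative contrasts are stable: the
M2 support-recovery headline at full n = 500, p = 150 with L = 50
replicates; the M1 procedure-ranking contrast (SSnet-BIC vs SSnet-EBIC1 vs
LFT) at the same n, p with L = 12; CV and separation properties with 50
seeded replicates of smaller designs. Full-size sweeps (L = 500, 13 ρ
values, all procedure × loss × penalty cells) remain available through
`run_experiment` / `ssgic run-experiment`.

## Known limitations

* The quadratic loss violates the Lipschitz assumption underlying the
  selection-consistency theory; it is provided for completeness and
  comparison, without the guarantee.
* κ_H(ε) is an upper bound; it certifies ill-conditioning (small values)
  but not well-conditioning.
* The λ-grid construction (geometric, ratio 0.01, anchored at the KKT λ₁)
  is a declared convention; published implementations differ in their grid
  defaults, so numerical agreement with other software at matched λ should
  only be expected fit-by-fit, not grid-by-grid.
* Elastic-net/SCAD/MCP penalties, adaptive or thresholded Lasso, probit
  loss, weighted observations and post-selection inference are out of
  scope.
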
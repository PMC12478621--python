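# Methods

## Model

Counts `y_ij` (person i = 1..N, item j = 1..M) are conditionally independent
given an L-dimensional latent trait vector `theta_i ~ MVN(0, Sigma)` with
unit-diagonal `Sigma`, and follow the mean-parameterized Conway–Maxwell–
Poisson (CMP) distribution

    P(Y = y | mu, nu) = lam(mu, nu)^y / (y!)^nu / Z(lam, nu),

where the rate `lam` is defined implicitly by the mean constraint
`E[Y; lam, nu] = mu` and `Z` is the normalizing series. The conditional mean
is log-linear in the traits, `log mu_ij = delta_j + a_j' theta_i`. `nu_j = 1`
recovers a multidimensional two-parameter Poisson model; `nu_j` above/below 1
gives conditional under-/overdispersion. Dispersions are optimized as
`log nu_j` so the search space is unconstrained.

### CMP numerics

All CMP quantities (normalizer, mean, variance, third central moment,
`E[log Y!]`, `E[Y log Y!]`) come from direct summation of the series in a
mode-anchored log scale (a numba kernel; summation stops once a term falls
below 1e-12 of the running sum past the mode, hard cap 10 000 terms, failure
raised as an error). No interpolation grid is used: direct summation is
exact at the mean/dispersion ranges this model family occupies and removes a
class of off-grid approximation error. The rate solve is Newton in
`log lam` — monotone because `d mean / d log lam = Var > 0` — warm-started
along optimization paths, with a bisection fallback. Viewing the pmf as an
exponential family in `log lam` gives the cumulant identities used
throughout: `d mu/d log lam = V` and `d V/d log lam = kappa3`.

## Estimation

The marginal likelihood integral is approximated by fixed Gauss–Hermite
quadrature: a tensor product of probabilists' rules mapped through the
Cholesky factor of `Sigma`, with nodes of product weight below 1e-10 dropped
and weights renormalized (the threshold is configurable; 0 keeps the full
tensor grid). Default nodes per trait: 10 for L ≤ 3, 4 for L = 4 — the
tensor grid grows geometrically in L, so density must fall with dimension.

EM alternates:

* **E-step** — posterior node probabilities `p_ik ∝ w_k prod_j CMP(y_ij |
  mu_jk, nu_j)`, computed with log-sum-exp.
* **M-step** — the expected complete-data log-likelihood Q decomposes over
  items; each item's block is maximized by damped-Newton coordinate updates
  (slopes and intercept) using the analytic gradient and Hessian diagonal,
  followed by one safeguarded Newton update of `log nu_j`. Every coordinate
  step is protected by per-item step-halving on Q. The dispersion gradient
  is analytic; its curvature is a finite difference of that gradient — the
  exact second derivative needs third-order log-factorial cross-moments
  whose numerical surface area is not worth one scalar per item. Because
  the updates are vectorized across items, one M-step costs a handful of
  (M × K) CMP-table builds regardless of M.

Identification uses the echelon (upper-triangle) constraint: item j < L is
free on its first j traits and fixed to zero above, L(L−1)/2 zeros in total.
Starts come from a multidimensional two-parameter Poisson fit (all CMP
quantities closed-form, so it is cheap), with moment-based dispersion starts
`-log(mean posterior-weighted squared Pearson residual)` clipped to [−2, 2];
this start recipe is a documented surrogate for the published unidimensional
one, and equidispersed data give starts near 0 as required.

Convergence is declared on the maximum absolute parameter change (default
1e-4) rather than on the likelihood, which is quadrature-approximated. The
observed-data log-likelihood trace is retained and is non-decreasing within
1e-6 (a generalized-EM property that holds for partial inner maximization,
which is the default: `inner_max_iter = 2` coordinate/dispersion cycles per
M-step; study-scale runs use 1).

## Lasso-penalized EM

The penalized M-step objective is `Q − eta * sum |a_jl|` over free slopes
(intercepts, dispersions and masked entries are never penalized). Each free
slope update is the closed-form soft-threshold solution of the local
quadratic approximation: Newton target `a + g/d` thresholded at `eta/d`,
where `d` is the curvature magnitude; the intercept gets the unpenalized
analogue. Sweeps repeat until the largest coordinate move is below 1e-6,
then dispersions are updated. A slope is "shrunken to zero" iff the update
returns exactly 0 — no epsilon thresholding, which is what makes the CER
comparison against rotation meaningful.

The penalty is applied on the whole-sample Q scale, so useful `eta` values
grow with N. The grid upper bound `eta_max` is the KKT bound: the largest
absolute slope gradient at zero slopes *under the Poisson warm-start
posterior*. (At the all-zero-slope fixed point the posterior collapses to
the prior and the slope score vanishes identically — zero slopes make the
traits unidentifiable — so the informative warm-start posterior is the
meaningful reference.) The default grid is 0 followed by 12 log-equidistant
values from `eta_max/1000` to `eta_max`; fits proceed in increasing order
with warm starts, the `eta = 0` entry starting from the unpenalized fit and
therefore converging in one iteration.

Model selection: `BIC(eta) = −2 l(theta_hat_eta) + log(N) · df`, with `l`
the *unpenalized* marginal log-likelihood at the penalized estimates and
`df` the number of parameters neither shrunken nor constrained to zero
(free nonzero slopes + all intercepts + all dispersions; whether the 2M
intercept/dispersion count is included shifts BIC by a constant in `eta`
and cannot change the selection). Ties resolve to the smallest `eta`.

Correlated traits: `Sigma` is never estimated inside the EM. The "oblique
lasso" plugs in the factor correlation matrix from an oblimin rotation of
the unpenalized discrimination matrix, falling back to the nearest
correlation matrix if numerically indefinite.

## Rotation

A single gradient-projection engine drives both criteria — varimax
(orthogonal) and oblimin with γ = 0, i.e. quartimin (oblique; γ = 0 is the
common default of reference implementations). Criteria are multimodal, so
10 seeded random restarts are run and the best criterion kept. Projected
gradient tolerance 1e-6. Conventions: `Lambda = A T` (orthogonal),
`Lambda = A (T')^{-1}`, `Phi = T'T` (oblique); both leave the Gram matrix
`Lambda Phi Lambda'` equal to `A A'`, which is the rotation-invariant
quantity the evaluation metrics consume. Criterion values were verified
against statsmodels' factor-rotation implementation to 1e-5 in tests.

## Synthetic data

The generator reproduces the design the model family was validated under,
and its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| L | 3 (or 4) | latent traits |
| m | 3 (or 5) | items per trait (M = L·m) |
| slopes | equidistant 0.2–0.3 per trait block | weak-to-moderate discriminations |
| intercepts | equidistant 1.5–3.5, randomly permuted | item means ≈ 4.5–33 |
| log-dispersions | equidistant −0.8–0.8, randomly permuted | mixed over/underdispersion |
| rho | 0 or 0.5 | trait correlation (the positive level is configurable; 0.5 is a moderate correlation typical of ability subdomains) |
| cross-loadings | value 0.1, probability 0.5, ceil(m/4) items per trait, ≥ 1 guaranteed | "slightly complex" structure |
| N | 600 per trial | study-scale sample size |

Cross-loading size/probability and the positive correlation level are
configurable: the original design's exact values live in unavailable
supplementary material, so the defaults above were chosen once as realistic
for weak secondary loadings and are documented rather than silently fixed.
What the generator does **not** emulate: zero-inflation, missing responses,
person misfit, non-normal traits — conclusions from passing tests transfer
to real data only where those assumptions are tenable.

## Evaluation

* **CER** — share of unconstrained discrimination entries whose exact
  zero/nonzero status matches the truth; the truth's columns are aligned to
  each estimate by greedy absolute-congruence matching (labels and signs are
  arbitrary) before scoring. Rotated solutions cannot produce exact zeros
  and legitimately score near the dense baseline.
* **Gram off-diagonals** — bias/RMSE of the upper off-diagonal of
  `Lambda Phi Lambda'`, identical for all rotations of one fit.
* **Bias/RMSE** of intercepts and log-dispersions per item, averaged with
  between-item spread.

## Problem sizes and numerical defaults

Chosen for a single CPU; all are configuration, not constants:

* Default EM tolerance 1e-4 (parameter change), max 1000 iterations;
  study-scale runs use 3e-4 and one inner M-step cycle, which changes CER
  and zero-selection results only in the third decimal on spot checks.
* Acceptance-scale runs: recovery and CER comparisons at N = 1000, L = 3,
  m = 5 with 4–5 quadrature nodes per trait; the condition sweep runs the
  full 16-cell design at N = 300 with one trial per cell and a 10-value
  penalty grid, and the acceptance script a 4-condition sweep at N = 600.
* Rate solver tolerance 1e-10 relative on the mean; series term rule 1e-12.
* Step-halving: 30 halvings maximum; moves below 1e-8 are accepted without
  the ascent check (they sit below the rate-solver noise floor).

## Known limitations

* Tensor-product quadrature limits practical dimension to L ≤ 4–5; no
  adaptive or Monte-Carlo E-step.
* No standard errors, person scoring, missing-data handling, or fit
  statistics; `Sigma` is fixed during estimation (two-step plug-in only).
* The lasso shrinks surviving slopes toward zero (no relaxed/adaptive
  variant), so BIC sometimes prefers dense solutions when true slopes are
  weak and N is small; with the design's slope range 0.2–0.3 this is
  visible below N ≈ 500.
* Very large counts or extreme dispersions can exhaust the series cap; the
  failure is raised, not silently truncated.
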
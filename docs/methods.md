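# Methods

## Model

For each node α of an undirected graphical model over mixed
continuous/binary variables X = (X₁, …, X_p), splinegraph estimates the
conditional density of X_α given the rest through the logistic density
transform

    f(x_α | x_∖α) ∝ e^{η(x)} ρ(x_α),     η(x) = ς + Σ_j η_j(x_j) + Σ_{k≠α} η_{αk}(x_α, x_k),

where ρ is a fixed, known reference density of x_α (below) and η lives in a
smoothing-spline ANOVA (SS ANOVA) model space with all main effects and the
two-way interactions involving α. Conditional independence X_α ⟂ X_k | rest
corresponds to η_{αk} ≡ 0, so the neighborhood of α is the set of k with a
nonzero fitted interaction. Running the fit for every α and intersecting
(AND rule, default) or uniting (OR rule) the two directed estimates per pair
gives the undirected graph.

Each continuous variable is affinely rescaled to [0, 1] and modeled in the
cubic-spline Sobolev space W₂²[0,1], decomposed as
{constants} ⊕ span{k1} ⊕ H1 with the scaled Bernoulli-polynomial kernels

    k1(x) = x − 1/2,   k2 = (k1² − 1/12)/2,   k4 = (k1⁴ − k1²/2 + 7/240)/24,
    R0(x,z) = k1(x)k1(z),   R1(x,z) = k2(x)k2(z) − k4(|x−z|).

Binary variables use the two-level discrete space with contrast kernel
δ(x,z) − 1/2. Interaction spaces are tensor products with kernel
R̄_α(s,s′)·R̄_k(t,t′), R̄ = R0 + R1 (continuous) or δ − 1/2 (binary).

## Estimation

The fit minimizes a penalized pseudo log-likelihood: the normalizing
integral of e^η is replaced by a single integral of η against ρ, computed
once per observation by 25-node Gauss–Legendre quadrature (two-term sums for
a binary node). The constant ς has the closed-form profile
ς̂ = log{n⁻¹ Σ_i e^{−g(x_i)}}. The solution is approximated on a seeded
subset of q = min(n, ⌈10 n^{2/9}⌉) representers, giving

    g(x) = φᵀ(x) d + ξᵀ(x) c,

with φ the linear/binary contrasts and ξ aggregating kernel sections scaled
by main-effect parameters θ₁ and interaction parameters θ₂. Main effects
carry a quadratic roughness penalty (λ₁/2)cᵀQc; interactions carry an L1
budget wᵀθ₂ ≤ M with θ₂ ≥ 0, which both selects edges (coordinates leave the
budget exactly at zero) and is equivalent to an L1 penalty on the
interaction norms (penalty-form equivalence, verified in the test suite
against an independent free-block group-lasso solver).

Two steps alternate until the support, the budget and the relative change of
θ₂ stabilize:

1. **Newton–Raphson** in (c, d), with λ₁ selected from a 10-point log-spaced
   grid and θ₁ from the equal-trace heuristic (θ_j ∝ 1/tr Q_j) with one
   greedy refinement round on the first pass. Selection uses exact 5-fold
   cross-validation of the held-out pseudo-likelihood loss; a one-step
   leave-one-out approximation (ACV) is available as a cheaper option but
   understates optimism for very flexible fits, so the exact refit score is
   the default.
2. **Quadratic programming** in θ₂: sequential quadratic approximation of
   the convex reduced objective, each subproblem solved exactly by a primal
   active-set method over {θ₂ ≥ 0, wᵀθ₂ ≤ M} (an accelerated projected-
   gradient solver cross-checks it in the tests). M is chosen per iteration
   by 5-fold CV (coefficients refit per training fold so the held-out loss
   is honest) at the CV minimizer; a one-standard-error variant and a BIC
   criterion are available.

**Scale canonicalization.** The parametrization is invariant under
(c, θ) → (s·c, θ/s) except through the penalties, and without a scale
convention the alternation drifts along this ray (the roughness penalty
vanishes as θ grows). After every outer iteration the scales are
canonicalized to wᵀθ₂ = 1 (θ₁ and c rescaled consistently), making the CV
choice of λ₁ the single control of effective smoothness. The loop stops when
the relative θ₂ change falls below ε = 1e-3, or when the selected support
and budget have been stable for three consecutive iterations with relative
change below 5% — past that point the remaining motion is a slow joint
rescaling that leaves the fitted function and the selected edges unchanged.
Non-convergence within 20 iterations is flagged, not raised.

## Reference density

For a continuous node, ρ is a truncated normal on [0,1],
ρ(x_α) = φ((x_α−μ)/σ) / σ[Φ((1−μ)/σ) − Φ(−μ/σ)]. The default uses the
*marginal* member of this family — μ = mean(x_α), σ = SD(x_α), floored at
0.05 — so that ρ carries no information about the other variables and the
fitted interactions are exactly the interactions of the log conditional
density. This matters: if ρ is centered with a fitted conditional-mean
regression μ(x_∖α) (available as `reference="regression"`, with an additive
penalized-spline fit and GCV smoothing), any dependence acting through the
conditional mean is absorbed into ρ and the corresponding interactions of
g = log f − log ρ cancel, silently deleting exactly the edges the method is
supposed to find. The regression reference is therefore appropriate for
conditional density estimation per se, not for edge detection. For a binary
node ρ is the empirical frequency.

## Synthetic data

Four generators with known edge sets emulate common regimes at the study
scale p = 20, n ∈ {150, 300}:

- **gaussian** — N(0, Ω⁻¹) with Erdős–Rényi precision support (poff = 0.2 or
  0.4), entries ±U(0.5, 1), diagonal set to |λ_min| + 0.2. The resulting
  partial correlations are weak (≈0.15–0.3), which is what makes recovery at
  n = 150 hard.
- **skew_gaussian** — multivariate skew-normal
  f(x) = 2 φ_p(x; μ, Σ) Φ(aᵀ(x−μ)) with a ∈ {1, 4}, μ = 0.5·1, sampled
  exactly via the latent half-normal construction (δ = Σa/√(1+aᵀΣa)); the
  location-shifted form is used because the unshifted skewing factor does
  not integrate to one when aᵀμ ≠ 0. Truth is the support of Σ⁻¹.
- **dag** — random DAG with m ∈ {20, 40} edges; the 5-node Y block gets
  polynomial parent functions b₁t + b₂t² + b₃t³ with coefficient variances
  (1, 0.3, 0.1) (the printed duplicate quadratic term is read as a cubic;
  `cubic=False` restores two quadratics), the 15-node Z block linear N(0,1)
  functions; standard normal noise; truth is the skeleton.
- **gauss_bernoulli** — pairwise model on a ladder of m Gaussian and m
  Bernoulli nodes, couplings ±U(0.3, 0.6), node potentials −x²/2 (Gaussian)
  and 0 (Bernoulli), sampled by systematic-scan Gibbs (1000 burn-in sweeps,
  thinning 10).

These generators reproduce the *distributional* regimes (weak partial
correlations, skewness, non-linear parent effects, mixed types) but not the
features of real assay data — heavy-tailed technical noise, missingness,
batch structure — so passing recovery tests demonstrates correctness of the
machinery under the stated models, not field performance.

## Diagnostics

The squared-error projection distance
Ṽ(ĝ−g) = E[∫{(ĝ−g) − ∫(ĝ−g)ρ}² ρ dx_α], with the outer expectation taken
over the observed conditioning vectors (a product-quadrature alternative
exists for p ≤ 3), measures what a reduced model space misses: the ratio
Ṽ(ĝ−g̃)/Ṽ(ĝ−gu), with g̃ the projection onto the reduced space and
gu = −log ρ, is the contribution of the dropped components. Interaction
spaces split into linear-linear, linear-smooth, smooth-linear and
smooth-smooth blocks. Because the kernel blocks are RKHS-orthogonal but not
L2-orthogonal (the smooth space can approximate the linear contrast in L2),
both the block norms and the projection use the L2-orthogonalized split:
smooth factors have their k1 component removed, and the retained design is
projected onto the Ṽ-orthogonal complement of the dropped blocks. Squared
block norms then add exactly to the squared interaction norm, and a dropped
block cannot be re-expressed by the retained ones.

## Numerical choices

- Newton stops at sup-norm gradient 1e-7 (or at a numerical plateau below
  1e-4 when step halving stalls in the last floating-point digits); Hessians
  are jittered adaptively; divergent cross-validation refits (possible at
  the smallest grid λ₁) score +∞ rather than aborting.
- The active-set QP clamps coordinates exactly to zero; θ_{αk} > 1e-8 is the
  edge-presence threshold.
- Interaction norms are empirical L2 norms on a 41×41 Gauss–Legendre tensor
  grid (counting measure on {0,1} for binary coordinates); a 21-vs-201-node
  refinement check bounds the quadrature error.
- Penalty-form equivalence between the shared-representer θ parametrization
  and the free-block norm-penalized form holds exactly only up to the
  integral-functional representers that neither parametrization carries;
  the discrepancy scales like θ/λ₁ and the equivalence test asserts the
  1e-3 agreement in the penalty regimes where that residual is dominated.
- All randomness (representer subsets, CV folds, simulators) flows from
  explicit seeds; per-node seeds are spawned deterministically from a master
  seed so results do not depend on the worker count.

## Problem sizes

The test suite exercises graphs up to p = 5, n = 300 (ten seeds per
recovery property) and single-node fits up to n = 500; the acceptance
script runs the full pipeline at the study scale p = 20, n = 150 with three
replicates of the Gaussian scenario and one replicate of each other
scenario, which completes on a single CPU in well under an hour.

## Known limitations

- Sensitivity at p = 20, n = 150 on the Gaussian scenario is below the
  strongest published figures for this class of estimator: the AND-rule
  operating point here is more conservative (higher specificity, lower
  sensitivity). The directed estimates find most edges (OR-rule sensitivity
  ≈ 0.9–1.0); the loss happens at the intersection when the two directions
  disagree on weak edges.
- The pseudo-likelihood pays for its single-integral economy with some
  statistical inefficiency relative to the full likelihood; only the
  pseudo-likelihood route is implemented.
- Edge selection consistency and false-positive control are not calibrated:
  the CV-selected budget controls prediction risk, not the family-wise
  error of the selected edge set.
- Categorical variables with more than two levels are supported by the
  discrete kernel but not exercised by the simulators.
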
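"""Synthetic-data generators with known true edge sets.

Four scenarios exercise the structure learner end to end:

- ``simulate_gaussian``: N(0, Ω⁻¹) with a sparse Erdős–Rényi precision
  matrix (off-diagonal support probability ``poff``), made positive definite
  by diagonal dominance.
- ``simulate_skew_gaussian``: multivariate skew-normal
  f(x) = 2 φp(x; μ, Σ) Φ(aᵀ(x − μ)), sampled exactly by the latent
  half-normal construction; truth is the support of Σ⁻¹.
- ``simulate_dag``: directed acyclic graph with additive structural
  equations — linear parent functions for the Z block, cubic polynomial
  functions for the Y block — and standard normal noise; truth is the
  skeleton of the DAG.
- ``simulate_gauss_bernoulli``: pairwise Gaussian–Bernoulli model on a
  ladder graph sampled by systematic-scan Gibbs.

All generators are deterministic given a seed and return
``(raw data, true adjacency)``. Continuous outputs are on the original
scale; rescaling to [0, 1] happens in :class:`~splinegraph.data.Dataset`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _sparse_precision(p: int, poff: float, rng) -> np.ndarray:
    """Random sparse precision matrix: ER support, values ±U(0.5, 1),
    symmetrized, diagonal set to |λmin| + 0.2 to force positive definiteness."""
    if not 0.0 <= poff < 1.0:
        raise ValueError("poff must be in [0, 1)")
    omega = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    mask = rng.random(len(iu[0])) < poff
    vals = rng.uniform(0.5, 1.0, len(iu[0])) * rng.choice([-1.0, 1.0], len(iu[0]))
    omega[iu] = np.where(mask, vals, 0.0)
    omega = omega + omega.T
    lam_min = float(np.linalg.eigvalsh(omega).min())
    np.fill_diagonal(omega, abs(lam_min) + 0.2)
    return omega


def simulate_gaussian(p: int, n: int, poff: float, seed=None):
    """Multivariate Gaussian scenario. Returns (X, truth adjacency)."""
    rng = np.random.default_rng(seed)
    omega = _sparse_precision(p, poff, rng)
    cov = np.linalg.inv(omega)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    truth = (np.abs(omega) > 1e-12) & ~np.eye(p, dtype=bool)
    return X, truth


def skew_normal_delta(a: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """δ = Σa / sqrt(1 + aᵀΣa), the latent-correlation vector."""
    Sa = cov @ a
    return Sa / np.sqrt(1.0 + a @ Sa)


def simulate_skew_gaussian(p: int, n: int, a=1.0, mu=0.5, cov=None,
                           poff: float = 0.4, seed=None):
    """Multivariate skew-normal scenario, exact latent half-normal sampling.

    ``a`` scalar means slant vector a·1; ``mu`` scalar means location μ·1.
    ``cov`` defaults to the inverse of a random sparse precision matrix with
    off-diagonal support probability ``poff``. Truth is the support of Σ⁻¹.
    """
    rng = np.random.default_rng(seed)
    a_vec = np.full(p, float(a)) if np.isscalar(a) else np.asarray(a, float)
    mu_vec = np.full(p, float(mu)) if np.isscalar(mu) else np.asarray(mu, float)
    if cov is None:
        omega = _sparse_precision(p, poff, rng)
        cov = np.linalg.inv(omega)
    else:
        cov = np.asarray(cov, dtype=float)
        omega = np.linalg.inv(cov)
    delta = skew_normal_delta(a_vec, cov)
    resid_cov = cov - np.outer(delta, delta)
    z0 = np.abs(rng.standard_normal(n))
    W = rng.multivariate_normal(np.zeros(p), resid_cov, size=n,
                                method="eigh")
    X = mu_vec[None, :] + delta[None, :] * z0[:, None] + W
    truth = (np.abs(omega) > 1e-12) & ~np.eye(p, dtype=bool)
    return X, truth


def skew_normal_density(x, a, mu, cov):
    """Density 2 φp(x; μ, Σ) Φ(aᵀ(x − μ)) at rows of x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    p = x.shape[1]
    a_vec = np.full(p, float(a)) if np.isscalar(a) else np.asarray(a, float)
    mu_vec = np.full(p, float(mu)) if np.isscalar(mu) else np.asarray(mu, float)
    pdf = stats.multivariate_normal.pdf(x, mean=mu_vec, cov=cov)
    return 2.0 * pdf * stats.norm.cdf((x - mu_vec) @ a_vec)


def simulate_dag(p: int, m: int, n: int, seed=None, n_y: int = 5,
                 cubic: bool = True):
    """DAG scenario with additive structural equations.

    The first ``n_y`` nodes in topological order form the Y block whose
    parent functions are polynomials b1·t + b2·t² + b3·t³ with coefficient
    variances (1, 0.3, 0.1); the remaining Z block uses linear functions
    with N(0, 1) coefficients. ``cubic=False`` replaces the cubic term with
    a second quadratic term. Noise is standard normal. Returns
    (X, skeleton adjacency); columns are in node order (Y block first).
    """
    if m > p * (p - 1) // 2:
        raise ValueError("m exceeds the number of possible edges")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    chosen = rng.choice(len(pairs), size=m, replace=False) if m else []
    edges = [pairs[i] for i in np.atleast_1d(chosen)]
    X = np.zeros((n, p))
    truth = np.zeros((p, p), dtype=bool)
    funcs = {}
    for (i, j) in edges:  # i -> j in topological order
        truth[i, j] = truth[j, i] = True
        if j < n_y:
            b1 = rng.normal(0.0, 1.0)
            b2 = rng.normal(0.0, np.sqrt(0.3))
            b3 = rng.normal(0.0, np.sqrt(0.1))
            power = 3 if cubic else 2
            funcs[(i, j)] = lambda t, b1=b1, b2=b2, b3=b3, pw=power: (
                b1 * t + b2 * t**2 + b3 * t**pw
            )
        else:
            b1 = rng.normal(0.0, 1.0)
            funcs[(i, j)] = lambda t, b1=b1: b1 * t
    parents = {j: [i for (i, jj) in edges if jj == j] for j in range(p)}
    for j in range(p):
        col = rng.standard_normal(n)
        for i in parents[j]:
            col = col + funcs[(i, j)](X[:, i])
        X[:, j] = col
    return X, truth


def gibbs_conditional_mean(gamma: np.ndarray, x: np.ndarray, j: int) -> float:
    """Gaussian full-conditional mean Σ_k γ_jk x_k under the pairwise model."""
    return float(gamma[j] @ x - gamma[j, j] * x[j])


def simulate_gauss_bernoulli(m_half: int, n: int, seed=None,
                             burn_in: int = 1000, thin: int = 10):
    """Gaussian–Bernoulli ladder scenario sampled by Gibbs.

    Nodes 1..m are a Gaussian chain, nodes m+1..2m a Bernoulli chain, with
    rungs j ↔ j+m. Edge potentials are ±Unif(0.3, 0.6); node potentials are
    h_j(x) = −x²/2 for Gaussian nodes and 0 for Bernoulli nodes, so the
    Gaussian full conditionals are N(Σ_k γ_jk x_k, 1) and the Bernoulli
    conditionals are logistic. Returns (X, truth, gamma).
    """
    rng = np.random.default_rng(seed)
    m = m_half
    p = 2 * m
    truth = np.zeros((p, p), dtype=bool)
    for j in range(m - 1):
        truth[j, j + 1] = truth[j + 1, j] = True  # Gaussian chain
        truth[m + j, m + j + 1] = truth[m + j + 1, m + j] = True  # Bernoulli chain
    for j in range(m):
        truth[j, j + m] = truth[j + m, j] = True  # rungs
    gamma = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    for j, k in zip(*iu):
        if truth[j, k]:
            val = rng.uniform(0.3, 0.6) * rng.choice([-1.0, 1.0])
            gamma[j, k] = gamma[k, j] = val
    x = np.zeros(p)
    x[m:] = rng.integers(0, 2, m).astype(float)
    samples = np.zeros((n, p))
    total = burn_in + n * thin
    got = 0
    for sweep in range(total):
        for j in range(p):
            eta = gamma[j] @ x - gamma[j, j] * x[j]
            if j < m:
                x[j] = rng.normal(eta, 1.0)
            else:
                prob = 1.0 / (1.0 + np.exp(-eta))
                x[j] = float(rng.random() < prob)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0 and got < n:
            samples[got] = x
            got += 1
    kinds = ["continuous"] * m + ["binary"] * m
    return samples, truth, gamma, kinds


SCENARIOS = ("gaussian", "skew_gaussian", "dag", "gauss_bernoulli")


def simulate(scenario: str, p: int = 20, n: int = 150, seed=None, **kw):
    """Dispatch on scenario name; returns (X, truth, kinds)."""
    if scenario == "gaussian":
        X, truth = simulate_gaussian(p, n, kw.get("poff", 0.2), seed)
        return X, truth, ["continuous"] * p
    if scenario == "skew_gaussian":
        X, truth = simulate_skew_gaussian(
            p, n, a=kw.get("a", 1.0), mu=kw.get("mu", 0.5),
            poff=kw.get("poff", 0.4), seed=seed,
        )
        return X, truth, ["continuous"] * p
    if scenario == "dag":
        X, truth = simulate_dag(p, kw.get("m", 20), n, seed)
        return X, truth, ["continuous"] * p
    if scenario == "gauss_bernoulli":
        X, truth, _, kinds = simulate_gauss_bernoulli(
            kw.get("m_half", p // 2), n, seed,
            burn_in=kw.get("burn_in", 1000), thin=kw.get("thin", 10),
        )
        return X, truth, kinds
    raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
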
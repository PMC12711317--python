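"""Model space for one target node: basis, representers, kernel matrices.

For target node α the log conditional density (up to a constant) is modeled
in the space with all main effects and the two-way interactions that involve
α::

    g(x) = Σ_j η_j(x_j) + Σ_{k≠α} η_{αk}(x_α, x_k)

Each main effect splits into an unpenalized linear contrast (basis function
``k1``) and, for continuous variables, a penalized smooth part spanned by
representers of the cubic-spline kernel ``R1``. Interactions are spanned by
representers of the tensor-product kernel. The fitted estimate is

    g(x) = φᵀ(x) d + ξᵀ(x) c,

where ``ξ`` aggregates representer evaluations weighted by the scale
parameters θ1 (main effects) and θ2 (interactions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .data import BINARY, CONTINUOUS, Dataset

#: θ entries below this are treated as exact zeros (edge absent).
ACTIVE_TOL = 1e-8


def gauss_legendre_01(num: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights on [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(num)
    return 0.5 * (x + 1.0), 0.5 * w


def coordinate_rule(kind: str, num: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature rule for one coordinate (counting measure if binary)."""
    if kind == BINARY:
        return np.array([0.0, 1.0]), np.array([1.0, 1.0])
    return gauss_legendre_01(num)


@dataclass
class NodeModel:
    """Basis, representers and kernel matrices for target node α."""

    data: Dataset
    alpha: int
    representer_idx: np.ndarray
    weights: np.ndarray  # w_{αk}, entry α unused

    def __post_init__(self):
        self.representers = self.data.values[self.representer_idx]
        self.q = len(self.representer_idx)
        p = self.data.p
        self.m = p  # one linear contrast per variable
        self.continuous = [j for j in range(p) if self.data.kinds[j] == CONTINUOUS]
        # Main-effect kernel matrices (continuous variables only).
        self.Q_main = {
            j: kernels.gram(self.representers[:, j], kernels.cubic_R1)
            for j in self.continuous
        }
        # Interaction kernel matrices for every k ≠ α.
        self.Q_int = {}
        ka = self.data.kinds[self.alpha]
        ra = self.representers[:, self.alpha]
        Ka = kernels.marginal_kernel(ra[:, None], ra[None, :], ka)
        for k in range(p):
            if k == self.alpha:
                continue
            rk = self.representers[:, k]
            Kk = kernels.marginal_kernel(
                rk[:, None], rk[None, :], self.data.kinds[k]
            )
            self.Q_int[k] = Ka * Kk

    @property
    def p(self) -> int:
        return self.data.p

    # ---- evaluation helpers -------------------------------------------------

    def phi(self, X: np.ndarray) -> np.ndarray:
        """Unpenalized basis matrix: column j is ``k1(x_j)`` (n × m)."""
        return np.asarray(X, dtype=float) - 0.5

    def xi_main(self, X: np.ndarray, j: int) -> np.ndarray:
        """Representer matrix of main effect j: ``R1(x̃_uj, x_ij)`` (n × q)."""
        if j not in self.Q_main:
            raise ValueError(f"variable {j} has no penalized main effect")
        return kernels.cubic_R1(
            np.asarray(X, dtype=float)[:, j][:, None], self.representers[:, j][None, :]
        )

    def xi_interaction(self, X: np.ndarray, k: int) -> np.ndarray:
        """Representer matrix of interaction (α, k) at data rows (n × q)."""
        X = np.asarray(X, dtype=float)
        a = self.alpha
        ka = kernels.marginal_kernel(
            X[:, a][:, None], self.representers[:, a][None, :], self.data.kinds[a]
        )
        kk = kernels.marginal_kernel(
            X[:, k][:, None], self.representers[:, k][None, :], self.data.kinds[k]
        )
        return ka * kk

    def xi_interaction_grid(self, s: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
        """Interaction representers on a tensor grid: (len(s), len(t), q)."""
        a = self.alpha
        ka = kernels.marginal_kernel(
            np.asarray(s)[:, None], self.representers[:, a][None, :],
            self.data.kinds[a],
        )
        kk = kernels.marginal_kernel(
            np.asarray(t)[:, None], self.representers[:, k][None, :],
            self.data.kinds[k],
        )
        return ka[:, None, :] * kk[None, :, :]

    def assemble_Q(self, theta1: np.ndarray, theta2: np.ndarray) -> np.ndarray:
        """Penalty matrix Q = Σ_j θ_j Q_j + Σ_k w⁻¹ θ_{αk} Q_{αk}."""
        Q = np.zeros((self.q, self.q))
        for j in self.continuous:
            Q += theta1[j] * self.Q_main[j]
        for k, Qk in self.Q_int.items():
            if theta2[k] != 0.0:
                Q += theta2[k] / self.weights[k] * Qk
        return Q

    def xi_theta(self, X: np.ndarray, theta1, theta2) -> np.ndarray:
        """Aggregated representer matrix ξ(x)ᵀ rows at X (n × q)."""
        n = np.asarray(X).shape[0]
        out = np.zeros((n, self.q))
        for j in self.continuous:
            if theta1[j] != 0.0:
                out += theta1[j] * self.xi_main(X, j)
        for k in self.Q_int:
            if theta2[k] != 0.0:
                out += theta2[k] / self.weights[k] * self.xi_interaction(X, k)
        return out


@dataclass
class NodeFit:
    """Fitted coefficients and tuning parameters for one node."""

    c: np.ndarray
    d: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    lambda1: float
    M: float
    varsigma: float = 0.0
    converged: bool = True
    trace: list = field(default_factory=list)

    def active_interactions(self, tol: float = ACTIVE_TOL) -> list[int]:
        return [int(k) for k in np.nonzero(self.theta2 > tol)[0]]


def build_node_model(
    data: Dataset, alpha: int, q: int | None = None, seed=None, weights=None
) -> NodeModel:
    """Build the model space for node α with a seeded representer subset.

    The representer count defaults to ``min(n, ceil(10 n^{2/9}))``, the usual
    smoothing-spline scaling. With ``q = n`` the representers are all rows in
    original order.
    """
    if not 0 <= alpha < data.p:
        raise ValueError(f"alpha must be in [0, {data.p - 1}]")
    for j in range(data.p):
        if data.kinds[j] == CONTINUOUS and np.ptp(data.values[:, j]) < 1e-12:
            raise ValueError(f"column {data.columns[j]!r} is constant")
    n = data.n
    if q is None:
        q = default_q(n)
    if not 2 <= q <= n:
        raise ValueError("representer count q must satisfy 2 <= q <= n")
    if q == n:
        idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=q, replace=False))
    w = np.ones(data.p) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return NodeModel(data, alpha, idx, w)


def default_q(n: int) -> int:
    return int(min(n, np.ceil(10.0 * n ** (2.0 / 9.0))))


def eval_g(model: NodeModel, fit: NodeFit, X: np.ndarray) -> np.ndarray:
    """Evaluate ĝ(x) = φᵀ(x) d + ξᵀ(x) c at rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.phi(X) @ fit.d + model.xi_theta(X, fit.theta1, fit.theta2) @ fit.c


def eval_eta(model: NodeModel, fit: NodeFit, X: np.ndarray) -> np.ndarray:
    """Evaluate η̂ = ς̂ + ĝ at rows of X."""
    return fit.varsigma + eval_g(model, fit, X)


def decompose_g(model: NodeModel, fit: NodeFit, X: np.ndarray) -> dict:
    """Per-component values of the ANOVA decomposition at rows of X.

    Returns ``{"main": {j: values}, "interaction": {k: values}}``; the
    components sum pointwise to ``eval_g``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phi = model.phi(X)
    main = {}
    for j in range(model.p):
        vals = phi[:, j] * fit.d[j]
        if j in model.Q_main and fit.theta1[j] != 0.0:
            vals = vals + fit.theta1[j] * (model.xi_main(X, j) @ fit.c)
        main[j] = vals
    inter = {}
    for k in model.Q_int:
        if fit.theta2[k] != 0.0:
            inter[k] = (
                fit.theta2[k] / model.weights[k]
                * (model.xi_interaction(X, k) @ fit.c)
            )
        else:
            inter[k] = np.zeros(X.shape[0])
    return {"main": main, "interaction": inter}


def eval_main_effect(model: NodeModel, fit: NodeFit, j: int, grid: np.ndarray):
    """Main-effect curve η̂_j on a grid of x_j values."""
    grid = np.asarray(grid, dtype=float)
    vals = (grid - 0.5) * fit.d[j]
    if j in model.Q_main and fit.theta1[j] != 0.0:
        R = kernels.cubic_R1(grid[:, None], model.representers[:, j][None, :])
        vals = vals + fit.theta1[j] * (R @ fit.c)
    return vals


def interaction_surface(
    model: NodeModel, fit: NodeFit, k: int, s: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """η̂_{αk} on the tensor grid s × t (s indexes x_α, t indexes x_k)."""
    scale = fit.theta2[k] / model.weights[k]
    if scale == 0.0:
        return np.zeros((len(s), len(t)))
    Xi = model.xi_interaction_grid(np.asarray(s), np.asarray(t), k)
    return scale * (Xi @ fit.c)


def interaction_norm(
    model: NodeModel, fit: NodeFit, k: int, n_grid: int = 41
) -> float:
    """Empirical L2 norm of η̂_{αk} over a tensor quadrature grid.

    Continuous coordinates use Gauss-Legendre nodes on [0, 1]; binary
    coordinates use the counting measure on {0, 1}. Returns exactly 0 when
    θ_{αk} = 0 or c = 0.
    """
    if fit.theta2[k] <= ACTIVE_TOL or not np.any(fit.c):
        return 0.0
    s, ws = coordinate_rule(model.data.kinds[model.alpha], n_grid)
    t, wt = coordinate_rule(model.data.kinds[k], n_grid)
    surf = interaction_surface(model, fit, k, s, t)
    return float(np.sqrt(np.einsum("a,b,ab->", ws, wt, surf**2)))
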
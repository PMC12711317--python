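"""Reference conditional density ρ and the quadrature machinery.

The pseudo log-likelihood replaces the normalizing integral of ``e^η`` with
a single integral of ``η`` against a *known* reference density ρ of x_α
given x_{∖α}. For a continuous node ρ is a truncated normal on [0, 1]::

    ρ(x_α | x_{∖α}) = φ((x_α − μ(x_{∖α}))/σ) /
                      σ [Φ((1 − μ)/σ) − Φ((−μ)/σ)]

with μ(·) an additive penalized-spline regression of x_α on the remaining
variables (GCV-selected smoothness) and σ the residual standard deviation
(floored to avoid degenerate spikes). For a binary node ρ is the empirical
marginal frequency and all integrals become two-term sums.

Correctness of the estimator only requires ρ to be a fixed positive density,
so the regression need not be optimal; it just centers the reference mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import kernels
from .data import BINARY, CONTINUOUS, Dataset
from .model_space import NodeModel, coordinate_rule

SIGMA_FLOOR = 0.05


@dataclass
class QuadratureRule:
    """Nodes and weights for integrals over the target coordinate."""

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def for_node(cls, data: Dataset, alpha: int, num: int = 25) -> "QuadratureRule":
        nodes, weights = coordinate_rule(data.kinds[alpha], num)
        return cls(nodes, weights)


class ReferenceDensity:
    """Truncated-normal (or empirical-frequency) reference density for node α."""

    def __init__(self, data: Dataset, alpha: int, mu_model=None, sigma=None,
                 freq=None):
        self.alpha = alpha
        self.kind = data.kinds[alpha]
        self._mu_model = mu_model
        self.sigma = sigma
        self.freq = freq  # P(x_α = 1) for a binary node

    # -- evaluation -----------------------------------------------------------

    def mu(self, X: np.ndarray) -> np.ndarray:
        """Reference mean μ(x_{∖α}) at full p-column rows (α column ignored)."""
        if self.kind == BINARY:
            raise ValueError("binary reference has no mean function")
        return self._mu_model.predict(np.atleast_2d(X))

    def density_on_nodes(self, X: np.ndarray, rule: QuadratureRule,
                         renormalize: bool = True) -> np.ndarray:
        """ρ(node | x_{i,∖α}) for each row i and quadrature node (n × #nodes).

        With ``renormalize`` the values are scaled so that the rule integrates
        each row's density exactly to 1.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == BINARY:
            vals = np.tile(np.array([1.0 - self.freq, self.freq]), (X.shape[0], 1))
        else:
            m = self.mu(X)[:, None]
            s = self.sigma
            z = (rule.nodes[None, :] - m) / s
            denom = stats.norm.cdf((1.0 - m) / s) - stats.norm.cdf(-m / s)
            vals = stats.norm.pdf(z) / (s * denom)
        if renormalize:
            vals = vals / (vals @ rule.weights)[:, None]
        return vals


class _AdditiveSplineRegression:
    """Additive cubic-spline ridge regression with GCV smoothing selection.

    Model: y ≈ b0 + Σ_j d_j k1(x_j) + smooth part spanned by representers of
    the summed main-effect kernel Σ_j R1. Used only to center the reference
    density.
    """

    def __init__(self, max_representers: int = 60,
                 lambdas=np.logspace(-9, 0, 13)):
        self.max_representers = max_representers
        self.lambdas = lambdas

    def fit(self, X: np.ndarray, y: np.ndarray, cont_cols, bin_cols, seed=None):
        n = X.shape[0]
        if np.ptp(y) < 1e-12:
            raise ValueError("degenerate response in reference regression")
        self.cont_cols = list(cont_cols)
        self.bin_cols = list(bin_cols)
        r = min(n, self.max_representers)
        if r == n:
            idx = np.arange(n)
        else:
            idx = np.sort(np.random.default_rng(seed).choice(n, r, replace=False))
        self.rep = X[idx]
        T = self._linear_design(X)
        K = self._kernel_cross(X)
        Krr = K[idx]
        Z = np.column_stack([T, K])
        B = Z.T @ Z
        Zty = Z.T @ y
        mt = T.shape[1]
        P = np.zeros_like(B)
        P[mt:, mt:] = Krr + 1e-10 * np.eye(r)
        best = (np.inf, None, None)
        for lam in self.lambdas:
            A = B + n * lam * P + 1e-12 * np.eye(B.shape[0])
            try:
                coef = np.linalg.solve(A, Zty)
            except np.linalg.LinAlgError:
                continue
            resid = y - Z @ coef
            tr_h = np.trace(np.linalg.solve(A, B))
            denom = max(n - tr_h, 1e-8)
            gcv = n * float(resid @ resid) / denom**2
            if gcv < best[0]:
                best = (gcv, coef, lam)
        self.coef_ = best[1]
        self.lambda_ = best[2]
        return self

    def _linear_design(self, X):
        cols = [np.ones(X.shape[0])]
        for j in self.cont_cols + self.bin_cols:
            cols.append(X[:, j] - 0.5)
        return np.column_stack(cols)

    def _kernel_cross(self, X):
        K = np.zeros((X.shape[0], self.rep.shape[0]))
        for j in self.cont_cols:
            K += kernels.cubic_R1(X[:, j][:, None], self.rep[:, j][None, :])
        return K

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = np.column_stack([self._linear_design(X), self._kernel_cross(X)])
        return Z @ self.coef_


class _ConstantMean:
    """Intercept-only mean model for the marginal reference."""

    def __init__(self, value: float):
        self.value = value

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.atleast_2d(X).shape[0], self.value)


def fit_reference(data: Dataset, alpha: int, seed=None,
                  mode: str = "marginal") -> ReferenceDensity:
    """Fit the reference density ρ for node α.

    Continuous node: truncated normal on [0, 1]. The default ``marginal``
    mode uses the intercept-only member of the family — μ = mean(x_α),
    σ = SD(x_α) — so that ρ carries no neighbor structure and the estimated
    interactions are exactly those of the log conditional density (the edge
    signal). ``mode="regression"`` instead centers ρ with the additive-
    spline conditional-mean fit and residual SD; this sharpens the reference
    but absorbs any dependence acting through the conditional mean, which
    cancels the corresponding interactions — useful for conditional density
    estimation per se, not for edge detection. σ is floored at 0.05 in both
    modes. Binary node: empirical marginal frequency (clipped away from
    0 and 1).
    """
    if data.n < 10:
        raise ValueError("need at least 10 observations to fit the reference")
    y = data.values[:, alpha]
    if data.kinds[alpha] == BINARY:
        freq = float(np.clip(y.mean(), 1.0 / (2 * data.n), 1 - 1.0 / (2 * data.n)))
        return ReferenceDensity(data, alpha, freq=freq)
    if mode == "marginal":
        sigma = max(float(np.std(y)), SIGMA_FLOOR)
        return ReferenceDensity(
            data, alpha, mu_model=_ConstantMean(float(y.mean())), sigma=sigma
        )
    if mode != "regression":
        raise ValueError("mode must be 'marginal' or 'regression'")
    others = [j for j in range(data.p) if j != alpha]
    cont = [j for j in others if data.kinds[j] == CONTINUOUS]
    bins = [j for j in others if data.kinds[j] == BINARY]
    reg = _AdditiveSplineRegression().fit(data.values, y, cont, bins, seed=seed)
    resid = y - reg.predict(data.values)
    sigma = max(float(np.std(resid)), SIGMA_FLOOR)
    return ReferenceDensity(data, alpha, mu_model=reg, sigma=sigma)


def integrate_against_rho(f, rho: ReferenceDensity, x_cond: np.ndarray,
                          rule: QuadratureRule) -> float:
    """∫ f(x_α) ρ(x_α | x_cond) dx_α by quadrature (ρ renormalized on the rule)."""
    dens = rho.density_on_nodes(np.atleast_2d(x_cond), rule)[0]
    return float(np.sum(rule.weights * dens * f(rule.nodes)))


class BCache:
    """Cached per-observation integrals of basis and representer functions.

    The pseudo log-likelihood needs ``b_φ = n⁻¹ Σ_i ∫ φ(x_i^α) ρ dx_α`` and the
    matching representer integrals. Every component's integral is stored once
    per observation so ``b_ξ`` re-assembles under new θ without re-integration.
    """

    def __init__(self, model: NodeModel, rho: ReferenceDensity,
                 rule: QuadratureRule):
        self.model = model
        self.rule = rule
        data = model.data
        X = data.values
        n, a = data.n, model.alpha
        self.rho_nodes = rho.density_on_nodes(X, rule)  # n × #nodes
        wr = rule.weights[None, :] * self.rho_nodes  # quadrature × density
        # φ integrals: columns j ≠ α are unchanged evaluations, column α is
        # the integral of k1 against ρ_i.
        self.phi_b = model.phi(X).copy()
        self.phi_b[:, a] = wr @ (rule.nodes - 0.5)
        # main-effect representer integrals (continuous j only)
        self.main_b = {}
        for j in model.continuous:
            if j == a:
                Rg = kernels.cubic_R1(
                    rule.nodes[:, None], model.representers[:, a][None, :]
                )
                self.main_b[j] = wr @ Rg
            else:
                self.main_b[j] = model.xi_main(X, j)
        # interaction representer integrals: the α factor is integrated, the
        # k factor is evaluated at the observation.
        Rg_full = kernels.marginal_kernel(
            rule.nodes[:, None], model.representers[:, a][None, :],
            data.kinds[a],
        )
        A = wr @ Rg_full  # n × q, ∫ R̄_α(x̃_uα, ·) ρ_i
        self.int_b = {}
        for k in model.Q_int:
            Ck = kernels.marginal_kernel(
                X[:, k][:, None], model.representers[:, k][None, :],
                data.kinds[k],
            )
            self.int_b[k] = A * Ck
        self.phi_mean = self.phi_b.mean(axis=0)
        self.main_mean = {j: v.mean(axis=0) for j, v in self.main_b.items()}
        self.int_mean = {k: v.mean(axis=0) for k, v in self.int_b.items()}

    def b_xi(self, theta1, theta2) -> np.ndarray:
        """Assembled b_ξ = Σ_j θ_j (main part)_j + Σ_k w⁻¹ θ_{αk} (int part)_k."""
        out = np.zeros(self.model.q)
        for j, v in self.main_mean.items():
            if theta1[j] != 0.0:
                out += theta1[j] * v
        for k, v in self.int_mean.items():
            if theta2[k] != 0.0:
                out += theta2[k] / self.model.weights[k] * v
        return out

    def b_xi_rows(self, theta1, theta2) -> np.ndarray:
        """Per-observation b_ξ rows (n × q), for leave-one-out scores."""
        out = np.zeros((self.model.data.n, self.model.q))
        for j, v in self.main_b.items():
            if theta1[j] != 0.0:
                out += theta1[j] * v
        for k, v in self.int_b.items():
            if theta2[k] != 0.0:
                out += theta2[k] / self.model.weights[k] * v
        return out

    def b_psi2(self, c: np.ndarray) -> np.ndarray:
        """Interaction block of the integrals with θ2 factored out (length p)."""
        out = np.zeros(self.model.p)
        for k, v in self.int_mean.items():
            out[k] = (v @ c) / self.model.weights[k]
        return out
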
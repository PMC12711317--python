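"""Squared-error projection diagnostics for fitted conditional densities.

The diagnostic distance between the fitted ĝ and any candidate g is::

    Ṽ(ĝ − g) = E_{x_{∖α}} ∫ {(ĝ − g)(x) − ∫ (ĝ − g)(x) ρ dx_α}² ρ(x) dx_α

with the outer expectation realized as the empirical average over observed
conditioning vectors (a product-quadrature alternative is available for
small p). Projecting ĝ onto a reduced model space M0 (e.g. the space a
parametric method implicitly assumes) gives g̃, and the ratio
Ṽ(ĝ − g̃) / Ṽ(ĝ − gu) with gu = −log ρ measures the contribution of the
dropped components: a large ratio means the reduced model misses real
structure.

Interaction spaces decompose into linear-linear, linear-smooth,
smooth-linear and smooth-smooth blocks. Block norms here use the
L2-orthogonalized tensor split (project each coordinate onto its linear
contrast, remainder is the smooth part), so squared block norms add exactly
to the squared interaction norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_space import (
    NodeFit,
    NodeModel,
    coordinate_rule,
    eval_g,
    gauss_legendre_01,
    interaction_surface,
)
from .reference import QuadratureRule, ReferenceDensity

BLOCK_NAMES = {0: "linear-linear", 1: "linear-smooth",
               2: "smooth-linear", 3: "smooth-smooth"}


@dataclass
class ProjectionReport:
    """Result of a squared-error projection onto a reduced subspace."""

    dropped: dict
    V_num: float  # Ṽ(ĝ − g̃)
    V_den: float  # Ṽ(ĝ − gu)
    ratio: float
    pythagorean_residual: float | None = None
    notes: list = field(default_factory=list)


def _ensure_rule(model, rule):
    return rule or QuadratureRule.for_node(model.data, model.alpha, 25)


def _conditioning_points(model, points, n_grid=7):
    """Rows of conditioning vectors for the outer average."""
    if isinstance(points, np.ndarray):
        return points
    if points == "data":
        return model.data.values
    if points == "grid":
        if model.p > 3:
            raise ValueError("product-quadrature outer integral needs p <= 3")
        axes = []
        for j in range(model.p):
            if j == model.alpha:
                axes.append(np.array([0.0]))  # overwritten by the rule
            else:
                axes.append(model.data.column_grid(j, n_grid))
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])
    raise ValueError("points must be 'data', 'grid', or an array")


class _VtildeSpace:
    """Discretization of the Ṽ quadratic form and the retained design."""

    def __init__(self, model: NodeModel, fit: NodeFit, rho: ReferenceDensity,
                 rule: QuadratureRule, points="data"):
        self.model = model
        self.fit = fit
        cond = _conditioning_points(model, points)
        self.n_outer = cond.shape[0]
        nodes = rule.nodes
        self.n_nodes = len(nodes)
        dens = rho.density_on_nodes(cond, rule)  # n_outer × nodes
        self.w = rule.weights[None, :] * dens  # rows sum to 1
        self.log_rho = np.log(np.maximum(dens, 1e-300))
        # evaluation points: outer row i with α set to each node
        reps = np.repeat(cond, self.n_nodes, axis=0)
        reps[:, model.alpha] = np.tile(nodes, self.n_outer)
        self.X_eval = reps
        self.nodes = nodes

    def center(self, vals: np.ndarray) -> np.ndarray:
        """Remove the ρ-mean over x_α within each outer row."""
        V = vals.reshape(self.n_outer, self.n_nodes, -1)
        mean = np.einsum("ia,iab->ib", self.w, V)
        return (V - mean[:, None, :]).reshape(vals.shape)

    def quad_form(self, vals: np.ndarray) -> float:
        """Ṽ of a function given its (centered or raw) values."""
        c = self.center(vals[:, None])[:, 0]
        W = self.w.reshape(-1) / self.n_outer
        return float(np.sum(W * c * c))

    def inner(self, u: np.ndarray, v: np.ndarray) -> float:
        cu = self.center(u[:, None])[:, 0]
        cv = self.center(v[:, None])[:, 0]
        W = self.w.reshape(-1) / self.n_outer
        return float(np.sum(W * cu * cv))


def _smooth_k1_coefficients(reps: np.ndarray) -> np.ndarray:
    """L2[0,1] component of each smooth section R1(x̃_u, ·) along k1.

    γ_u = ⟨R1(x̃_u, ·), k1⟩ / ⟨k1, k1⟩ computed by Gauss-Legendre quadrature;
    subtracting γ_u·k1 makes the smooth factor L2-orthogonal to the linear
    contrast, so tensor blocks are genuinely disjoint in the geometry the
    diagnostic distance measures.
    """
    from . import kernels

    s, w = gauss_legendre_01(64)
    R = kernels.cubic_R1(s[:, None], reps[None, :])  # nodes × q
    k1s = kernels.k1(s)
    return (w * k1s) @ R / np.sum(w * k1s * k1s)


def _factor_parts(x, reps, kind):
    """Linear-contrast and (k1-orthogonalized) smooth factor matrices."""
    from . import kernels

    if kind != "continuous":
        lin = kernels.binary_kernel(x[:, None], reps[None, :])
        return lin, np.zeros((len(x), len(reps)))
    lin = kernels.k1(x)[:, None] * kernels.k1(reps)[None, :]
    smooth = kernels.cubic_R1(x[:, None], reps[None, :])
    gamma = _smooth_k1_coefficients(reps)
    smooth = smooth - np.outer(kernels.k1(x), gamma)
    return lin, smooth


def _retained_design(space: _VtildeSpace, drop: dict):
    """Retained and dropped design columns, evaluated at the Ṽ points.

    Only x_α-dependent functions matter (the Ṽ centering annihilates the
    rest): the α linear contrast, the α smooth main effect, and each
    interaction's tensor blocks (smooth factors L2-orthogonalized against
    the linear contrast). Returns (retained, dropped) column stacks; the
    caller removes the dropped span from the retained columns in the Ṽ
    geometry, so a dropped block cannot be re-expressed by the rest.
    """
    from . import kernels

    model = space.model
    a = model.alpha
    X = space.X_eval
    cols = [X[:, a] - 0.5]
    if a in model.Q_main:
        cols.append(
            kernels.cubic_R1(X[:, a][:, None], model.representers[:, a][None, :])
        )
    kind_a = model.data.kinds[a]
    dropped_cols = []

    for k in model.Q_int:
        dropped = set(drop.get(k, ()))
        ra, rk = model.representers[:, a], model.representers[:, k]
        la, sa = _factor_parts(X[:, a], ra, kind_a)
        lk, sk = _factor_parts(X[:, k], rk, model.data.kinds[k])
        blocks = {0: la * lk, 1: la * sk, 2: sa * lk, 3: sa * sk}
        for bi, B in blocks.items():
            if not np.any(B):
                continue
            (dropped_cols if bi in dropped else cols).append(B)

    def stack(lst):
        if not lst:
            return None
        return np.column_stack([c if c.ndim == 2 else c[:, None] for c in lst])

    return stack(cols), stack(dropped_cols)


def project(
    model: NodeModel,
    fit: NodeFit,
    rho: ReferenceDensity,
    drop: dict | None = None,
    rule: QuadratureRule | None = None,
    points="data",
) -> ProjectionReport:
    """Squared-error projection of ĝ onto a reduced subspace.

    ``drop`` maps an interaction coordinate k to the block indices (0..3)
    removed from the retained space; everything else is kept. Returns the
    contribution ratio Ṽ(ĝ − g̃) / Ṽ(ĝ − gu) of the dropped components.
    """
    drop = drop or {}
    rule = _ensure_rule(model, rule)
    space = _VtildeSpace(model, fit, rho, rule, points)
    g_hat = eval_g(model, fit, space.X_eval)
    gu = -space.log_rho.reshape(-1)

    D, D_drop = _retained_design(space, drop)
    Dc = space.center(D)
    W = (space.w.reshape(-1) / space.n_outer)[:, None]
    sqw = np.sqrt(W)
    target = space.center(g_hat[:, None])[:, 0]
    A = Dc * sqw
    if D_drop is not None:
        # retained space = Ṽ-orthogonal complement of the dropped blocks:
        # remove the dropped span from the retained columns
        A_drop = space.center(D_drop) * sqw
        proj, *_ = np.linalg.lstsq(A_drop, A, rcond=1e-10)
        A = A - A_drop @ proj
    coef, *_ = np.linalg.lstsq(A, target * sqw[:, 0], rcond=1e-10)
    g_tilde = A @ coef / sqw[:, 0]

    resid = target - g_tilde
    V_num = float(np.sum(W[:, 0] * resid**2))
    gu_c = space.center(gu[:, None])[:, 0]
    V_den = float(np.sum(W[:, 0] * (target - gu_c) ** 2))
    ratio = 0.0 if V_den <= 1e-300 else V_num / V_den
    report = ProjectionReport(dropped=drop, V_num=V_num, V_den=V_den, ratio=ratio)

    # Pythagorean identity holds when gu lies in the retained space
    coef_u, *_ = np.linalg.lstsq(A, gu_c * sqw[:, 0], rcond=1e-10)
    gu_res = float(np.sum(W[:, 0] * (gu_c - Dc @ coef_u) ** 2))
    if gu_res < 1e-8 * max(V_den, 1e-12):
        V_mid = float(np.sum(W[:, 0] * (g_tilde - gu_c) ** 2))
        report.pythagorean_residual = abs(V_den - V_num - V_mid)
    else:
        report.notes.append("gu outside retained space; identity skipped")
    return report


def interaction_blocks(
    model: NodeModel, fit: NodeFit, k: int, n_grid: int = 41
) -> dict[int, float]:
    """Per-block L2 norms of η̂_{αk} under the orthogonal tensor split.

    Returns {0: linear-linear, 1: linear-smooth, 2: smooth-linear,
    3: smooth-smooth}; the squared norms sum to ‖η̂_{αk}‖².
    """
    s, ws = coordinate_rule(model.data.kinds[model.alpha], n_grid)
    t, wt = coordinate_rule(model.data.kinds[k], n_grid)
    F = interaction_surface(model, fit, k, s, t)

    def split(axis_vals, axis_w):
        e1 = axis_vals - 0.5
        nrm = np.sqrt(np.sum(axis_w * e1 * e1))
        e1 = e1 / max(nrm, 1e-300)
        e0 = np.ones_like(axis_vals) / np.sqrt(np.sum(axis_w))
        return e0, e1

    e0s, e1s = split(s, ws)
    e0t, e1t = split(t, wt)

    def proj_axis0(G, e):
        coef = np.einsum("a,a,ab->b", ws, e, G)
        return np.outer(e, coef)

    def proj_axis1(G, e):
        coef = np.einsum("b,b,ab->a", wt, e, G)
        return np.outer(coef, e)

    # strip constants (should already be ~0 by construction)
    F = F - proj_axis0(F, e0s)
    F = F - proj_axis1(F, e0t)
    lin_s = proj_axis0(F, e1s)
    smooth_s = F - lin_s
    blocks = {
        0: proj_axis1(lin_s, e1t),
        2: proj_axis1(smooth_s, e1t),
    }
    blocks[1] = lin_s - blocks[0]
    blocks[3] = smooth_s - blocks[2]
    return {
        bi: float(np.sqrt(np.einsum("a,b,ab->", ws, wt, B**2)))
        for bi, B in blocks.items()
    }


def write_block_report(model, fit, path, n_grid: int = 41) -> None:
    """Per-pair TSV of interaction norms and block norms (1-based nodes)."""
    lines = ["node_a\tnode_b\ttotal\tlin_lin\tlin_smooth\tsmooth_lin\tsmooth_smooth"]
    from .model_space import interaction_norm

    for k in sorted(model.Q_int):
        total = interaction_norm(model, fit, k, n_grid)
        b = interaction_blocks(model, fit, k, n_grid)
        lines.append(
            f"{model.alpha + 1}\t{k + 1}\t{total:.12g}\t{b[0]:.12g}\t{b[1]:.12g}"
            f"\t{b[2]:.12g}\t{b[3]:.12g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
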
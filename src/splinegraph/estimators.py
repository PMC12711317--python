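"""Scikit-learn style estimators wrapping the neighborhood selection engine."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .data import Dataset
from .fitter import NodeFitConfig, conditional_density, fit_node
from .graph import fit_graph
from .model_space import interaction_norm


def _config_from(est, seed) -> NodeFitConfig:
    return NodeFitConfig(
        q=est.q,
        n_quad=est.n_quad,
        epsilon=est.epsilon,
        max_iter=est.max_iter,
        lambda1_grid=est.lambda1_grid,
        refine_theta1=est.refine_theta1,
        n_M=est.n_M,
        folds=est.folds,
        criterion=est.criterion,
        seed=seed,
    )


class NeighborhoodGraphEstimator(BaseEstimator):
    """Undirected graph structure learner for mixed continuous/binary data.

    Estimates each node's conditional density nonparametrically in a
    smoothing-spline ANOVA space with an L1 budget on interaction scales,
    then combines the p directed neighborhood estimates into an undirected
    graph with the AND (default) or OR rule.

    Parameters
    ----------
    rule : {"and", "or"}
        Edge combination rule.
    criterion : {"cv", "bic"}
        Selector for the sparsity budget M.
    q : int or None
        Representer count; defaults to min(n, ceil(10 n^{2/9})).
    n_jobs : int
        Independent node fits may run in parallel.
    random_state : int or None
        Master seed; per-node seeds are spawned deterministically.

    Attributes
    ----------
    norms_ : ndarray of shape (p, p)
        Directed interaction norms ‖η̂_{αk}‖.
    adjacency_ : ndarray of bool, shape (p, p)
        Undirected adjacency under the chosen rule.
    graph_ : GraphEstimate
        Full estimate (both rules, θ2 matrix, convergence flags).
    """

    def __init__(self, rule="and", criterion="cv", q=None, n_quad=25,
                 epsilon=1e-3, max_iter=20, lambda1_grid=None,
                 refine_theta1=True, n_M=15, folds=5, n_jobs=1,
                 random_state=None):
        self.rule = rule
        self.criterion = criterion
        self.q = q
        self.n_quad = n_quad
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.lambda1_grid = lambda1_grid
        self.refine_theta1 = refine_theta1
        self.n_M = n_M
        self.folds = folds
        self.n_jobs = n_jobs
        self.random_state = random_state

    def fit(self, X, y=None, kinds=None):
        """Fit all neighborhoods. X is raw data (rescaled internally)."""
        if isinstance(X, Dataset):
            data = X
        else:
            X = check_array(X, ensure_min_features=2)
            data = Dataset.from_array(X, kinds)
        config = _config_from(self, self.random_state)
        self.graph_ = fit_graph(data, config, n_jobs=self.n_jobs)
        self.norms_ = self.graph_.norms
        self.adjacency_ = self.graph_.adjacency(self.rule)
        self.n_features_in_ = data.p
        return self

    def edges(self):
        check_is_fitted(self, "graph_")
        return self.graph_.edges(self.rule)


class NodeConditionalDensity(BaseEstimator):
    """Nonparametric conditional density estimator for a single node.

    Fits f(x_α | x_{∖α}) ∝ e^{ĝ} ρ with ĝ in the SS ANOVA space of main
    effects plus pairwise interactions involving α, the interactions under
    an L1 sparsity budget. Useful on its own for variable selection in
    conditional density estimation.
    """

    def __init__(self, alpha=0, criterion="cv", q=None, n_quad=25,
                 epsilon=1e-3, max_iter=20, lambda1_grid=None,
                 refine_theta1=True, n_M=15, folds=5, random_state=None):
        self.alpha = alpha
        self.criterion = criterion
        self.q = q
        self.n_quad = n_quad
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.lambda1_grid = lambda1_grid
        self.refine_theta1 = refine_theta1
        self.n_M = n_M
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y=None, kinds=None):
        if isinstance(X, Dataset):
            data = X
        else:
            X = check_array(X, ensure_min_features=2)
            data = Dataset.from_array(X, kinds)
        config = _config_from(self, self.random_state)
        self.model_, self.fit_ = fit_node(data, self.alpha, config)
        self.data_ = data
        self.theta2_ = self.fit_.theta2
        self.neighbors_ = self.fit_.active_interactions()
        self.n_features_in_ = data.p
        return self

    def interaction_norms(self):
        check_is_fitted(self, "fit_")
        return {
            k: interaction_norm(self.model_, self.fit_, k)
            for k in self.model_.Q_int
        }

    def predict_density(self, x_cond):
        """Conditional density on a grid given one conditioning vector
        (on the rescaled [0, 1] / {0, 1} domain)."""
        check_is_fitted(self, "fit_")
        return conditional_density(
            self.model_, self.fit_, self.fit_._rho, np.asarray(x_cond)
        )
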
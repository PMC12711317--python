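"""Graph assembly: per-node fits, AND/OR combination, scoring, writers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .data import Dataset
from .fitter import NodeFitConfig, fit_node
from .model_space import ACTIVE_TOL, interaction_norm


@dataclass
class GraphEstimate:
    """Ordered-pair interaction norms and the combined undirected graph.

    ``norms[a, k]`` is the empirical L2 norm of η̂_{αk} from node a's fit
    (0 when θ_{αk} = 0). The AND rule keeps edge {a, k} when both directed
    estimates are nonzero; OR keeps it when either is.
    """

    p: int
    norms: np.ndarray
    theta2: np.ndarray
    converged: np.ndarray
    columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.columns:
            self.columns = [f"x{j + 1}" for j in range(self.p)]

    @property
    def directed(self) -> np.ndarray:
        return self.theta2 > ACTIVE_TOL

    def adjacency(self, rule: str = "and") -> np.ndarray:
        D = self.directed
        if rule.lower() == "and":
            A = D & D.T
        elif rule.lower() == "or":
            A = D | D.T
        else:
            raise ValueError("rule must be 'and' or 'or'")
        A = A.copy()
        np.fill_diagonal(A, False)
        return A

    def edges(self, rule: str = "and") -> list[tuple[int, int]]:
        A = self.adjacency(rule)
        return [(a, k) for a in range(self.p) for k in range(a + 1, self.p) if A[a, k]]


@dataclass
class ConfusionMetrics:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def SPE(self) -> float:
        return self.TN / (self.TN + self.FP) if (self.TN + self.FP) else 1.0

    @property
    def SEN(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 1.0

    @property
    def F1(self) -> float:
        denom = 2 * self.TP + self.FN + self.FP
        return 2 * self.TP / denom if denom else 1.0

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "SPE": self.SPE, "SEN": self.SEN, "F1": self.F1,
        }


def node_seeds(master_seed, p: int) -> list[int]:
    """Deterministic per-node child seeds from a master seed.

    Derived once from the master so the worker count never changes results.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(p)]


def fit_graph(
    data: Dataset,
    config: NodeFitConfig | None = None,
    nodes=None,
    n_jobs: int = 1,
) -> GraphEstimate:
    """Fit all neighborhoods and assemble the interaction-norm matrix.

    Node fits share no mutable state and run independently (optionally in
    parallel); per-node seeds are spawned deterministically from the config
    seed.
    """
    config = config or NodeFitConfig()
    p = data.p
    nodes = list(range(p)) if nodes is None else list(nodes)
    seeds = node_seeds(config.seed, p)

    def one(alpha):
        model, fit = fit_node(data, alpha, replace(config, seed=seeds[alpha]))
        norms = np.zeros(p)
        for k in model.Q_int:
            norms[k] = interaction_norm(model, fit, k)
        return alpha, norms, fit.theta2, fit.converged

    if n_jobs == 1:
        results = [one(a) for a in nodes]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(one)(a) for a in nodes)

    norms = np.zeros((p, p))
    theta2 = np.zeros((p, p))
    converged = np.ones(p, dtype=bool)
    for alpha, nrm, th2, conv in results:
        norms[alpha] = nrm
        theta2[alpha] = th2
        converged[alpha] = conv
    return GraphEstimate(p, norms, theta2, converged, list(data.columns))


def score(est, truth) -> ConfusionMetrics:
    """Confusion metrics over unordered pairs against a true adjacency."""
    A = est.adjacency() if isinstance(est, GraphEstimate) else np.asarray(est, bool)
    T = np.asarray(truth, dtype=bool)
    if A.shape != T.shape:
        raise ValueError("adjacency shapes differ")
    if not np.array_equal(T, T.T):
        raise ValueError("truth adjacency must be symmetric")
    iu = np.triu_indices(A.shape[0], k=1)
    a, t = A[iu], T[iu]
    return ConfusionMetrics(
        TP=int(np.sum(a & t)),
        TN=int(np.sum(~a & ~t)),
        FP=int(np.sum(a & ~t)),
        FN=int(np.sum(~a & t)),
    )


# ---------------------------------------------------------------------------
# Writers / readers (node indices are 1-based in all outputs)
# ---------------------------------------------------------------------------

def write_edge_list(est: GraphEstimate, path, rule: str = "and") -> None:
    lines = ["node_a\tnode_b\tnorm_ab\tnorm_ba"]
    for a, k in est.edges(rule):
        lines.append(f"{a + 1}\t{k + 1}\t{est.norms[a, k]:.12g}\t{est.norms[k, a]:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_adjacency(est: GraphEstimate, path, rule: str = "and") -> None:
    A = est.adjacency(rule).astype(int)
    header = ",".join(est.columns)
    body = "\n".join(",".join(str(v) for v in row) for row in A)
    Path(path).write_text(header + "\n" + body + "\n")


def write_norms(est: GraphEstimate, path) -> None:
    lines = ["node_a\tnode_b\tnorm_ab\tnorm_ba\ttheta_ab\ttheta_ba"]
    for a in range(est.p):
        for k in range(a + 1, est.p):
            lines.append(
                f"{a + 1}\t{k + 1}\t{est.norms[a, k]:.17g}\t{est.norms[k, a]:.17g}"
                f"\t{est.theta2[a, k]:.17g}\t{est.theta2[k, a]:.17g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_norms(path, p: int) -> GraphEstimate:
    norms = np.zeros((p, p))
    theta2 = np.zeros((p, p))
    lines = Path(path).read_text().strip().splitlines()[1:]
    for line in lines:
        a, k, nab, nba, tab, tba = line.split("\t")
        a, k = int(a) - 1, int(k) - 1
        norms[a, k], norms[k, a] = float(nab), float(nba)
        theta2[a, k], theta2[k, a] = float(tab), float(tba)
    return GraphEstimate(p, norms, theta2, np.ones(p, dtype=bool))


def write_graphml(est: GraphEstimate, path, rule: str = "and") -> None:
    import networkx as nx

    G = nx.Graph()
    for j, name in enumerate(est.columns):
        G.add_node(j + 1, name=name)
    for a, k in est.edges(rule):
        G.add_edge(a + 1, k + 1, norm_ab=float(est.norms[a, k]),
                   norm_ba=float(est.norms[k, a]))
    nx.write_graphml(G, path)


def read_adjacency(path) -> np.ndarray:
    """Read a 0/1 adjacency CSV (with header) into a boolean matrix."""
    import pandas as pd

    df = pd.read_csv(path)
    return df.to_numpy(dtype=int).astype(bool)
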
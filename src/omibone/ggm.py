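"""Inter-omics Gaussian graphical model selection.

Workflow: a graphical-lasso path over ~100 regularization values yields
up to 100 distinct candidate edge structures; each structure is refit
without regularization (maximum likelihood with the zero pattern held
fixed, via iterative proportional scaling over the graph's cliques); the
structure minimising the extended Bayesian information criterion

    EBIC = −2ℓ + |E| log n + 4 γ |E| log p

is selected. Edges carry partial correlations r_ij = −Ω_ij / √(Ω_ii Ω_jj).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

__all__ = [
    "GgmResults",
    "NetworkStats",
    "GaussianGraphicalModel",
    "glasso_path",
    "refit_unregularized",
    "ebic",
    "network_stats",
]

_EDGE_EPS = 1e-8


def _support_from_precision(K: np.ndarray, eps: float = _EDGE_EPS) -> frozenset:
    p = K.shape[0]
    scale = np.sqrt(np.abs(np.outer(np.diag(K), np.diag(K))))
    edges = set()
    for i in range(p):
        for j in range(i + 1, p):
            if abs(K[i, j]) > eps * max(1.0, scale[i, j]):
                edges.add((i, j))
    return frozenset(edges)


def glasso_path(data, n_lambdas: int = 100, lambda_ratio: float = 0.01,
                max_structures: int = 100):
    """Distinct edge structures along a graphical-lasso path.

    The penalty grid is log-spaced from λ_max (the smallest λ giving the
    empty graph, i.e. the largest off-diagonal of the correlation
    matrix) down to λ_max·``lambda_ratio``. Supports are returned in
    non-increasing λ order, deduplicated, at most ``max_structures``.
    """
    if isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n <= 3:
        raise ValueError("need more than 3 samples")
    S = np.corrcoef(X, rowvar=False)
    lam_max = np.abs(S - np.eye(p)).max()
    if lam_max == 0:
        return [frozenset()], S, n
    lams = np.geomspace(lam_max, lam_max * lambda_ratio, n_lambdas)
    structures: list[frozenset] = [frozenset()]  # λ ≥ λ_max gives the empty graph
    seen = {frozenset()}
    for lam in lams:
        try:
            with warnings.catch_warnings():
                # small-λ path points need not converge tightly: only the
                # support is consumed, the refit is unregularized anyway
                warnings.simplefilter("ignore")
                _, K = graphical_lasso(S, alpha=lam, max_iter=200)
        except Exception as err:  # noqa: BLE001 - a failed λ is skipped
            warnings.warn(f"graphical lasso failed at lambda={lam:.4g}: {err}",
                          RuntimeWarning)
            continue
        support = _support_from_precision(K)
        if support not in seen:
            seen.add(support)
            structures.append(support)
        if len(structures) >= max_structures:
            break
    return structures, S, n


@dataclass
class GgmResults:
    """Unregularized GGM fit on a fixed edge structure.

    ``precision`` is the constrained MLE Ω (symmetric positive
    definite, exactly zero off the edge set); ``partial_correlations``
    holds r_ij = −Ω_ij/√(Ω_ii Ω_jj) with unit diagonal.
    """

    precision: pd.DataFrame
    edges: frozenset
    loglik: float
    n: int
    gamma: float = 0.5
    converged: bool = True
    ebic_value: float = 0.0

    def __post_init__(self):
        self.ebic_value = ebic(self, self.gamma)

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def partial_correlations(self) -> pd.DataFrame:
        K = self.precision.to_numpy()
        d = np.sqrt(np.diag(K))
        r = -K / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        return pd.DataFrame(r, index=self.precision.index,
                            columns=self.precision.columns)

    def edge_list(self) -> pd.DataFrame:
        names = self.precision.columns
        r = self.partial_correlations.to_numpy()
        rows = [
            {"node1": names[i], "node2": names[j], "partial_r": float(r[i, j]),
             "sign": "positive" if r[i, j] > 0 else "negative"}
            for i, j in sorted(self.edges)
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "partial_r", "sign"])

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(str(c) for c in self.precision.columns)
        r = self.partial_correlations.to_numpy()
        names = list(self.precision.columns)
        for i, j in self.edges:
            g.add_edge(str(names[i]), str(names[j]), partial_r=float(r[i, j]))
        return g

    def stats(self) -> "NetworkStats":
        return network_stats(self)

    def summary(self) -> str:
        s = self.stats()
        trans = f"{s.transitivity:.4f}" if s.transitivity is not None else "NA"
        return (
            "Gaussian graphical model\n"
            + "=" * 30 + "\n"
            f"nodes:        {self.p}\n"
            f"edges:        {len(self.edges)}\n"
            f"density:      {s.density:.4f}\n"
            f"transitivity: {trans}\n"
            f"EBIC (gamma={self.gamma}): {self.ebic_value:.4f}\n"
            f"log-likelihood: {self.loglik:.4f}"
        )


@dataclass
class NetworkStats:
    """Density (|E| over possible edges) and transitivity (closed-triple
    fraction); transitivity is None when undefined (p < 3 or no triples)."""

    density: float
    transitivity: float | None
    n_edges: int
    n_nodes: int


def _gaussian_loglik(K: np.ndarray, S: np.ndarray, n: int) -> float:
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(S @ K) - p * np.log(2 * np.pi))


def refit_unregularized(S, edges, n: int, gamma: float = 0.5,
                        tol: float = 1e-8, max_cycles: int = 1_000,
                        names=None) -> GgmResults:
    """Constrained MLE of a GGM with a fixed edge set.

    Iterative proportional scaling over the maximal cliques of the edge
    graph: each step replaces the clique block of the precision matrix
    so that the implied covariance matches S on that clique. Works for
    non-decomposable graphs. The fitted covariance Ω̂⁻¹ equals S exactly
    on the diagonal and on every edge; off-graph precision entries are
    exactly zero.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if names is None:
        names = pd.RangeIndex(p)
    edges = frozenset((min(i, j), max(i, j)) for i, j in edges)
    g = nx.Graph()
    g.add_nodes_from(range(p))
    g.add_edges_from(edges)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    K = np.diag(1.0 / np.diag(S))
    converged = False
    if all(len(c) == 1 for c in cliques):
        converged = True  # empty graph: diagonal MLE is exact
    else:
        for _ in range(max_cycles):
            for c in cliques:
                if len(c) == 1:
                    continue
                idx = np.array(c)
                sigma = np.linalg.inv(K)
                block = sigma[np.ix_(idx, idx)]
                K[np.ix_(idx, idx)] += (
                    np.linalg.inv(S[np.ix_(idx, idx)]) - np.linalg.inv(block)
                )
            sigma = np.linalg.inv(K)
            err = max(
                np.abs(np.diag(sigma) - np.diag(S)).max(),
                max((abs(sigma[i, j] - S[i, j]) for i, j in edges), default=0.0),
            )
            if err < tol:
                converged = True
                break
        if not converged:
            warnings.warn("IPF refit did not converge", RuntimeWarning)
    K = 0.5 * (K + K.T)
    # enforce exact zeros off the structure
    mask = np.zeros((p, p), dtype=bool)
    for i, j in edges:
        mask[i, j] = mask[j, i] = True
    np.fill_diagonal(mask, True)
    K[~mask] = 0.0
    ll = _gaussian_loglik(K, S, n)
    return GgmResults(
        precision=pd.DataFrame(K, index=names, columns=names),
        edges=edges, loglik=ll, n=n, gamma=gamma, converged=converged,
    )


def ebic(model: GgmResults, gamma: float = 0.5) -> float:
    """Extended BIC: −2ℓ + |E| log n + 4 γ |E| log p. γ = 0 recovers BIC."""
    E = len(model.edges)
    return float(
        -2.0 * model.loglik + E * np.log(model.n) + 4.0 * gamma * E * np.log(model.p)
    )


def network_stats(model: GgmResults) -> NetworkStats:
    g = model.to_graph()
    p = g.number_of_nodes()
    e = g.number_of_edges()
    density = 0.0 if p < 2 else e / (p * (p - 1) / 2)
    if p < 3:
        trans = None
    else:
        trans = nx.transitivity(g)
        # networkx returns 0 for no connected triples; keep that as 0.0
    return NetworkStats(density=float(density), transitivity=trans,
                        n_edges=e, n_nodes=p)


class GaussianGraphicalModel:
    """EBIC-selected Gaussian graphical model of a standardized data matrix.

    Parameters
    ----------
    data : DataFrame
        Samples × nodes (typically the sCCA-selected features plus the
        phenotype). The correlation matrix is used throughout, so the
        selection is invariant to column scaling.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(np.asarray(data, dtype=float))
        self.data = data

    def fit(self, gamma: float = 0.5, n_lambdas: int = 100,
            lambda_ratio: float = 0.01, max_structures: int = 100) -> GgmResults:
        """Path → unregularized refits → argmin EBIC (ties to the
        sparser structure, guaranteed by scanning in sparsity order)."""
        structures, S, n = glasso_path(
            self.data, n_lambdas=n_lambdas, lambda_ratio=lambda_ratio,
            max_structures=max_structures,
        )
        names = self.data.columns
        best = None
        n_failed = 0
        for edges in sorted(structures, key=len):
            try:
                model = refit_unregularized(S, edges, n, gamma=gamma, names=names)
            except np.linalg.LinAlgError:
                n_failed += 1
                continue
            if not np.isfinite(model.ebic_value):
                n_failed += 1
                continue
            if best is None or model.ebic_value < best.ebic_value - 1e-12:
                best = model
        if best is None:
            raise RuntimeError(f"all {n_failed} structure refits failed")
        return best
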
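"""SparCC co-occurrence inference for compositional taxon tables.

Correlations computed directly on relative abundances carry a negative
bias from the unit-sum constraint. SparCC instead estimates the
correlations of the (unobserved) absolute abundances from log-ratio
variances: with T_ij = var(log(x_i/x_j)) and basis variances ω,

    T_ij = ω_i + ω_j − 2·cov(log w_i, log w_j),

which under an assumption of sparse correlations yields a linear system
for ω; basis correlations follow by moment matching. Strongly correlated
pairs violate the sparsity assumption, so the procedure iteratively
excludes the most-correlated pair and re-solves. Sampling noise is
averaged out over Dirichlet resamples of each sample's composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "sparcc_correlations",
    "sparcc_pvalues",
    "build_network",
    "CorrelationNetwork",
]


def _basis_correlations(fracs, n_iter, exclusion_threshold):
    """One-pass SparCC estimate from a fixed fraction matrix (samples × taxa)."""
    logs = np.log(fracs)
    C = np.cov(logs, rowvar=False)          # covariance of log fractions
    p = C.shape[0]
    var_diag = np.diag(C)
    # T_ij = var(log x_i − log x_j)
    T = var_diag[:, None] + var_diag[None, :] - 2.0 * C
    included = np.ones((p, p), dtype=bool)  # pair (i,j) participates in the system
    np.fill_diagonal(included, False)
    rho = None
    for _ in range(max(1, n_iter)):
        M = included.astype(float)
        np.fill_diagonal(M, included.sum(axis=1))
        t = (T * included).sum(axis=1)
        try:
            omega = np.linalg.solve(M, t)
        except np.linalg.LinAlgError:
            break
        omega = np.maximum(omega, 1e-12)
        cov = 0.5 * (omega[:, None] + omega[None, :] - T)
        denom = np.sqrt(np.outer(omega, omega))
        new_rho = cov / denom
        np.fill_diagonal(new_rho, 1.0)
        rho = new_rho
        # exclude the strongest remaining pair above the threshold
        masked = np.where(included, np.abs(rho), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        # a taxon left with too few pairs would make the system singular
        if included.sum(axis=1).min() < 2:
            included[i, j] = included[j, i] = True
            break
    return rho


def _resample_fractions(counts, rng):
    """Dirichlet(counts + 1) posterior draw of each sample's composition."""
    return np.vstack([rng.dirichlet(row + 1.0) for row in counts])


def sparcc_correlations(
    table,
    n_iter: int = 20,
    exclusion_threshold: float = 0.1,
    n_inner: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate basis correlations between taxa from a count table.

    Parameters
    ----------
    table : DataFrame or ndarray, samples × taxa
        Counts (preferred; enables Dirichlet resampling) or strictly
        positive relative abundances (used as-is, n_inner collapses to 1).
    n_iter : int
        Maximum strongly-correlated-pair exclusion rounds.
    exclusion_threshold : float
        |ρ| above which the strongest pair is excluded from the basis
        variance system.
    n_inner : int
        Dirichlet resamples averaged over.
    """
    if isinstance(table, pd.DataFrame):
        names = table.columns
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        names = pd.RangeIndex(values.shape[1])
    p = values.shape[1]
    if p < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    if (values < 0).any():
        raise ValueError("abundances must be nonnegative")
    is_counts = np.allclose(values, np.round(values)) and values.max() > 1.0
    rng = np.random.default_rng(seed)
    if is_counts:
        draws = [_resample_fractions(values, rng) for _ in range(max(1, n_inner))]
    else:
        if (values == 0).any():
            raise ValueError(
                "relative-abundance input must be strictly positive; "
                "pass counts to enable Dirichlet resampling of zeros"
            )
        fracs = values / values.sum(axis=1, keepdims=True)
        draws = [fracs]
    rhos = [_basis_correlations(f, n_iter, exclusion_threshold) for f in draws]
    rho = np.mean([r for r in rhos if r is not None], axis=0)
    if np.abs(rho).max() > 1.0 + 1e-9:
        warnings.warn("out-of-range SparCC correlations clipped to [-1, 1]",
                      RuntimeWarning)
    rho = np.clip(rho, -1.0, 1.0)
    rho = 0.5 * (rho + rho.T)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=names, columns=names)


def sparcc_pvalues(
    table,
    n_perm: int = 100,
    seed: int = 0,
    n_iter: int = 20,
    exclusion_threshold: float = 0.1,
    n_inner: int = 10,
    n_inner_perm: int | None = None,
) -> pd.DataFrame:
    """Two-sided permutation p-values for SparCC correlations.

    Each permutation shuffles every taxon column independently,
    destroying all inter-taxon dependence while preserving marginals;
    p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (1 + n_perm), so the smallest
    attainable p is 1/(1 + n_perm).

    ``n_inner_perm`` sets the Dirichlet-resample count used inside each
    permutation run (default: same as ``n_inner``). A single draw per
    permutation makes large permutation counts affordable; the noisier
    per-permutation estimates widen the null slightly, which errs on the
    conservative side.
    """
    if n_inner_perm is None:
        n_inner_perm = n_inner
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if isinstance(table, pd.DataFrame):
        names = table.columns
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        names = pd.RangeIndex(values.shape[1])
    rng = np.random.default_rng(seed)
    obs = np.abs(
        sparcc_correlations(
            pd.DataFrame(values, columns=names), n_iter, exclusion_threshold,
            n_inner, seed=int(rng.integers(2**31)),
        ).to_numpy()
    )
    exceed = np.zeros_like(obs)
    n = values.shape[0]
    for _ in range(n_perm):
        perm = np.empty_like(values)
        for j in range(values.shape[1]):
            perm[:, j] = values[rng.permutation(n), j]
        r = sparcc_correlations(
            pd.DataFrame(perm, columns=names), n_iter, exclusion_threshold,
            n_inner_perm, seed=int(rng.integers(2**31)),
        ).to_numpy()
        exceed += np.abs(r) >= obs
    pmat = (1.0 + exceed) / (1.0 + n_perm)
    np.fill_diagonal(pmat, np.nan)
    return pd.DataFrame(pmat, index=names, columns=names)


@dataclass
class CorrelationNetwork:
    """Thresholded co-occurrence network.

    ``edges`` lists taxon pairs with |ρ| strictly above the correlation
    threshold and p strictly below the p threshold.
    """

    correlations: pd.DataFrame
    pvalues: pd.DataFrame | None
    edges: pd.DataFrame
    rho_threshold: float
    p_threshold: float

    @property
    def n_positive(self) -> int:
        return int((self.edges["rho"] > 0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.edges["rho"] < 0).sum())

    def summary(self) -> str:
        return (
            "SparCC co-occurrence network\n"
            f"taxa: {self.correlations.shape[0]}\n"
            f"edges: {len(self.edges)} "
            f"({self.n_positive} positive, {self.n_negative} negative)\n"
            f"criteria: |rho| > {self.rho_threshold}, p < {self.p_threshold}"
        )

    def to_graphml(self, path, phylum=None) -> None:
        import networkx as nx

        g = nx.Graph()
        for node in self.correlations.columns:
            attrs = {}
            if phylum is not None and node in phylum:
                attrs["phylum"] = str(phylum[node])
            g.add_node(str(node), **attrs)
        for _, row in self.edges.iterrows():
            g.add_edge(str(row["source"]), str(row["target"]),
                       rho=float(row["rho"]), sign=str(row["sign"]))
        nx.write_graphml(g, path)


def build_network(
    correlations: pd.DataFrame,
    pvalues: pd.DataFrame | None = None,
    rho_threshold: float = 0.5,
    p_threshold: float = 0.001,
) -> CorrelationNetwork:
    """Threshold a correlation (and p-value) matrix into an edge list.

    Both criteria are strict inequalities: |ρ| > rho_threshold AND
    p < p_threshold (the latter skipped when no p matrix is given).
    """
    rho = correlations.to_numpy()
    names = correlations.columns
    if pvalues is not None and pvalues.shape != correlations.shape:
        raise ValueError("correlation and p-value matrices must be conformable")
    rows = []
    p = rho.shape[0]
    pv = pvalues.to_numpy() if pvalues is not None else None
    for i in range(p):
        for j in range(i + 1, p):
            if abs(rho[i, j]) > rho_threshold and (
                pv is None or pv[i, j] < p_threshold
            ):
                rows.append(
                    {"source": names[i], "target": names[j],
                     "rho": float(rho[i, j]),
                     "p": float(pv[i, j]) if pv is not None else np.nan,
                     "sign": "positive" if rho[i, j] > 0 else "negative"}
                )
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])
    return CorrelationNetwork(correlations, pvalues, edges, rho_threshold, p_threshold)
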
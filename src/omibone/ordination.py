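"""Ordinations feeding the coinertia analysis.

Microbiome profiles enter as a principal coordinate analysis (PCoA) of
Bray-Curtis distances on re-closed relative abundances; metabolite
profiles enter as a PCA of the standardized feature matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["OrdinationResult", "bray_curtis", "pcoa", "pca"]


@dataclass
class OrdinationResult:
    """Sample coordinates on ordination axes.

    Eigenvalues are non-increasing; only axes with positive eigenvalue
    are retained (``n_dropped`` counts the discarded ones).
    """

    coordinates: pd.DataFrame        # samples × axes
    eigenvalues: np.ndarray
    method: str
    variance_explained: np.ndarray
    n_dropped: int = 0

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def top_axes(self, min_variance: float = 0.8, max_axes: int = 10) -> pd.DataFrame:
        """Leading axes covering ≥ ``min_variance`` of positive inertia,
        capped at ``max_axes``."""
        cum = np.cumsum(self.variance_explained)
        k = int(np.searchsorted(cum, min_variance) + 1)
        k = min(k, max_axes, self.n_axes)
        return self.coordinates.iloc[:, :k]


def bray_curtis(table) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix of a samples × taxa table.

    d_ij = Σ|x_i − x_j| / Σ(x_i + x_j); symmetric, zero diagonal,
    entries in [0, 1] for nonnegative input.
    """
    if isinstance(table, pd.DataFrame):
        index = table.index
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=index, columns=index)


def pcoa(distances) -> OrdinationResult:
    """Principal coordinate analysis (classical MDS).

    Eigendecomposes the Gower-centered matrix −½ J D² J; axes with
    eigenvalue ≤ 0 (possible for non-Euclidean dissimilarities such as
    Bray-Curtis) are dropped and counted.
    """
    if isinstance(distances, pd.DataFrame):
        index = distances.index
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        index = pd.RangeIndex(D.shape[0])
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if np.abs(np.diag(D)).max() > 1e-10:
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals[0]) if n else 1.0)
    n_dropped = int((~pos).sum())
    evals_pos = evals[pos]
    coords = evecs[:, pos] * np.sqrt(evals_pos)[None, :]
    var_exp = evals_pos / evals_pos.sum() if evals_pos.size else evals_pos
    cols = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=evals_pos,
        method="PCoA-BrayCurtis",
        variance_explained=var_exp,
        n_dropped=n_dropped,
    )


def pca(matrix, n_axes: int | None = None) -> OrdinationResult:
    """PCA scores of a samples × features matrix (columns centered
    internally; no rescaling — standardize beforehand if desired)."""
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    evals = s**2 / (n - 1)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_axes is None:
        n_axes = rank
    elif n_axes > rank:
        warnings.warn(f"n_axes={n_axes} exceeds rank {rank}; truncated",
                      RuntimeWarning)
        n_axes = rank
    coords = U[:, :n_axes] * s[:n_axes][None, :]
    total_var = Xc.var(axis=0, ddof=1).sum()
    var_exp = evals[:n_axes] / total_var if total_var > 0 else evals[:n_axes]
    cols = [f"PC{i+1}" for i in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=evals[:n_axes],
        method="PCA",
        variance_explained=var_exp,
        n_dropped=int(len(evals) - rank),
    )
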
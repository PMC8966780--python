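"""Coinertia analysis and the RV coefficient.

Coinertia measures the shared structure of two data tables observed on
the same samples: the total coinertia is the sum of squared covariances
over all cross-table variable pairs, and the RV coefficient

    RV = coinertia(X, Y) / sqrt(coinertia(X, X) · coinertia(Y, Y))

is its [0, 1]-normalised form — a multivariate extension of the squared
Pearson correlation. Significance comes from a Monte-Carlo permutation
test that shuffles the rows of one table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordination import OrdinationResult

__all__ = ["CoinertiaResult", "coinertia", "rv_permutation_test"]


def _coords(obj) -> np.ndarray:
    if isinstance(obj, OrdinationResult):
        return obj.coordinates.to_numpy(dtype=float)
    if isinstance(obj, pd.DataFrame):
        return obj.to_numpy(dtype=float)
    return np.asarray(obj, dtype=float)


def _cross_inertia(Xc: np.ndarray, Yc: np.ndarray) -> float:
    # uniform row weights 1/n; covariance = XᵀY/n on centered columns
    K = Xc.T @ Yc / Xc.shape[0]
    return float((K**2).sum())


def _rv(Xc: np.ndarray, Yc: np.ndarray) -> float:
    cxy = _cross_inertia(Xc, Yc)
    cxx = _cross_inertia(Xc, Xc)
    cyy = _cross_inertia(Yc, Yc)
    if cxx == 0 or cyy == 0:
        raise ValueError("degenerate (zero-variance) table in RV computation")
    return cxy / np.sqrt(cxx * cyy)


@dataclass
class CoinertiaResult:
    """Coinertia of two ordinations with its RV coefficient."""

    rv: float
    total_coinertia: float
    axes_x: np.ndarray
    axes_y: np.ndarray
    singular_values: np.ndarray
    p_value: float | None = None
    n_permutations: int | None = None

    def summary(self) -> str:
        lines = [
            "Coinertia analysis",
            "=" * 30,
            f"RV coefficient:  {self.rv:.4f}",
            f"total coinertia: {self.total_coinertia:.6g}",
        ]
        if self.p_value is not None:
            lines.append(
                f"permutation p:   {self.p_value:.4g} "
                f"({self.n_permutations} permutations)"
            )
        return "\n".join(lines)


def coinertia(ord_x, ord_y) -> CoinertiaResult:
    """Coinertia of two sample-aligned ordinations (or raw matrices).

    Columns are centered with uniform row weights 1/n. The coinertia
    axes are the singular vectors of the cross-covariance matrix.
    """
    X = _coords(ord_x)
    Y = _coords(ord_y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("tables must share the same samples in the same order")
    if isinstance(ord_x, OrdinationResult) and isinstance(ord_y, OrdinationResult):
        ix = ord_x.coordinates.index
        iy = ord_y.coordinates.index
        if not ix.equals(iy):
            raise ValueError("sample IDs of the two ordinations differ")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    K = Xc.T @ Yc / Xc.shape[0]
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    return CoinertiaResult(
        rv=_rv(Xc, Yc),
        total_coinertia=float((s**2).sum()),
        axes_x=U,
        axes_y=Vt.T,
        singular_values=s,
    )


def rv_permutation_test(ord_x, ord_y, n_perm: int = 999, seed: int = 0) -> CoinertiaResult:
    """Monte-Carlo permutation test of the RV coefficient.

    The rows of Y are permuted (X fixed);
    p = (1 + #{RV_perm ≥ RV_obs}) / (1 + n_perm), so the smallest
    attainable p is 1/(1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    result = coinertia(ord_x, ord_y)
    X = _coords(ord_x)
    Y = _coords(ord_y)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = Xc.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _rv(Xc, Yc[perm]) >= result.rv:
            exceed += 1
    result.p_value = (1.0 + exceed) / (1.0 + n_perm)
    result.n_permutations = n_perm
    return result
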
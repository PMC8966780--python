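"""Supervised sparse canonical correlation analysis.

Finds sparse canonical vectors u, v maximising uᵀXᵀYv subject to
‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1, ‖u‖₁ ≤ c1, ‖v‖₁ ≤ c2, with supervision imposed by
hard-zeroing coordinates outside the phenotype-screened supports Q1, Q2.
The L1 bounds are enforced by soft-thresholding with the threshold found
by bisection (the penalised-matrix-decomposition scheme); the alternating
updates never decrease the objective. Tuning of (c1, c2) uses k-fold
cross-validated held-out canonical correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import adjusted_linear_model

__all__ = [
    "supervised_prescreen",
    "SupervisedSparseCCA",
    "SccaResults",
    "scca_cv_tune",
]


def supervised_prescreen(X, y, q: int | None = 50, alpha: float | None = None) -> np.ndarray:
    """Indices of features with large univariate phenotype correlation.

    Either the ``q`` features with the largest |Pearson r| (default), or
    all features with correlation-test p < ``alpha`` when ``alpha`` is
    given.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = Xv.shape[1]
    Xc = Xv - Xv.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sx > 0, Xc.T @ yc / (sx * sy), 0.0)
    if alpha is not None:
        from scipy import stats

        n = Xv.shape[0]
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
        pvals = 2 * stats.t.sf(np.abs(t), n - 2)
        return np.flatnonzero(pvals < alpha)
    if q is None or q <= 0:
        raise ValueError("q must be a positive count (or pass alpha)")
    q = min(q, p)
    return np.sort(np.argsort(np.abs(r))[::-1][:q])


def _soft(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _l1_l2_update(a: np.ndarray, c: float) -> np.ndarray:
    """argmax wᵀa over ‖w‖₂ ≤ 1, ‖w‖₁ ≤ c: soft-threshold and renormalise,
    with the threshold found by bisection on the resulting L1 norm."""
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.zeros_like(a)
    w = a / norm
    if np.abs(w).sum() <= c:
        return w
    lo, hi = 0.0, np.abs(a).max()
    for _ in range(200):
        mid = (lo + hi) / 2.0
        s = _soft(a, mid)
        ns = np.linalg.norm(s)
        l1 = np.abs(s).sum() / ns if ns > 0 else 0.0
        if l1 > c:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * (1.0 + np.abs(a).max()):
            break
    s = _soft(a, hi)
    ns = np.linalg.norm(s)
    return s / ns if ns > 0 else np.zeros_like(s)


@dataclass
class SccaResults:
    """Fitted supervised sparse CCA model.

    ``u``/``v`` are the canonical weight vectors (zero outside Q1/Q2),
    ``scores`` the per-subject canonical variates Xu and Yv, and
    ``loadings`` the correlation of each selected feature with its own
    modality's score.
    """

    u: pd.Series
    v: pd.Series
    c1: float
    c2: float
    q1: np.ndarray
    q2: np.ndarray
    objective: float
    converged: bool
    n_iter: int
    scores: pd.DataFrame | None = None
    loadings: dict = field(default_factory=dict)
    cv_table: pd.DataFrame | None = None

    @property
    def support_x(self) -> pd.Index:
        return self.u.index[self.u.to_numpy() != 0.0]

    @property
    def support_y(self) -> pd.Index:
        return self.v.index[self.v.to_numpy() != 0.0]

    def summary(self) -> str:
        lines = [
            "Supervised sparse CCA",
            "=" * 34,
            f"c1 / c2:      {self.c1:.3f} / {self.c2:.3f}",
            f"objective:    {self.objective:.6g}",
            f"converged:    {self.converged} ({self.n_iter} iterations)",
            f"|support X|:  {len(self.support_x)}",
            f"|support Y|:  {len(self.support_y)}",
        ]
        if self.scores is not None:
            r = np.corrcoef(self.scores.iloc[:, 0], self.scores.iloc[:, 1])[0, 1]
            lines.append(f"score corr:   {r:.4f}")
        return "\n".join(lines)


class SupervisedSparseCCA:
    """Supervised sparse CCA of two column-standardized modalities.

    Parameters
    ----------
    X, Y : DataFrame
        Sample-aligned feature matrices (taxa CLR values and metabolite
        intensities, both standardized).
    y : array-like
        Quantitative phenotype used for the supervision screens.
    q : int
        Per-modality prescreen size (features with the largest
        univariate phenotype correlation).
    alpha : float, optional
        Use a p < alpha prescreen instead of a fixed count.
    """

    def __init__(self, X: pd.DataFrame, Y: pd.DataFrame, y, q: int = 50,
                 alpha: float | None = None):
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share samples")
        self.X = X
        self.Y = Y
        self.y = np.asarray(y, dtype=float).ravel()
        self.q1 = supervised_prescreen(X, self.y, q=q, alpha=alpha)
        self.q2 = supervised_prescreen(Y, self.y, q=q, alpha=alpha)
        if self.q1.size == 0 or self.q2.size == 0:
            raise ValueError("empty supervision support Q1 or Q2")

    def c_max(self) -> tuple[float, float]:
        """Upper ends of the admissible (c1, c2) ranges: √|Q1|, √|Q2|."""
        return float(np.sqrt(self.q1.size)), float(np.sqrt(self.q2.size))

    def fit(self, c1: float, c2: float, max_iter: int = 200, tol: float = 1e-8,
            rows=None) -> SccaResults:
        c1_hi, c2_hi = self.c_max()
        if not 1.0 <= c1 <= c1_hi + 1e-9:
            raise ValueError(f"c1 must lie in [1, {c1_hi:.3f}]")
        if not 1.0 <= c2 <= c2_hi + 1e-9:
            raise ValueError(f"c2 must lie in [1, {c2_hi:.3f}]")
        Xv = self.X.to_numpy(dtype=float)
        Yv = self.Y.to_numpy(dtype=float)
        if rows is not None:
            Xv, Yv = Xv[rows], Yv[rows]
        # restrict the cross-product to the supervised supports: the
        # hard-zero constraints make coordinates outside Q1/Q2 inert
        K = Xv[:, self.q1].T @ Yv[:, self.q2]
        # initialise v from the leading right singular vector
        _, _, Vt = np.linalg.svd(K, full_matrices=False)
        v_s = Vt[0]
        if np.abs(v_s).sum() > c2:
            v_s = _l1_l2_update(v_s, c2)
        obj_prev = -np.inf
        converged = False
        u_s = np.zeros(self.q1.size)
        it = 0
        for it in range(1, max_iter + 1):
            u_s = _l1_l2_update(K @ v_s, c1)
            v_s = _l1_l2_update(K.T @ u_s, c2)
            obj = float(u_s @ K @ v_s)
            if obj < obj_prev - 1e-10 * max(1.0, abs(obj_prev)):
                raise AssertionError("sCCA objective decreased")
            if obj - obj_prev < tol * max(1.0, abs(obj)):
                converged = True
                obj_prev = obj
                break
            obj_prev = obj
        if not converged:
            warnings.warn("sCCA did not converge", RuntimeWarning)
        u = np.zeros(self.X.shape[1])
        v = np.zeros(self.Y.shape[1])
        u[self.q1] = u_s
        v[self.q2] = v_s
        # orient the pair so cor(Xu, y) >= 0
        xu_full = self.X.to_numpy(dtype=float) @ u
        if np.std(xu_full) > 0 and np.corrcoef(xu_full, self.y)[0, 1] < 0:
            u, v = -u, -v
        return SccaResults(
            u=pd.Series(u, index=self.X.columns),
            v=pd.Series(v, index=self.Y.columns),
            c1=c1, c2=c2, q1=self.q1, q2=self.q2,
            objective=obj_prev, converged=converged, n_iter=it,
        )

    def fit_cv(self, grid=None, folds: int = 10, seed: int = 0,
               max_iter: int = 200, tol: float = 1e-8) -> SccaResults:
        """Fit at the (c1, c2) grid point maximising mean held-out
        correlation cor(X_test u, Y_test v) over k folds."""
        c1_sel, c2_sel, table = scca_cv_tune(
            self, grid=grid, folds=folds, seed=seed, max_iter=max_iter, tol=tol
        )
        res = self.fit(c1_sel, c2_sel, max_iter=max_iter, tol=tol)
        res.cv_table = table
        return res

    def scores_and_loadings(self, result: SccaResults, covariates=None) -> SccaResults:
        """Attach canonical scores, within-modality loadings and
        covariate-adjusted score–phenotype regressions to a fit."""
        Xv = self.X.to_numpy(dtype=float)
        Yv = self.Y.to_numpy(dtype=float)
        xu = Xv @ result.u.to_numpy()
        yv = Yv @ result.v.to_numpy()
        result.scores = pd.DataFrame(
            {"microbiome_score": xu, "metabolome_score": yv}, index=self.X.index
        )
        load_x = {
            f: float(np.corrcoef(self.X[f], xu)[0, 1]) for f in result.support_x
        }
        load_y = {
            f: float(np.corrcoef(self.Y[f], yv)[0, 1]) for f in result.support_y
        }
        tests = {}
        for name, score in (("microbiome_score", xu), ("metabolome_score", yv)):
            beta, p = adjusted_linear_model(score, self.y, covariates)
            tests[name] = {"beta_adj": beta, "p_value": p}
        result.loadings = {"X": pd.Series(load_x), "Y": pd.Series(load_y),
                           "phenotype_tests": tests}
        return result


def scca_cv_tune(model: SupervisedSparseCCA, grid=None, folds: int = 10,
                 seed: int = 0, max_iter: int = 200, tol: float = 1e-8,
                 one_se: bool = True):
    """Grid search over (c1, c2) by cross-validated held-out canonical
    correlation. Returns (c1*, c2*, cv table).

    With ``one_se`` (default) the sparsest grid point — smallest c1 + c2 —
    whose mean held-out correlation is within one standard error of the
    best is chosen: the held-out correlation surface is typically flat
    towards dense models, and the flat region's extra features are noise.
    """
    from sklearn.model_selection import KFold

    c1_hi, c2_hi = model.c_max()
    if grid is None:
        # log-spaced: sparsity varies fastest near the low end of c
        grid = [(a, b) for a in np.geomspace(1.0, c1_hi, 6)
                for b in np.geomspace(1.0, c2_hi, 6)]
    if len(grid) == 0:
        raise ValueError("empty (c1, c2) grid")
    Xv = model.X.to_numpy(dtype=float)
    Yv = model.Y.to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xv))
    rows = []
    for c1, c2 in grid:
        cors = []
        for tr, te in splits:
            res = model.fit(c1, c2, max_iter=max_iter, tol=tol, rows=tr)
            xu = Xv[te] @ res.u.to_numpy()
            yv = Yv[te] @ res.v.to_numpy()
            if np.std(xu) == 0 or np.std(yv) == 0:
                warnings.warn("zero-variance scores in a CV fold; fold skipped",
                              RuntimeWarning)
                continue
            cors.append(np.corrcoef(xu, yv)[0, 1])
        rows.append({"c1": c1, "c2": c2,
                     "cv_cor": float(np.mean(cors)) if cors else -np.inf,
                     "cv_se": (float(np.std(cors, ddof=1) / np.sqrt(len(cors)))
                               if len(cors) > 1 else np.inf),
                     "n_folds": len(cors)})
    table = pd.DataFrame(rows)
    best = int(table["cv_cor"].idxmax())
    if one_se:
        cutoff = table.loc[best, "cv_cor"] - table.loc[best, "cv_se"]
        ok = table[table["cv_cor"] >= cutoff]
        best = int((ok["c1"] + ok["c2"]).idxmin())
    return float(table.loc[best, "c1"]), float(table.loc[best, "c2"]), table
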
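"""Single-omics association screening.

Microbiome side: a zero-sum (log-contrast) elastic net on CLR-transformed
abundances performs the initial feature selection — the Σβ = 0 constraint
makes coefficients invariant to the compositional scale — followed by
covariate-adjusted partial Spearman tests with Benjamini-Hochberg FDR on
the selected subset.

Metabolite side: PLS with variable-importance-in-projection (VIP)
screening plus per-feature covariate-adjusted linear models.

Also houses the fecal-metabolite imputer: per-metabolite elastic-net
models mapping microbial gene abundances to metabolite levels, retaining
metabolites whose training Spearman ρ exceeds 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ZeroSumElasticNet",
    "ZeroSumResults",
    "partial_spearman",
    "bh_fdr",
    "pls_vip",
    "PlsVipResults",
    "adjusted_linear_model",
    "MetaboliteImputer",
    "microbiome_screen",
    "metabolite_screen",
]


# ---------------------------------------------------------------------------
# zero-sum elastic net
# ---------------------------------------------------------------------------


def _pair_move(beta_j, beta_k, a, b, lam1):
    """Best update δ for the move (β_j, β_k) → (β_j + δ, β_k − δ).

    Minimises aδ² + bδ + λ1(|β_j+δ| + |β_k−δ|) over δ, vectorised over
    the partner coordinate(s) k. The penalised objective is piecewise
    quadratic with breakpoints at δ = −β_j and δ = β_k; the minimiser is
    either an interior soft-thresholded stationary point of one sign
    region or a breakpoint.
    """
    cands = np.empty((6, np.shape(a)[0] if np.ndim(a) else 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        i = 0
        for s1 in (1.0, -1.0):
            for s2 in (1.0, -1.0):
                cands[i] = -(b + lam1 * (s1 - s2)) / (2.0 * a)
                i += 1
    cands[4] = -beta_j
    cands[5] = beta_k
    # objective change for each candidate
    dj = np.abs(beta_j + cands) - np.abs(beta_j)
    dk = np.abs(beta_k - cands) - np.abs(beta_k)
    delta_f = a * cands**2 + b * cands + lam1 * (dj + dk)
    # validity of the interior candidates: the assumed signs must hold
    idx = 0
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            bad = (s1 * (beta_j + cands[idx]) < 0) | (s2 * (beta_k - cands[idx]) < 0)
            delta_f[idx] = np.where(bad | ~np.isfinite(cands[idx]), np.inf, delta_f[idx])
            idx += 1
    best = np.argmin(delta_f, axis=0)
    take = np.arange(delta_f.shape[1])
    return cands[best, take], delta_f[best, take]


def _cd_kernel_py(G, q, lam1, lam2, beta, max_sweeps, tol):  # pragma: no cover
    """Pure-numpy sweep kernel (fallback when numba is unavailable)."""
    p = G.shape[0]
    g = q - G @ beta
    diag = np.diag(G).copy()
    for sweep in range(1, max_sweeps + 1):
        best_drop = 0.0
        for j in range(p):
            a = diag[j] + diag - 2.0 * G[j] + 2.0 * lam2
            b = -2.0 * (g[j] - g) + 2.0 * lam2 * (beta[j] - beta)
            a[j] = 1.0  # placeholder; the self-pair is masked below
            deltas, drops = _pair_move(beta[j], beta, a, b, lam1)
            drops[j] = np.inf
            k = int(np.argmin(drops))
            if drops[k] < -tol:
                d = deltas[k]
                beta[j] += d
                beta[k] -= d
                g -= d * (G[:, j] - G[:, k])
                if drops[k] < best_drop:
                    best_drop = drops[k]
        if best_drop > -tol:
            return sweep, True
    return max_sweeps, False


def _cd_kernel_scalar(G, q, lam1, lam2, beta, max_sweeps, tol):
    """Scalar sweep kernel, written for numba JIT compilation."""
    p = G.shape[0]
    g = q - G @ beta
    for sweep in range(1, max_sweeps + 1):
        sweep_drop = 0.0
        for j in range(p):
            bj = beta[j]
            best_drop = 0.0
            best_k = -1
            best_delta = 0.0
            for k in range(p):
                if k == j:
                    continue
                a = G[j, j] + G[k, k] - 2.0 * G[j, k] + 2.0 * lam2
                bk = beta[k]
                b = -2.0 * (g[j] - g[k]) + 2.0 * lam2 * (bj - bk)
                # interior candidates for the four sign regions
                if a > 0.0:
                    for s1 in (1.0, -1.0):
                        for s2 in (1.0, -1.0):
                            d = -(b + lam1 * (s1 - s2)) / (2.0 * a)
                            if s1 * (bj + d) < 0.0 or s2 * (bk - d) < 0.0:
                                continue
                            df = (a * d * d + b * d
                                  + lam1 * (abs(bj + d) - abs(bj)
                                            + abs(bk - d) - abs(bk)))
                            if df < best_drop:
                                best_drop = df
                                best_k = k
                                best_delta = d
                # breakpoints: a coordinate hits exactly zero
                for d in (-bj, bk):
                    df = (a * d * d + b * d
                          + lam1 * (abs(bj + d) - abs(bj)
                                    + abs(bk - d) - abs(bk)))
                    if df < best_drop:
                        best_drop = df
                        best_k = k
                        best_delta = d
            if best_k >= 0 and best_drop < -tol:
                d = best_delta
                beta[j] = bj + d
                beta[best_k] -= d
                for i in range(p):
                    g[i] -= d * (G[i, j] - G[i, best_k])
                if best_drop < sweep_drop:
                    sweep_drop = best_drop
        if sweep_drop > -tol:
            return sweep, True
    return max_sweeps, False


try:  # JIT-compile when numba is present; the numpy kernel is equivalent
    from numba import njit

    _cd_kernel = njit(cache=True)(_cd_kernel_scalar)
except ImportError:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


def _zerosum_cd(G, q, lam1, lam2, beta0=None, max_sweeps=10_000, tol=1e-8):
    """Cyclic two-coordinate descent for the zero-sum elastic net.

    Works on the Gram matrix G = XᵀX and q = Xᵀy. Each accepted move
    shifts a coordinate pair by (+δ, −δ), so Σβ = 0 holds exactly at
    every iterate. For each cycled coordinate j the partner k with the
    largest objective decrease is chosen, which makes a full sweep a
    check of every coordinate pair.
    """
    p = G.shape[0]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    n_sweeps, converged = _cd_kernel(
        np.ascontiguousarray(G, dtype=np.float64),
        np.ascontiguousarray(q, dtype=np.float64),
        float(lam1), float(lam2), beta, int(max_sweeps), float(tol),
    )
    return beta, n_sweeps, converged


@dataclass
class ZeroSumResults:
    """Fit results for a zero-sum elastic net.

    ``params`` carries the per-taxon coefficients (Σ params = 0 exactly),
    ``selected`` the taxa with nonzero coefficients.
    """

    params: pd.Series
    intercept: float
    lam1: float
    lam2: float
    objective: float
    converged: bool
    n_sweeps: int
    cv_table: pd.DataFrame | None = None

    @property
    def selected(self) -> pd.Index:
        return self.params.index[self.params.to_numpy() != 0.0]

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.params.to_numpy()

    def summary(self) -> str:
        lines = [
            "Zero-sum elastic net",
            "=" * 34,
            f"lambda1 (L1): {self.lam1:.6g}",
            f"lambda2 (L2): {self.lam2:.6g}",
            f"objective:    {self.objective:.6g}",
            f"converged:    {self.converged} ({self.n_sweeps} sweeps)",
            f"selected:     {len(self.selected)} / {len(self.params)} taxa",
            f"sum(beta):    {self.params.sum():.3e}",
            "-" * 34,
        ]
        nz = self.params[self.params != 0].sort_values(key=np.abs, ascending=False)
        for name, b in nz.items():
            lines.append(f"{str(name):<24s} {b:+.4f}")
        return "\n".join(lines)


class ZeroSumElasticNet:
    """Linear model on CLR covariates with a Σβ = 0 constraint.

    Minimises ‖y − β₀ − Xβ‖² + λ1‖β‖₁ + λ2‖β‖₂² subject to Σβ = 0.
    The constraint is maintained exactly by a pairwise coordinate-descent
    solver; the ridge term is squared (standard elastic-net convention).

    Parameters
    ----------
    X : DataFrame or ndarray
        CLR-transformed abundances, samples × taxa.
    y : array-like
        Quantitative phenotype (standardized).
    """

    def __init__(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names = X.columns
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = pd.RangeIndex(X.shape[1])
        y = np.asarray(y, dtype=float).ravel()
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in X or y")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different sample counts")
        self.X = X
        self.y = y
        self._xmean = X.mean(axis=0)
        self._ymean = y.mean()
        self._Xc = X - self._xmean
        self._yc = y - self._ymean

    def _fit_gram(self, G, q, lam1, lam2, beta0=None, max_sweeps=10_000, tol=1e-8):
        return _zerosum_cd(G, q, lam1, lam2, beta0, max_sweeps, tol)

    def fit(self, lam1: float, lam2: float, max_sweeps: int = 10_000, tol: float = 1e-8) -> ZeroSumResults:
        if lam1 < 0 or lam2 < 0:
            raise ValueError("penalties must be nonnegative")
        G = self._Xc.T @ self._Xc
        q = self._Xc.T @ self._yc
        scale = max(1.0, float(self._yc @ self._yc))
        beta, sweeps, converged = self._fit_gram(
            G, q, lam1, lam2, max_sweeps=max_sweeps, tol=tol * scale
        )
        if not converged:
            warnings.warn(
                "zero-sum elastic net did not converge within "
                f"{max_sweeps} sweeps", RuntimeWarning,
            )
        obj = self._objective(beta, lam1, lam2)
        return ZeroSumResults(
            params=pd.Series(beta, index=self.feature_names),
            intercept=float(self._ymean - self._xmean @ beta),
            lam1=lam1,
            lam2=lam2,
            objective=obj,
            converged=converged,
            n_sweeps=sweeps,
        )

    def _objective(self, beta, lam1, lam2) -> float:
        r = self._yc - self._Xc @ beta
        return float(r @ r + lam1 * np.abs(beta).sum() + lam2 * beta @ beta)

    def lambda_max(self, l1_ratio: float = 0.5) -> float:
        """Smallest λ on the path for which β = 0 is optimal."""
        q = self._Xc.T @ self._yc
        return float((q.max() - q.min()) / l1_ratio)

    def fit_cv(
        self,
        n_lambdas: int = 50,
        l1_ratio: float = 0.5,
        cv: int = 10,
        seed: int = 0,
        lambda_min_ratio: float = 1e-3,
        one_se: bool = True,
        max_sweeps: int = 2_000,
        tol: float = 1e-7,
    ) -> ZeroSumResults:
        """Tune λ along a log-spaced path by k-fold cross-validated MSE.

        λ splits into λ1 = λ·r and λ2 = λ·(1−r) with mixing ratio
        r = ``l1_ratio``. With ``one_se`` the sparsest model within one
        standard error of the CV minimum is chosen.
        """
        if not 0 < l1_ratio <= 1:
            raise ValueError("l1_ratio must lie in (0, 1]")
        lam_max = self.lambda_max(l1_ratio)
        lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        n = self.X.shape[0]
        mse = np.zeros((cv, n_lambdas))
        for f, (tr, te) in enumerate(folds.split(self.X)):
            Xtr, ytr = self.X[tr], self.y[tr]
            xm, ym = Xtr.mean(axis=0), ytr.mean()
            Xc, yc = Xtr - xm, ytr - ym
            G, q = Xc.T @ Xc, Xc.T @ yc
            scale = max(1.0, float(yc @ yc))
            Xte_c = self.X[te] - xm
            beta = None
            for li, lam in enumerate(lams):
                beta, _, _ = self._fit_gram(
                    G, q, lam * l1_ratio, lam * (1 - l1_ratio),
                    beta0=beta, max_sweeps=max_sweeps, tol=tol * scale,
                )
                resid = self.y[te] - (ym + Xte_c @ beta)
                mse[f, li] = float(resid @ resid) / len(te)
        mean_mse = mse.mean(axis=0)
        se_mse = mse.std(axis=0, ddof=1) / np.sqrt(cv)
        i_min = int(np.argmin(mean_mse))
        if one_se:
            # lams are decreasing: earlier index = sparser model
            ok = mean_mse <= mean_mse[i_min] + se_mse[i_min]
            i_sel = int(np.argmax(ok))
        else:
            i_sel = i_min
        lam = lams[i_sel]
        res = self.fit(lam * l1_ratio, lam * (1 - l1_ratio), tol=tol)
        res.cv_table = pd.DataFrame(
            {"lambda": lams, "cv_mse": mean_mse, "cv_se": se_mse}
        )
        return res


# ---------------------------------------------------------------------------
# rank-based and linear per-feature tests
# ---------------------------------------------------------------------------


def partial_spearman(x, y, covariates=None):
    """Covariate-adjusted Spearman correlation.

    All variables (x, y and each covariate) are replaced by average
    ranks; the partial Pearson correlation of the ranked x and y given
    the ranked covariates is returned with a two-sided p-value from the
    t approximation on n − n_cov − 2 degrees of freedom. With no
    covariates this reduces to the plain Spearman ρ.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    ncov = Z.shape[1]
    if n <= ncov + 2:
        raise ValueError("need n > n_covariates + 2")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable after ranking")
    rz = np.column_stack([stats.rankdata(Z[:, j]) for j in range(ncov)]) if ncov else Z
    design = np.column_stack([np.ones(n), rz])
    coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ coef_x
    ey = ry - design @ coef_y
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        raise ValueError("degenerate residuals in partial Spearman")
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    df = n - ncov - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjusted_linear_model(x, y, covariates=None):
    """OLS slope of y on x adjusting for covariates, with two-sided t test.

    The design matrix [1, x, covariates] must be full rank; collinearity
    raises an error rather than silently producing a pseudoinverse fit.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    cols = [np.ones_like(x), x]
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        cols.extend(Z.T)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates?)")
    fit = sm.OLS(y, design).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# PLS / VIP
# ---------------------------------------------------------------------------


@dataclass
class PlsVipResults:
    """PLS fit with per-feature variable importance in projection.

    VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ) where SS_a is
    the phenotype variance explained by component a; the squared VIPs
    average to one across features, so VIP ≥ 2 singles out features
    contributing ≥4× the average.
    """

    vip: pd.Series
    n_components: int
    scores: np.ndarray
    weights: np.ndarray
    q2: pd.Series | None = None

    def selected(self, threshold: float = 2.0) -> pd.Index:
        return self.vip.index[self.vip.to_numpy() >= threshold]

    def summary(self) -> str:
        top = self.vip.sort_values(ascending=False).head(10)
        lines = [
            "PLS-VIP screen",
            "=" * 30,
            f"components: {self.n_components}",
            f"sum(VIP^2)/p: {float((self.vip**2).mean()):.6f}",
            "-" * 30,
        ]
        lines += [f"{str(k):<24s} {v:6.3f}" for k, v in top.items()]
        return "\n".join(lines)


def _vip_from_fit(pls: PLSRegression, p: int) -> np.ndarray:
    W = pls.x_weights_              # p × A
    T = pls.x_scores_               # n × A
    q = pls.y_loadings_.ravel()     # A
    ss = (q**2) * (T**2).sum(axis=0)
    wnorm = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wnorm**2 @ ss) / ss.sum())


def pls_vip(X, y, n_components: int | None = None, max_components: int = 5,
            cv: int = 5, seed: int = 0) -> PlsVipResults:
    """Fit PLS regression of the phenotype on a standardized feature
    matrix and compute VIP scores.

    When ``n_components`` is None the component count is chosen by
    k-fold cross-validated Q² (capped at ``max_components`` and the
    matrix rank).
    """
    if isinstance(X, pd.DataFrame):
        names = X.columns
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = pd.RangeIndex(Xv.shape[1])
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    n, p = Xv.shape
    cap = int(min(max_components, p, n - 1))
    q2 = None
    if n_components is None:
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        press = np.zeros(cap)
        ss_tot = 0.0
        for tr, te in folds.split(Xv):
            ss_tot += float(((y[te] - y[tr].mean()) ** 2).sum())
            for a in range(1, cap + 1):
                m = PLSRegression(n_components=a, scale=False).fit(Xv[tr], y[tr])
                press[a - 1] += float(((y[te] - m.predict(Xv[te]).ravel()) ** 2).sum())
        q2_vals = 1.0 - press / ss_tot
        n_components = int(np.argmax(q2_vals)) + 1
        q2 = pd.Series(q2_vals, index=pd.RangeIndex(1, cap + 1, name="n_components"))
    if n_components > cap:
        raise ValueError(f"n_components={n_components} exceeds cap {cap}")
    pls = PLSRegression(n_components=n_components, scale=False).fit(Xv, y)
    vip = _vip_from_fit(pls, p)
    return PlsVipResults(
        vip=pd.Series(vip, index=names),
        n_components=n_components,
        scores=pls.x_scores_,
        weights=pls.x_weights_,
        q2=q2,
    )


# ---------------------------------------------------------------------------
# fecal-metabolite imputer
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteImputer:
    """Per-metabolite elastic-net predictors from microbial gene abundances.

    Trained on a paired reference set; only metabolites whose training-set
    Spearman ρ between observed and predicted values exceeds ``retain_rho``
    are kept for imputation. The ρ used for retention is computed on
    out-of-fold predictions within the reference set, so it is not
    inflated by in-sample overfitting.
    """

    weights: pd.DataFrame            # genes × metabolites
    intercepts: pd.Series
    training_rho: pd.Series
    retain_rho: float
    retained: pd.Index = field(init=False)

    def __post_init__(self):
        self.retained = self.training_rho.index[
            self.training_rho.to_numpy() > self.retain_rho
        ]

    @classmethod
    def train(
        cls,
        genes: pd.DataFrame,
        metabolites: pd.DataFrame,
        retain_rho: float = 0.3,
        l1_ratio: float = 0.9,
        cv: int = 5,
        seed: int = 0,
    ) -> "MetaboliteImputer":
        if genes.shape[0] != metabolites.shape[0]:
            raise ValueError("gene and metabolite tables must share samples")
        if genes.shape[0] < 10:
            raise ValueError("need at least 10 reference samples")
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.linear_model import ElasticNet
        from sklearn.model_selection import cross_val_predict

        G = genes.to_numpy(dtype=float)
        W = np.zeros((genes.shape[1], metabolites.shape[1]))
        b0 = np.zeros(metabolites.shape[1])
        rho = np.zeros(metabolites.shape[1])
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        for j in range(metabolites.shape[1]):
            yj = metabolites.iloc[:, j].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = ElasticNetCV(
                    l1_ratio=l1_ratio, cv=cv, alphas=30, random_state=seed,
                    max_iter=5_000,
                ).fit(G, yj)
                # retention ρ from out-of-fold predictions: in-sample fits of
                # a p ≫ n elastic net are optimistic enough to retain pure
                # noise, so the ρ > threshold rule is applied honestly
                oof = cross_val_predict(
                    ElasticNet(alpha=model.alpha_, l1_ratio=l1_ratio,
                               max_iter=5_000),
                    G, yj, cv=folds,
                )
            W[:, j] = model.coef_
            b0[j] = model.intercept_
            if np.ptp(oof) == 0:
                rho[j] = 0.0
            else:
                rho[j] = stats.spearmanr(yj, oof).statistic
        return cls(
            weights=pd.DataFrame(W, index=genes.columns, columns=metabolites.columns),
            intercepts=pd.Series(b0, index=metabolites.columns),
            training_rho=pd.Series(rho, index=metabolites.columns),
            retain_rho=retain_rho,
        )

    def predict(self, genes: pd.DataFrame) -> pd.DataFrame:
        """Impute retained metabolites as G·W + intercepts.

        Gene columns are aligned by ID; genes absent from ``genes`` are
        zero-filled with a warning, and zero overlap is an error.
        """
        overlap = self.weights.index.intersection(genes.columns)
        if len(overlap) == 0:
            raise ValueError("no overlapping gene IDs between model and input")
        missing = self.weights.index.difference(genes.columns)
        if len(missing) > 0:
            warnings.warn(
                f"{len(missing)} training gene(s) absent from input; zero-filled",
                UserWarning,
            )
        G = genes.reindex(columns=self.weights.index, fill_value=0.0).to_numpy(dtype=float)
        pred = G @ self.weights.to_numpy() + self.intercepts.to_numpy()
        out = pd.DataFrame(pred, index=genes.index, columns=self.weights.columns)
        return out.loc[:, self.retained]


# ---------------------------------------------------------------------------
# two-stage screens
# ---------------------------------------------------------------------------


def microbiome_screen(
    clr: pd.DataFrame,
    y,
    covariates=None,
    lam1: float | None = None,
    lam2: float | None = None,
    cv: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
    fdr_scope: str = "table",
) -> pd.DataFrame:
    """Two-stage microbiome screen.

    Stage 1 selects taxa by the zero-sum elastic net (CV-tuned unless
    λ1, λ2 are given); stage 2 tests every taxon by covariate-adjusted
    partial Spearman correlation. The final call is
    ``selected = stage1_selected AND fdr < fdr_alpha``.

    ``fdr_scope`` controls the BH multiplicity set. The default
    ``"table"`` corrects over all tested taxa: because stage 1 selects
    on the same data that stage 2 tests, restricting the correction to
    the selected subset understates the multiplicity actually incurred
    and is measurably anti-conservative. ``"selected"`` computes BH
    within the stage-1 subset instead (the convention used when
    reporting the screened-subset tables); the ``fdr_subset`` column
    always carries that subset-scoped value for table mirroring.
    """
    if fdr_scope not in ("table", "selected"):
        raise ValueError("fdr_scope must be 'table' or 'selected'")
    model = ZeroSumElasticNet(clr, y)
    if lam1 is not None and lam2 is not None:
        stage1 = model.fit(lam1, lam2)
    else:
        stage1 = model.fit_cv(cv=cv, seed=seed)
    chosen = stage1.selected
    records = []
    for taxon in clr.columns:
        in_stage1 = taxon in chosen
        rho, p = partial_spearman(clr[taxon].to_numpy(), y, covariates)
        records.append(
            {"feature": taxon, "rho_adj": rho, "p_value": p,
             "stage1_selected": in_stage1}
        )
    out = pd.DataFrame(records).set_index("feature")
    out["fdr_table"] = bh_fdr(out["p_value"].to_numpy())
    out["fdr_subset"] = np.nan
    mask = out["stage1_selected"].to_numpy()
    if mask.any():
        out.loc[mask, "fdr_subset"] = bh_fdr(out.loc[mask, "p_value"].to_numpy())
    out["fdr"] = out["fdr_table"] if fdr_scope == "table" else out["fdr_subset"]
    out["selected"] = out["stage1_selected"] & (out["fdr"] < fdr_alpha)
    out.attrs["stage1"] = stage1
    out.attrs["alpha"] = alpha
    return out


def metabolite_screen(
    features: pd.DataFrame,
    y,
    covariates=None,
    vip_threshold: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Metabolite screen: PLS-VIP plus per-feature adjusted linear models.

    A feature is flagged ``selected`` when VIP ≥ threshold or its
    adjusted linear-model p-value falls below ``alpha`` (the union the
    single-omics analysis reports; the intersection is recoverable from
    the columns).
    """
    res = pls_vip(features, y, seed=seed)
    records = []
    for col in features.columns:
        beta, p = adjusted_linear_model(features[col].to_numpy(), y, covariates)
        records.append({"feature": col, "beta_adj": beta, "p_value": p})
    out = pd.DataFrame(records).set_index("feature")
    out["vip"] = res.vip
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["vip_selected"] = out["vip"] >= vip_threshold
    out["lm_selected"] = out["p_value"] < alpha
    out["selected"] = out["vip_selected"] | out["lm_selected"]
    out.attrs["pls"] = res
    return out[["vip", "beta_adj", "p_value", "fdr",
                "vip_selected", "lm_selected", "selected"]]
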
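"""QC chain for untargeted LC-MS serum feature tables.

The fixed preprocessing order is

    detection filter → kNN imputation → probabilistic quotient
    normalisation → QC-RSD filter → log transform + autoscaling

mirroring common practice for pooled-QC-anchored untargeted runs: a
pooled QC sample injected every few biological samples anchors both the
detection and repeatability filters and serves as the PQN reference.

Missing values are encoded as NaN — never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "IntensityTable",
    "filter_detection",
    "knn_impute",
    "pqn_normalize",
    "rsd_filter",
    "log_autoscale",
    "preprocess",
]


@dataclass
class IntensityTable:
    """Samples × features intensity matrix with QC annotation.

    Parameters
    ----------
    values : DataFrame
        Positive intensities; missing entries are NaN.
    qc : array-like of bool
        True for pooled-QC injections, False for biological samples.
    batch : array-like, optional
        Batch labels per sample (only used by the optional per-batch
        median-centering hook).
    """

    values: pd.DataFrame
    qc: np.ndarray
    batch: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.qc = np.asarray(self.qc, dtype=bool)
        if self.qc.shape != (self.values.shape[0],):
            raise ValueError("qc flags must have one entry per sample")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("intensities must be nonnegative")
        if (vals == 0).any():
            raise ValueError("zeros found: encode missing values as NaN, not 0")

    @property
    def n_qc(self) -> int:
        return int(self.qc.sum())

    @property
    def n_bio(self) -> int:
        return int((~self.qc).sum())

    def with_values(self, values: pd.DataFrame) -> "IntensityTable":
        return replace(self, values=values)


def filter_detection(
    table: IntensityTable, qc_min: float = 0.5, bio_min: float = 0.8
) -> IntensityTable:
    """Keep features detected in ≥ ``qc_min`` of QC samples AND ≥ ``bio_min``
    of biological samples."""
    for name, t in (("qc_min", qc_min), ("bio_min", bio_min)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if table.n_qc == 0 or table.n_bio == 0:
        raise ValueError("need at least one QC and one biological sample")
    present = table.values.notna().to_numpy()
    qc_rate = present[table.qc].mean(axis=0)
    bio_rate = present[~table.qc].mean(axis=0)
    keep = (qc_rate >= qc_min) & (bio_rate >= bio_min)
    return table.with_values(table.values.loc[:, table.values.columns[keep]])


def knn_impute(table: IntensityTable, k: int = 10) -> IntensityTable:
    """k-nearest-neighbour imputation of missing intensities.

    Distances are Euclidean on log intensities over the features two
    samples share, rescaled by the shared-feature count (scikit-learn's
    nan-aware Euclidean metric); the imputed value is the mean of the k
    nearest samples' observed log values, exponentiated back.
    """
    n = table.values.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    vals = table.values.to_numpy(dtype=float)
    observed_per_feature = (~np.isnan(vals)).sum(axis=0)
    if (observed_per_feature == 0).any():
        bad = list(table.values.columns[observed_per_feature == 0])
        raise ValueError(f"feature(s) never observed: {bad}")
    if not np.isnan(vals).any():
        return table
    logged = np.log(vals)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = np.exp(imputer.fit_transform(logged))
    # observed entries must pass through untouched
    mask = ~np.isnan(vals)
    filled[mask] = vals[mask]
    out = pd.DataFrame(filled, index=table.values.index, columns=table.values.columns)
    return table.with_values(out)


def pqn_normalize(table: IntensityTable, reference: str = "qc") -> IntensityTable:
    """Probabilistic quotient normalisation.

    Each sample is divided by the median of its feature-wise quotients
    against a reference spectrum — the feature-wise median over QC
    samples (``reference="qc"``, falling back to all samples when no QC
    rows exist) or over all samples (``reference="all"``). This corrects
    sample-wide dilution while leaving the within-sample pattern intact.
    """
    vals = table.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("PQN requires a complete table; impute first")
    if (vals <= 0).any():
        raise ValueError("PQN requires strictly positive intensities")
    if reference not in ("qc", "all"):
        raise ValueError("reference must be 'qc' or 'all'")
    if reference == "qc" and table.n_qc > 0:
        ref = np.median(vals[table.qc], axis=0)
    else:
        ref = np.median(vals, axis=0)
    quotients = vals / ref[None, :]
    factors = np.median(quotients, axis=1)
    out = pd.DataFrame(
        vals / factors[:, None], index=table.values.index, columns=table.values.columns
    )
    return table.with_values(out)


def rsd_filter(table: IntensityTable, max_rsd: float = 0.30) -> IntensityTable:
    """Drop features whose relative standard deviation across QC samples
    exceeds ``max_rsd`` (default 30%)."""
    if max_rsd <= 0:
        raise ValueError("max_rsd must be positive")
    if table.n_qc < 2:
        raise ValueError("RSD filter needs at least two QC samples")
    qc_vals = table.values.to_numpy(dtype=float)[table.qc]
    if np.isnan(qc_vals).any():
        raise ValueError("RSD filter requires complete QC rows; impute first")
    means = qc_vals.mean(axis=0)
    if (means == 0).any():
        bad = list(table.values.columns[means == 0])
        raise ValueError(f"zero-mean feature(s) over QC — RSD undefined: {bad}")
    rsd = qc_vals.std(axis=0, ddof=1) / means
    keep = rsd <= max_rsd
    return table.with_values(table.values.loc[:, table.values.columns[keep]])


def log_autoscale(table: IntensityTable, biological_only: bool = True) -> pd.DataFrame:
    """Log-transform and autoscale (zero mean, unit variance per feature).

    Returns the standardized feature matrix of biological samples (QC
    rows are dropped by default — they have served their purpose). The
    variance uses the n−1 denominator.
    """
    if biological_only:
        frame = table.values.loc[~table.qc]
    else:
        frame = table.values
    vals = frame.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("log_autoscale requires a complete table")
    if (vals <= 0).any():
        raise ValueError("log_autoscale requires strictly positive intensities")
    logged = np.log(vals)
    sd = logged.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        bad = list(frame.columns[constant])
        raise ValueError(f"constant feature(s): {bad}")
    scaled = (logged - logged.mean(axis=0)) / sd
    return pd.DataFrame(scaled, index=frame.index, columns=frame.columns)


def batch_median_center(table: IntensityTable) -> IntensityTable:
    """Optional hook: divide each batch by its per-feature median ratio to
    the global per-feature median. A coarse stand-in for injection-order
    drift correction when acquisition metadata is unavailable."""
    if table.batch is None:
        return table
    vals = table.values.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals <= 0).any():
        raise ValueError("batch centering requires a complete, positive table")
    global_med = np.median(vals, axis=0)
    out = vals.copy()
    for b in np.unique(table.batch):
        rows = table.batch == b
        batch_med = np.median(vals[rows], axis=0)
        ratio = np.where(batch_med > 0, batch_med / global_med, 1.0)
        out[rows] = vals[rows] / ratio[None, :]
    frame = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return table.with_values(frame)


def preprocess(
    table: IntensityTable,
    qc_min: float = 0.5,
    bio_min: float = 0.8,
    k: int = 10,
    max_rsd: float = 0.30,
    pqn_reference: str = "qc",
    center_batches: bool = False,
) -> pd.DataFrame:
    """Run the full QC chain in its fixed order and return the
    standardized biological-sample feature matrix."""
    table = filter_detection(table, qc_min=qc_min, bio_min=bio_min)
    table = knn_impute(table, k=k)
    table = pqn_normalize(table, reference=pqn_reference)
    if center_batches:
        table = batch_median_center(table)
    table = rsd_filter(table, max_rsd=max_rsd)
    return log_autoscale(table)
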
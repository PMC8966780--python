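"""Compositional preprocessing of taxon abundance tables.

Shotgun-metagenomic taxon profiles are compositional: per-sample read
totals are an artifact of the sequencer, so only the proportions carry
information. The canonical workflow implemented here is

1. :func:`relative_abundance` — close each sample to unit sum;
2. :func:`filter_rare` — drop taxa whose mean relative abundance falls
   below a threshold (default 0.01%), keeping the bulk of the community;
3. :func:`clr_transform` — centred log-ratio transform, mapping each
   composition to a zero-sum real vector suitable for multivariate
   statistics.

Gene-abundance tables are normalised to transcripts per million (TPM)
with :func:`tpm`.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "relative_abundance",
    "filter_rare",
    "clr_transform",
    "tpm",
    "RareFilterResult",
    "default_pseudocount",
]


def _as_frame(values, name: str = "table") -> pd.DataFrame:
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.asarray(values, dtype=float))
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError(f"{name} contains non-finite values")
    return values


def relative_abundance(counts) -> pd.DataFrame:
    """Close a samples × taxa count (or abundance) table to row sums of 1.

    Already-relative rows pass through unchanged. Rows that sum to zero
    are an error: the offending sample is named.
    """
    table = _as_frame(counts, "counts")
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance table contains negative entries")
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = list(table.index[zero])
        raise ValueError(f"all-zero sample row(s): {bad}")
    rel = values / totals[:, None]
    return pd.DataFrame(rel, index=table.index, columns=table.columns)


class RareFilterResult(NamedTuple):
    """Filtered table plus the fraction of total abundance it retains."""

    table: pd.DataFrame
    retained_fraction: float
    n_removed: int


def filter_rare(
    table: pd.DataFrame,
    min_mean_abundance: float = 1e-4,
    renormalize: bool = False,
) -> RareFilterResult:
    """Drop taxa with mean relative abundance below ``min_mean_abundance``.

    Rows are *not* re-closed to unit sum unless ``renormalize`` is set:
    the CLR transform is scale-invariant so the choice is immaterial
    downstream of CLR, but Bray-Curtis distances should be computed on
    re-closed rows.
    """
    if not (0 < min_mean_abundance < 1):
        # threshold 0 is allowed as an explicit identity
        if min_mean_abundance != 0:
            raise ValueError("min_mean_abundance must lie in [0, 1)")
    table = _as_frame(table)
    _check_relative(table)
    means = table.to_numpy().mean(axis=0)
    keep = means >= min_mean_abundance
    out = table.loc[:, table.columns[keep]]
    retained = float(out.to_numpy().sum() / table.to_numpy().sum())
    if renormalize:
        out = relative_abundance(out)
    return RareFilterResult(out, retained, int((~keep).sum()))


def _check_relative(table: pd.DataFrame, tol: float = 1e-8) -> None:
    sums = table.to_numpy().sum(axis=1)
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError(
            "table is not relative (row sums deviate from 1); "
            "call relative_abundance() first"
        )


def default_pseudocount(table: pd.DataFrame) -> float:
    """Half the smallest nonzero entry — a multiplicative-replacement-style
    zero offset."""
    values = table.to_numpy()
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("table has no positive entries")
    return float(nonzero.min() / 2.0)


def clr_transform(table: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Centred log-ratio transform of a relative-abundance table.

    value_ij = log(x_ij + δ) − mean_j log(x_ij + δ). Each output row sums
    to zero. With zeros present a positive pseudocount δ is required;
    ``None`` selects :func:`default_pseudocount` when needed.
    """
    table = _as_frame(table)
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("composition contains negative entries")
    has_zeros = (values == 0).any()
    if pseudocount is None:
        pseudocount = default_pseudocount(table) if has_zeros else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if has_zeros and pseudocount == 0:
        raise ValueError("zeros present: a positive pseudocount is required")
    logs = np.log(values + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=table.index, columns=table.columns)
    out.attrs["pseudocount"] = pseudocount
    return out


def tpm(read_counts, lengths) -> pd.DataFrame:
    """Transcripts-per-million normalisation of gene read counts.

    G_k = (r_k / L_k) / Σ_i (r_i / L_i) × 10⁶ per sample; each sample's
    TPM values sum to 10⁶. ``read_counts`` is samples × genes; ``lengths``
    gives each gene's length in base pairs.
    """
    table = _as_frame(read_counts, "read_counts")
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape != (table.shape[1],):
        raise ValueError("lengths must have one entry per gene")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("read counts must be nonnegative")
    rates = values / lengths[None, :]
    totals = rates.sum(axis=1)
    if (totals == 0).any():
        bad = list(table.index[totals == 0])
        raise ValueError(f"all-zero sample row(s): {bad}")
    out = rates / totals[:, None] * 1e6
    return pd.DataFrame(out, index=table.index, columns=table.columns)
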
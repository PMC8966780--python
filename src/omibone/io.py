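"""TSV table I/O with strict validation.

All tables are tab-delimited with a header row and sample IDs in the
first column; missing values are encoded as "NA". Round trips preserve
values to full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_table", "write_table"]


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_table(path, allow_missing: bool = True) -> pd.DataFrame:
    """Read a samples × features TSV table.

    Raises on duplicate sample IDs and on non-numeric cells, naming the
    offending row/column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                      keep_default_na=False, dtype=str)
    if raw.index.has_duplicates:
        dup = list(raw.index[raw.index.duplicated()])
        raise ValueError(f"{path.name}: duplicate sample ID(s): {dup}")
    if raw.columns.has_duplicates:
        dup = list(raw.columns[raw.columns.duplicated()])
        raise ValueError(f"{path.name}: duplicate column(s): {dup}")
    out = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad][0]
            raise ValueError(
                f"{path.name}: non-numeric cell at row {row!r}, column {col!r}"
            )
        out[col] = converted
    frame = pd.DataFrame(out, index=raw.index)
    if not allow_missing and frame.isna().any().any():
        col = frame.columns[frame.isna().any()][0]
        raise ValueError(f"{path.name}: missing values in column {col!r}")
    return frame.astype(float) if frame.shape[1] else frame


def align_samples(*frames: pd.DataFrame) -> list[pd.DataFrame]:
    """Check that all tables share an identical sample-ID set and return
    them reindexed to the first table's order."""
    base = frames[0].index
    for f in frames[1:]:
        missing = base.difference(f.index)
        extra = f.index.difference(base)
        if len(missing) or len(extra):
            raise ValueError(
                "sample-ID mismatch across tables: "
                f"missing={list(missing[:5])} extra={list(extra[:5])}"
            )
    return [f.reindex(base) for f in frames]
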
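"""Shared input-validation helpers for matrix-like inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd


def check_unique_index(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} row identifiers: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} column identifiers: {dup}")


def check_beta_range(df: pd.DataFrame, what: str = "beta matrix") -> None:
    """Beta values must lie in [0,1]; NaN (missing) is allowed."""
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    bad &= ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{what}: value {vals[i, j]!r} out of [0,1] at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )


def check_nonnegative(df: pd.DataFrame, what: str = "expression matrix") -> None:
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{what}: negative value {vals[i, j]!r} at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )


def as_series_labels(labels, index, what: str = "labels") -> pd.Series:
    """Coerce labels to a Series aligned to ``index``; every id must be labeled."""
    s = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    if not s.index.equals(pd.Index(index)):
        missing = pd.Index(index).difference(s.index)
        if len(missing):
            raise ValueError(f"{what}: missing labels for {list(missing[:5])}")
        s = s.reindex(index)
    return s.astype(str)
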
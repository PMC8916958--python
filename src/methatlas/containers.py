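"""Core in-memory containers shared across modules.

The central object is :class:`DNAmReference`, a marker-gene-promoter by
cell-type matrix of expected beta values, optionally carrying per-marker
confidence weights and the cell type each marker gene is specific to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._validation import check_beta_range, check_unique_index


@dataclass
class DNAmReference:
    """Promoter-methylation reference: marker genes x cell types.

    Parameters
    ----------
    values : DataFrame
        Expected beta value of each marker-gene promoter in each cell type,
        all entries in [0, 1].
    weights : Series, optional
        Per-marker confidence in [0, 1]; defaults to unit weights.
        Markers whose imputed methylation in the non-expressing cell types
        is high are the informative ones and get weights near 1.
    target_type : Series, optional
        For each marker, the cell type it is a marker of.
    """

    values: pd.DataFrame
    weights: pd.Series | None = None
    target_type: pd.Series | None = None

    def __post_init__(self) -> None:
        check_unique_index(self.values, "DNAm reference")
        check_beta_range(self.values, "DNAm reference")
        if self.weights is None:
            self.weights = pd.Series(1.0, index=self.values.index)
        else:
            self.weights = pd.Series(self.weights).reindex(self.values.index)
            w = self.weights.to_numpy(dtype=float)
            if np.isnan(w).any() or (w < 0).any() or (w > 1).any():
                raise ValueError("reference weights must lie in [0,1]")
        if self.target_type is not None:
            self.target_type = pd.Series(self.target_type).reindex(self.values.index)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | Path) -> None:
        """Write the value matrix plus a ``<stem>.weights.tsv`` sidecar."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", float_format="%.10g", index_label="gene")
        side = pd.DataFrame({"weight": self.weights})
        if self.target_type is not None:
            side["target_type"] = self.target_type
        side.to_csv(
            path.with_suffix(".weights.tsv"),
            sep="\t",
            float_format="%.10g",
            index_label="gene",
        )

    @classmethod
    def from_tsv(cls, path: str | Path, weights_path: str | Path | None = None) -> "DNAmReference":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col=0)
        if weights_path is None:
            candidate = path.with_suffix(".weights.tsv")
            weights_path = candidate if candidate.exists() else None
        weights = None
        target = None
        if weights_path is not None:
            side = pd.read_csv(weights_path, sep="\t", index_col=0)
            weights = side["weight"]
            if "target_type" in side:
                target = side["target_type"]
        return cls(values=values, weights=weights, target_type=target)


@dataclass
class MatchedCompendium:
    """Paired promoter-DNAm / expression matrices over shared genes, samples.

    Used to decide which marker genes are *imputable*: genes whose promoter
    methylation is anticorrelated with expression across the compendium.
    """

    expression: pd.DataFrame
    beta: pd.DataFrame
    name: str = "compendium"

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.beta.index) or not (
            self.expression.columns.equals(self.beta.columns)
        ):
            raise ValueError(
                f"{self.name}: expression and beta matrices must share "
                "identical gene and sample index sets"
            )
        check_beta_range(self.beta, f"{self.name} beta")

    @property
    def genes(self) -> pd.Index:
        return self.expression.index


@dataclass
class ExpressionReference:
    """Marker-gene x cell-type matrix of median expression values."""

    values: pd.DataFrame          # markers x K, median expression per type
    target_type: pd.Series        # marker -> cell type it marks
    mss: pd.Series                # marker specificity score per marker

    def __post_init__(self) -> None:
        check_unique_index(self.values, "expression reference")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression reference values must be non-negative")
        self.target_type = pd.Series(self.target_type).reindex(self.values.index)
        self.mss = pd.Series(self.mss).reindex(self.values.index)

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns


@dataclass
class SingleNucleusMethylome:
    """Sparse single-nucleus methylation calls in long format.

    ``calls`` has columns (site_id, nucleus_id, call) with call in {0, 1};
    a (site, nucleus) pair absent from the table is uncovered (missing).
    """

    calls: pd.DataFrame
    labels: pd.Series                      # nucleus -> cell type
    sites: pd.DataFrame | None = None      # optional site_id -> chrom/pos

    def __post_init__(self) -> None:
        required = {"site_id", "nucleus_id", "call"}
        if not required.issubset(self.calls.columns):
            raise ValueError(f"calls table needs columns {sorted(required)}")
        vals = self.calls["call"].to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("methylation calls must be Bernoulli (0 or 1)")
        nuclei = pd.Index(self.calls["nucleus_id"].unique())
        missing = nuclei.difference(self.labels.index)
        if len(missing):
            raise ValueError(f"unlabeled nuclei: {list(missing[:5])}")
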
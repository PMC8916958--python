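"""Cell-type mRNA expression reference construction from annotated scRNA-seq.

Marker genes for each of the K annotated cell types are found with
one-vs-rest Wilcoxon rank-sum tests; a gene's marker specificity score
(MSS) is the number of *other* cell types in which its median expression
is zero, so an ideal marker attains MSS = K - 1. The reference entry for
gene g in cell type k is the median expression of g over the cells of k.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._validation import as_series_labels, check_nonnegative, check_unique_index
from .containers import ExpressionReference

MIN_RECOMMENDED_MARKERS = 100


def _per_type_medians(sc: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Median expression per gene (rows) and cell type (columns)."""
    return sc.T.groupby(labels).median().T


def rank_markers(
    sc: pd.DataFrame,
    labels,
    mss_min: int | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Score every gene as a candidate marker for every cell type.

    Parameters
    ----------
    sc : DataFrame
        Genes x cells expression matrix (counts or normalized), values >= 0.
    labels : Series
        Cell-type label per cell; K >= 2 types, each with >= 2 cells.
    mss_min : int, optional
        Minimum marker specificity score for selection; defaults to K - 1
        (perfect specificity).
    fdr : float
        BH false-discovery-rate threshold for the one-vs-rest Wilcoxon test.

    Returns
    -------
    DataFrame
        One row per (gene, cell_type) with columns ``median_target``,
        ``mss``, ``p``, ``fdr`` and a boolean ``selected`` flag. The
        Wilcoxon test uses the normal approximation with tie correction
        (one-sided, greater in the target type); FDR is computed per cell
        type across genes.
    """
    check_unique_index(sc, "scRNA-seq matrix")
    check_nonnegative(sc, "scRNA-seq matrix")
    labels = as_series_labels(labels, sc.columns, "cell labels")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"cell type(s) with fewer than 2 cells: {list(small.index)}")
    K = len(types)
    if mss_min is None:
        mss_min = K - 1
    if not 0 <= mss_min <= K - 1:
        raise ValueError(f"mss_min must lie in [0, {K - 1}]")

    medians = _per_type_medians(sc, labels)  # genes x K
    n_zero_other = (medians.to_numpy() == 0).sum(axis=1, keepdims=True) - (
        medians.to_numpy() == 0
    )
    mss = pd.DataFrame(n_zero_other, index=medians.index, columns=medians.columns)

    values = sc.to_numpy(dtype=float)
    chunks = []
    for t in types:
        in_t = (labels == t).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-tied genes yield p = NaN warnings
            res = stats.mannwhitneyu(
                values[:, in_t].T,
                values[:, ~in_t].T,
                axis=0,
                alternative="greater",
                method="asymptotic",
            )
        p = np.nan_to_num(res.pvalue, nan=1.0)
        q = multipletests(p, method="fdr_bh")[1]
        chunks.append(
            pd.DataFrame(
                {
                    "gene": medians.index,
                    "cell_type": t,
                    "median_target": medians[t].to_numpy(),
                    "mss": mss[t].to_numpy(),
                    "p": p,
                    "fdr": q,
                }
            )
        )
    table = pd.concat(chunks, ignore_index=True)
    table["selected"] = (
        (table["fdr"] < fdr)
        & (table["mss"] >= mss_min)
        & (table["median_target"] > 0)
    )
    return table


def assign_marker_targets(markers: pd.DataFrame) -> pd.DataFrame:
    """Reduce a marker table to one row per selected gene.

    Each selected gene is assigned the cell type with maximal median
    expression; ties are broken by smaller Wilcoxon p, then lexicographic
    type name, so the assignment is deterministic.
    """
    sel = markers[markers["selected"]].copy()
    if sel.empty:
        return sel
    sel = sel.sort_values(
        ["gene", "median_target", "p", "cell_type"],
        ascending=[True, False, True, True],
    )
    return sel.drop_duplicates("gene", keep="first").reset_index(drop=True)


def build_expression_reference(
    sc: pd.DataFrame, labels, markers: pd.DataFrame
) -> ExpressionReference:
    """Assemble the expression reference from a marker table.

    The reference entry (g, k) is the median expression of marker g over
    all cells labeled k. Fewer than 100 markers triggers a warning (more
    markers make downstream fraction estimates more robust), never an error.
    """
    assigned = assign_marker_targets(markers) if "selected" in markers else markers
    if assigned.empty:
        raise ValueError("marker table contains no selected markers")
    labels = as_series_labels(labels, sc.columns, "cell labels")
    missing = set(assigned["gene"]) - set(sc.index)
    if missing:
        raise ValueError(f"marker gene(s) absent from expression matrix: {sorted(missing)[:5]}")
    genes = assigned["gene"].tolist()
    medians = _per_type_medians(sc.loc[genes], labels)
    if len(genes) < MIN_RECOMMENDED_MARKERS:
        warnings.warn(
            f"only {len(genes)} marker genes; at least "
            f"{MIN_RECOMMENDED_MARKERS} are recommended for stable deconvolution",
            UserWarning,
            stacklevel=2,
        )
    return ExpressionReference(
        values=medians,
        target_type=pd.Series(assigned["cell_type"].to_numpy(), index=genes),
        mss=pd.Series(assigned["mss"].to_numpy(), index=genes),
    )


class ExpressionReferenceBuilder(BaseEstimator):
    """Build a cell-type expression reference from labeled scRNA-seq data.

    Marker selection starts at perfect specificity (MSS = K - 1) and, when
    fewer than ``min_markers`` genes qualify, relaxes the MSS threshold one
    step at a time down to ceil((K - 1) / 2).

    Parameters
    ----------
    fdr : float
        BH-FDR threshold for the Wilcoxon marker test.
    mss_min : int or None
        Starting MSS threshold; None means K - 1.
    min_markers : int
        Target marker count driving the relaxation schedule.
    relax_mss : bool
        Disable to keep ``mss_min`` fixed.

    Attributes
    ----------
    marker_table_ : DataFrame
        Full per-(gene, type) scoring table.
    reference_ : ExpressionReference
        The fitted reference (medians over cells per type).
    mss_min_ : int
        The MSS threshold actually used after relaxation.
    """

    def __init__(
        self,
        fdr: float = 0.05,
        mss_min: int | None = None,
        min_markers: int = MIN_RECOMMENDED_MARKERS,
        relax_mss: bool = True,
    ):
        self.fdr = fdr
        self.mss_min = mss_min
        self.min_markers = min_markers
        self.relax_mss = relax_mss

    def fit(self, X: pd.DataFrame, y) -> "ExpressionReferenceBuilder":
        """Fit on a genes x cells matrix ``X`` with cell-type labels ``y``."""
        labels = as_series_labels(y, X.columns, "cell labels")
        K = labels.nunique()
        start = (K - 1) if self.mss_min is None else self.mss_min
        floor = math.ceil((K - 1) / 2)
        table = rank_markers(X, labels, mss_min=start, fdr=self.fdr)
        mss_min = start
        if self.relax_mss:
            while (
                assign_marker_targets(table).shape[0] < self.min_markers
                and mss_min > floor
            ):
                mss_min -= 1
                table["selected"] = (
                    (table["fdr"] < self.fdr)
                    & (table["mss"] >= mss_min)
                    & (table["median_target"] > 0)
                )
        self.mss_min_ = mss_min
        self.marker_table_ = table
        self.reference_ = build_expression_reference(X, labels, table)
        return self

    def score(self, X: pd.DataFrame, y) -> float:
        """Arg-max assignment accuracy of the reference on labeled cells."""
        res = validate_reference_on_cells(X, y, self.reference_)
        return res["accuracy"]


def validate_reference_on_cells(
    sc_val: pd.DataFrame,
    labels,
    ref: ExpressionReference,
    min_marker_frac: float = 0.3,
) -> dict:
    """Validate an expression reference in an independent scRNA-seq dataset.

    Each cell is decomposed against the reference with the (unweighted)
    robust-partial-correlation estimator and assigned the cell type with
    the largest estimated fraction. Accuracy is the share of cells whose
    arg-max type equals their annotated label; cells of types missing from
    the reference still receive an arg-max and can only be flagged through
    a low maximal fraction.

    Returns a dict with per-cell ``fractions``, ``accuracy``,
    ``per_type_accuracy`` and the ``confusion`` matrix (true type rows).
    """
    from .deconvolve import estimate_fractions  # local import avoids a cycle

    labels = as_series_labels(labels, sc_val.columns, "cell labels")
    overlap = ref.values.index.intersection(sc_val.index)
    if len(overlap) == 0:
        raise ValueError("no reference markers overlap the validation dataset")
    if len(overlap) < min_marker_frac * len(ref.values.index):
        raise ValueError(
            f"only {len(overlap)}/{len(ref.values.index)} reference markers "
            f"present in validation data (need >= {min_marker_frac:.0%})"
        )
    fractions = estimate_fractions(
        sc_val.loc[overlap], ref.values.loc[overlap], weights=None, robust=True
    )
    predicted = fractions.idxmax(axis=1)
    correct = predicted == labels
    confusion = pd.crosstab(labels, predicted).reindex(
        index=sorted(labels.unique()), columns=fractions.columns, fill_value=0
    )
    per_type = correct.groupby(labels).mean()
    return {
        "fractions": fractions,
        "accuracy": float(correct.mean()),
        "per_type_accuracy": per_type,
        "confusion": confusion,
    }
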
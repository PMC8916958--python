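"""Promoter-level DNAm reference derivation from single-nucleus methylomes.

Single-nucleus methylcytosine sequencing yields sparse Bernoulli calls
(0/1) per CpG and nucleus. CpGs covered in too few nuclei are dropped,
remaining calls are averaged over the TSS200 CpGs of each gene to give a
gene x nucleus beta matrix (mostly missing), and per cell type the genes
with the most convincingly hypomethylated promoters — Wilcoxon FDR < 0.05,
ranked by AUC, where AUC near 1 means lower methylation in the target
type — become that type's markers. The reference entry is the mean beta
over the non-missing nuclei of the type.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._validation import as_series_labels
from .containers import DNAmReference, SingleNucleusMethylome


def aggregate_nucleus_promoters(
    snm: SingleNucleusMethylome,
    cpg_map: pd.DataFrame,
    min_nuclei: int = 5,
) -> pd.DataFrame:
    """Aggregate CpG-level Bernoulli calls to gene x nucleus promoter betas.

    Parameters
    ----------
    snm : SingleNucleusMethylome
        Long-format calls (site_id, nucleus_id, call).
    cpg_map : DataFrame
        Columns ``site_id`` and ``gene`` assigning CpGs to gene TSS200
        regions.
    min_nuclei : int
        CpGs with reads in fewer than this many nuclei are dropped
        (default 5).

    Returns
    -------
    DataFrame
        Genes x nuclei mean Bernoulli beta; NaN where no CpG of the gene
        is covered in a nucleus.
    """
    if cpg_map is None or len(cpg_map) == 0:
        raise ValueError("CpG-to-gene map is empty")
    if not {"site_id", "gene"}.issubset(cpg_map.columns):
        raise ValueError("cpg_map needs columns site_id and gene")
    calls = snm.calls
    coverage = calls.groupby("site_id")["nucleus_id"].nunique()
    keep_sites = coverage.index[coverage >= min_nuclei]
    calls = calls[calls["site_id"].isin(keep_sites)]
    merged = calls.merge(cpg_map[["site_id", "gene"]], on="site_id", how="inner")
    if merged.empty:
        return pd.DataFrame(dtype=float)
    agg = merged.groupby(["gene", "nucleus_id"])["call"].mean()
    mat = agg.unstack("nucleus_id")
    # keep all labeled nuclei as columns even if entirely uncovered
    mat = mat.reindex(columns=snm.labels.index)
    return mat


def derive_snm_reference(
    gene_by_nucleus: pd.DataFrame,
    labels,
    top_n: int = 20,
    min_nonmissing: int = 10,
    fdr: float = 0.05,
) -> tuple[DNAmReference, pd.DataFrame]:
    """Select hypomethylation markers per cell type and build a reference.

    Per cell type, genes with at least ``min_nonmissing`` non-missing
    values in the target nuclei are tested (Wilcoxon, alternative: lower
    methylation in the target type); genes at FDR < ``fdr`` are ranked by
    AUC descending and the ``top_n`` best kept. The reference entry
    (g, k) is the mean beta of g over non-missing nuclei of type k, with
    unit weights.

    Returns the reference and the full marker AUC table.
    """
    labels = as_series_labels(labels, gene_by_nucleus.columns, "nucleus labels")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    values = gene_by_nucleus.to_numpy(dtype=float)
    records = []
    selected: dict[str, list[str]] = {}
    for t in types:
        in_t = (labels == t).to_numpy()
        x = values[:, in_t]
        z = values[:, ~in_t]
        n1 = (~np.isnan(x)).sum(axis=1)
        n2 = (~np.isnan(z)).sum(axis=1)
        eligible = (n1 >= min_nonmissing) & (n2 >= 1)
        if not eligible.any():
            warnings.warn(
                f"cell type {t!r}: no gene meets the coverage rule; "
                "empty marker list",
                UserWarning,
                stacklevel=2,
            )
            selected[t] = []
            continue
        xe, ze = x[eligible], z[eligible]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                xe, ze, axis=1, alternative="less", nan_policy="omit",
                method="asymptotic",
            )
        # U counts pairs (target > other) + half-ties, so lower target
        # methylation maps to AUC near 1
        u = np.asarray(res.statistic, dtype=float)
        auc = 1.0 - u / (n1[eligible] * n2[eligible])
        p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
        q = multipletests(p, method="fdr_bh")[1]
        sub = pd.DataFrame(
            {
                "gene": gene_by_nucleus.index[eligible],
                "cell_type": t,
                "p": p,
                "fdr": q,
                "auc": auc,
                "n_target": n1[eligible],
            }
        )
        records.append(sub)
        hits = sub[sub["fdr"] < fdr].sort_values(
            ["auc", "p", "gene"], ascending=[False, True, True]
        )
        selected[t] = hits["gene"].head(top_n).tolist()
        if not selected[t]:
            warnings.warn(
                f"cell type {t!r}: no gene passes FDR < {fdr}; empty marker list",
                UserWarning,
                stacklevel=2,
            )
    auc_table = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["gene", "cell_type", "p", "fdr", "auc", "n_target"])
    )
    marker_genes = sorted({g for genes in selected.values() for g in genes})
    if not marker_genes:
        raise ValueError("no marker gene selected for any cell type")
    means = gene_by_nucleus.loc[marker_genes].T.groupby(labels).mean().T
    means = means.clip(0.0, 1.0).fillna(0.5)  # uncovered entries: uninformative
    target = pd.Series(index=pd.Index(marker_genes), dtype=object)
    for t, genes in selected.items():
        for g in genes:
            if pd.isna(target.get(g)):
                target[g] = t
    ref = DNAmReference(values=means, weights=None, target_type=target)
    return ref, auc_table


def marker_hypomethylation_test(
    gene_by_nucleus: pd.DataFrame,
    labels,
    dnam_ref: DNAmReference,
) -> pd.DataFrame:
    """Test each reference marker for promoter hypomethylation in its own type.

    Per marker, a one-tailed Welch t-test compares promoter betas of
    nuclei in the marker's own cell type against all others (alternative:
    lower in the own type, negative t), followed by BH-FDR across markers.
    """
    labels = as_series_labels(labels, gene_by_nucleus.columns, "nucleus labels")
    if dnam_ref.target_type is None:
        raise ValueError("reference carries no marker-to-cell-type assignment")
    rows = []
    for g, t in dnam_ref.target_type.items():
        if g not in gene_by_nucleus.index or pd.isna(t):
            continue
        vals = gene_by_nucleus.loc[g]
        x = vals[labels == t].dropna().to_numpy(dtype=float)
        z = vals[labels != t].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(z) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(x, z, equal_var=False, alternative="less")
        tstat = float(res.statistic) if np.isfinite(res.statistic) else 0.0
        p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        rows.append({"gene": g, "cell_type": t, "t": tstat, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no marker had enough non-missing values to test")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def compare_references(
    ref_a: DNAmReference,
    ref_b: DNAmReference,
    n_mc: int = 1000,
    seed: int = 0,
    min_shared: int = 10,
    exhaustive: bool = False,
) -> dict:
    """Compare two references over their shared (gene, cell type) entries.

    Reports the median absolute deviation (MAD) and Pearson correlation
    (PCC) plus Monte-Carlo permutation p-values: the null permutes the
    gene rows of the second reference (preserving each cell type's
    marginal distribution), and p = (1 + #null at least as extreme) /
    (1 + n_mc), so p is never zero. Low MAD and high PCC are the extreme
    directions. With ``exhaustive=True`` (feasible only for a handful of
    genes) all row permutations are enumerated instead of sampled and the
    p-value is the exact fraction of permutations at least as extreme.
    """
    genes = ref_a.values.index.intersection(ref_b.values.index)
    types = ref_a.values.columns.intersection(ref_b.values.columns)
    if len(genes) < min_shared:
        raise ValueError(
            f"only {len(genes)} shared markers; need at least {min_shared}"
        )
    A = ref_a.values.loc[genes, types].to_numpy(dtype=float)
    B = ref_b.values.loc[genes, types].to_numpy(dtype=float)

    def _mad(a, b):
        return float(np.median(np.abs(a - b)))

    def _pcc(a, b):
        return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])

    mad_obs = _mad(A, B)
    pcc_obs = _pcc(A, B)
    if exhaustive:
        from itertools import permutations

        perms = list(permutations(range(len(genes))))
        mad_null = np.array([_mad(A, B[list(p)]) for p in perms])
        pcc_null = np.array([_pcc(A, B[list(p)]) for p in perms])
        p_mad = np.mean(mad_null <= mad_obs)
        p_pcc = np.mean(pcc_null >= pcc_obs)
        n_mc = len(perms)
    else:
        rng = np.random.default_rng(seed)
        mad_null = np.empty(n_mc)
        pcc_null = np.empty(n_mc)
        for i in range(n_mc):
            perm = rng.permutation(len(genes))
            mad_null[i] = _mad(A, B[perm])
            pcc_null[i] = _pcc(A, B[perm])
        p_mad = (1 + np.sum(mad_null <= mad_obs)) / (1 + n_mc)
        p_pcc = (1 + np.sum(pcc_null >= pcc_obs)) / (1 + n_mc)
    return {
        "mad": mad_obs,
        "pcc": pcc_obs,
        "p_mad": float(p_mad),
        "p_pcc": float(p_pcc),
        "n_shared": int(len(genes)),
        "n_mc": int(n_mc),
    }


class SnmReferenceBuilder(BaseEstimator):
    """Derive a DNAm reference from a gene x nucleus beta matrix.

    Attributes after ``fit``: ``reference_`` (unit-weight
    :class:`DNAmReference` with marker target types) and ``auc_table_``.
    """

    def __init__(
        self,
        top_n: int = 20,
        min_nonmissing: int = 10,
        fdr: float = 0.05,
        min_nuclei: int = 5,
    ):
        self.top_n = top_n
        self.min_nonmissing = min_nonmissing
        self.fdr = fdr
        self.min_nuclei = min_nuclei

    def fit(self, X, y, cpg_map: pd.DataFrame | None = None) -> "SnmReferenceBuilder":
        """Fit from a gene x nucleus matrix (or raw calls plus ``cpg_map``)."""
        if isinstance(X, SingleNucleusMethylome):
            if cpg_map is None:
                raise ValueError("cpg_map required for raw single-nucleus calls")
            X = aggregate_nucleus_promoters(X, cpg_map, min_nuclei=self.min_nuclei)
        self.reference_, self.auc_table_ = derive_snm_reference(
            X,
            y,
            top_n=self.top_n,
            min_nonmissing=self.min_nonmissing,
            fdr=self.fdr,
        )
        return self
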
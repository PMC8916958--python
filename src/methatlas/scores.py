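"""Sample-level scores derived from cell-type fractions and references.

Tumor purity is one minus the summed stromal fractions (immune,
endothelial and fibroblast cell types, typically); the total immune score
is the summed immune fractions. The two-phenotype proxy builds a small
marker panel (differentiated versus proliferative smooth muscle cells is
the motivating case) whose mean TSS200 promoter methylation in a bulk
sample tracks the fraction of the *other* phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._validation import as_series_labels


def _check_group(fractions: pd.DataFrame, group, what: str) -> list[str]:
    group = list(group)
    missing = [g for g in group if g not in fractions.columns]
    if missing:
        raise ValueError(f"{what} cell type(s) not in fraction matrix: {missing}")
    return group


def tumor_purity(fractions: pd.DataFrame, stromal) -> pd.Series:
    """Tumor purity index: 1 - sum of stromal fractions, clipped to [0, 1].

    ``stromal`` names the cell types defining the tumor stroma (typically
    all immune cells, endothelial cells and fibroblasts).
    """
    stromal = _check_group(fractions, stromal, "stromal")
    purity = 1.0 - fractions[stromal].sum(axis=1)
    return purity.clip(0.0, 1.0).rename("tumor_purity")


def immune_score(fractions: pd.DataFrame, immune) -> pd.Series:
    """Total immune cell score: sum of the immune cell-type fractions."""
    immune = _check_group(fractions, immune, "immune")
    if not immune:
        warnings.warn("empty immune group; score is 0", UserWarning, stacklevel=2)
        return pd.Series(0.0, index=fractions.index, name="immune_score")
    return fractions[immune].sum(axis=1).rename("immune_score")


@dataclass
class ProxyMarkerPanel:
    """Marker panel whose mean promoter beta proxies a phenotype fraction.

    ``evidence`` records, per kept marker, the promoter beta in each of
    the other cell types used for the hypermethylation-exclusion rule.
    ``direction`` documents the sign convention: higher panel methylation
    means a *lower* fraction of the phenotype the markers belong to.
    """

    genes: list[str]
    evidence: pd.DataFrame
    beta_thresh: float
    min_other: int
    phenotype: str = "phenotype-A"
    direction: str = field(
        default="higher mean panel beta = lower fraction of the marker phenotype"
    )


def build_proxy_panel(
    markers,
    other_type_betas: pd.DataFrame,
    beta_thresh: float = 0.6,
    min_other: int = 3,
    phenotype: str = "phenotype-A",
) -> ProxyMarkerPanel:
    """Filter phenotype markers by hypermethylation in the other cell types.

    Keeps markers whose promoter beta exceeds ``beta_thresh`` in at least
    ``min_other`` of the other cell types' profiles, which guards the
    proxy against contamination by those cell types. Raising the threshold
    can only shrink the panel.
    """
    markers = [m for m in markers]
    present = [m for m in markers if m in other_type_betas.index]
    sub = other_type_betas.loc[present]
    n_high = (sub > beta_thresh).sum(axis=1)
    kept = sub.index[n_high >= min_other].tolist()
    if not kept:
        raise ValueError(
            "no marker passes the hypermethylation-exclusion rule; consider "
            f"relaxing beta_thresh (={beta_thresh}) or min_other (={min_other})"
        )
    return ProxyMarkerPanel(
        genes=kept,
        evidence=sub.loc[kept].copy(),
        beta_thresh=beta_thresh,
        min_other=min_other,
        phenotype=phenotype,
    )


def proxy_score(promoter_betas: pd.DataFrame, panel: ProxyMarkerPanel) -> pd.Series:
    """Mean TSS200 promoter beta over the panel genes, per sample."""
    present = [g for g in panel.genes if g in promoter_betas.index]
    if not present:
        raise ValueError("no panel gene present in the promoter beta matrix")
    return promoter_betas.loc[present].mean(axis=0).rename("proxy_score")


def two_phenotype_markers(
    sc: pd.DataFrame,
    labels,
    type_a: str,
    type_b: str,
    fdr: float = 0.05,
) -> dict[str, list[str]]:
    """Differential markers between two phenotypes of the same cell type.

    Genes with Wilcoxon BH-FDR < ``fdr`` and median expression above zero
    in one phenotype and exactly zero in the other; returns the two marker
    lists keyed by phenotype label.
    """
    labels = as_series_labels(labels, sc.columns, "cell labels")
    a_cells = labels == type_a
    b_cells = labels == type_b
    if a_cells.sum() < 2 or b_cells.sum() < 2:
        raise ValueError("both phenotypes need at least two cells")
    xa = sc.loc[:, a_cells.to_numpy()].to_numpy(dtype=float)
    xb = sc.loc[:, b_cells.to_numpy()].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            xa.T, xb.T, axis=0, alternative="two-sided", method="asymptotic"
        )
    p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    med_a = np.median(xa, axis=1)
    med_b = np.median(xb, axis=1)
    sig = q < fdr
    out = {
        type_a: sc.index[sig & (med_a > 0) & (med_b == 0)].tolist(),
        type_b: sc.index[sig & (med_b > 0) & (med_a == 0)].tolist(),
    }
    return out
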
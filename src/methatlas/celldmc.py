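"""Cell-type-specific differential methylation via interaction models.

For each CpG site c, the beta-value vector across samples is modeled as

    beta_c = sum_k mu_ck f_k + sum_k b_ck f_k * y + covariates + noise

where f_k are the estimated cell-type fractions and y the binary
phenotype. The interaction coefficient b_ck captures the phenotype-
associated methylation change *within* cell type k; a site is a DMCT
(differentially methylated cytosine in cell type k) when the BH-adjusted
p-value of b_ck falls below the FDR threshold, with direction given by
the coefficient's sign. There is no global intercept: the fraction terms
absorb it because fractions sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._validation import check_beta_range, check_unique_index


@dataclass
class DMCTResult:
    """Per-site, per-cell-type interaction-model results.

    All frames are sites x cell types unless noted. ``dmct`` holds
    -1 (hypomethylated in cases), 0 (not significant) or +1
    (hypermethylated in cases).
    """

    baseline: pd.DataFrame          # mu_ck
    interaction: pd.DataFrame       # b_ck
    tstats: pd.DataFrame
    pvals: pd.DataFrame
    fdr: pd.DataFrame               # BH per cell type across sites
    dmct: pd.DataFrame
    covariate_coefs: pd.DataFrame   # sites x covariate columns
    fdr_threshold: float

    def n_dmct(self) -> pd.Series:
        """Number of DMCTs per cell type."""
        return (self.dmct != 0).sum(axis=0)


def _build_design(
    fractions: pd.DataFrame, y: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    K = fractions.shape[1]
    frac = fractions.to_numpy(dtype=float)
    cols = [frac, frac * y[:, None]]
    base_names = [str(c) for c in fractions.columns]
    inter_names = [f"{c}:y" for c in fractions.columns]
    cov_names: list[str] = []
    if covariates is not None and covariates.shape[1] > 0:
        # one-hot encode categoricals dropping the first level
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        cols.append(enc.to_numpy(dtype=float))
        cov_names = [str(c) for c in enc.columns]
    X = np.hstack(cols)
    return X, base_names, inter_names, cov_names


def call_dmcts(
    betas: pd.DataFrame,
    fractions: pd.DataFrame,
    y,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> DMCTResult:
    """Fit the interaction model at every site and flag DMCTs.

    Parameters
    ----------
    betas : DataFrame
        Sites x samples beta matrix in [0, 1].
    fractions : DataFrame
        Samples x cell-type estimated fractions (rows sum to one).
    y : array-like
        Binary phenotype per sample (0 = control, 1 = case); both classes
        must be present.
    covariates : DataFrame, optional
        Samples x covariates; categorical columns are one-hot encoded
        dropping one level.
    fdr : float
        BH-FDR threshold for calling DMCTs, applied per cell type.
    """
    check_unique_index(betas, "beta matrix")
    check_beta_range(betas, "beta matrix")
    if not betas.columns.equals(fractions.index):
        fractions = fractions.reindex(betas.columns)
        if fractions.isna().any().any():
            raise ValueError("fractions are not aligned to the beta samples")
    y = np.asarray(pd.Series(y).reindex(betas.columns) if isinstance(y, pd.Series) else y)
    y = y.astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype is constant; both classes are required")
    if covariates is not None:
        covariates = covariates.reindex(betas.columns)

    X, base_names, inter_names, cov_names = _build_design(fractions, y, covariates)
    n, p = X.shape
    K = fractions.shape[1]
    if n <= p:
        raise ValueError(
            f"need more samples ({n}) than model parameters ({p}); "
            "the model has 2K fraction terms plus covariates"
        )
    low_var = fractions.var(axis=0) < 1e-10
    if low_var.any():
        warnings.warn(
            "cell type(s) with near-zero fraction variance: "
            f"{list(fractions.columns[low_var])}; their coefficients are "
            "poorly identified",
            UserWarning,
            stacklevel=2,
        )

    B = betas.to_numpy(dtype=float)  # sites x n
    xtx_inv = np.linalg.pinv(X.T @ X)
    coefs = B @ X @ xtx_inv  # sites x p
    resid = B - coefs @ X.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coefs / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    sites = betas.index
    types = fractions.columns
    inter_idx = slice(K, 2 * K)
    interaction = pd.DataFrame(coefs[:, inter_idx], index=sites, columns=types)
    tstats = pd.DataFrame(tvals[:, inter_idx], index=sites, columns=types)
    pv = pd.DataFrame(pvals[:, inter_idx], index=sites, columns=types)
    qv = pv.copy()
    for c in types:
        qv[c] = multipletests(pv[c].to_numpy(), method="fdr_bh")[1]
    flags = pd.DataFrame(0, index=sites, columns=types, dtype=int)
    sig = qv < fdr
    flags[sig & (interaction > 0)] = 1
    flags[sig & (interaction < 0)] = -1
    n_cov = len(cov_names)
    cov_coefs = pd.DataFrame(
        coefs[:, 2 * K : 2 * K + n_cov], index=sites, columns=cov_names
    )
    return DMCTResult(
        baseline=pd.DataFrame(coefs[:, :K], index=sites, columns=types),
        interaction=interaction,
        tstats=tstats,
        pvals=pv,
        fdr=qv,
        dmct=flags,
        covariate_coefs=cov_coefs,
        fdr_threshold=fdr,
    )


class CellDMC(BaseEstimator):
    """Interaction-model DMCT caller as an estimator.

    ``fit(betas, y, fractions=..., covariates=...)`` stores a
    :class:`DMCTResult` in ``result_``; convenience accessors expose the
    DMCT flags and counts.
    """

    def __init__(self, fdr: float = 0.05):
        self.fdr = fdr

    def fit(
        self,
        X: pd.DataFrame,
        y,
        fractions: pd.DataFrame = None,
        covariates: pd.DataFrame | None = None,
    ) -> "CellDMC":
        if fractions is None:
            raise ValueError("fractions are required")
        self.result_ = call_dmcts(X, fractions, y, covariates=covariates, fdr=self.fdr)
        return self

    @property
    def dmct_(self) -> pd.DataFrame:
        return self.result_.dmct


@dataclass
class LociSet:
    """Named locus sets (e.g. GWAS risk loci) against a background universe."""

    loci: dict[str, set]
    background: set

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background universe is empty")
        for name, members in self.loci.items():
            extra = set(members) - self.background
            if extra:
                raise ValueError(
                    f"locus set {name!r} has members outside the background: "
                    f"{sorted(extra)[:5]}"
                )


def fisher_enrichment(hits, locus_members, background) -> tuple[float, float]:
    """One-tailed Fisher's exact test for overenrichment of hits in a locus set.

    Builds the 2x2 table (hit / non-hit) x (in-locus / not in-locus) over
    the background universe and returns the sample odds ratio ad/bc and
    the hypergeometric one-tailed p-value for overrepresentation.
    """
    background = set(background)
    if not background:
        raise ValueError("background universe is empty")
    hits = set(hits)
    if hits - background:
        raise ValueError("hits must be a subset of the background")
    locus = set(locus_members) & background
    a = len(hits & locus)
    b = len(hits - locus)
    c = len(locus - hits)
    d = len(background) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def enrich_loci(hits, loci: LociSet) -> pd.DataFrame:
    """Fisher overenrichment of ``hits`` in every named locus set."""
    rows = []
    for name, members in loci.loci.items():
        odds, p = fisher_enrichment(hits, members, loci.background)
        rows.append({"locus_set": name, "odds_ratio": odds, "p": p,
                     "n_overlap": len(set(hits) & set(members))})
    return pd.DataFrame(rows)
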
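"""Imputation of a promoter-DNAm reference matrix from an expression reference.

Only *imputable* marker genes are retained: genes whose promoter
methylation and expression are anticorrelated in two independent matched
compendia. For such a gene, cell types where it is expressed get promoter
beta zero (high expression implies an unmethylated promoter); cell types
where it is silent get the mean of the high-methylation component of a
two-state gamma mixture fitted to the gene's compendium beta values in
low-expression samples. Each marker then receives a confidence weight —
the average imputed beta over its non-expressing cell types — so markers
whose silent-state promoters are convincingly methylated count more in
downstream deconvolution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import DNAmReference, ExpressionReference, MatchedCompendium
from .gamma_mixture import TwoGammaMixture

logger = logging.getLogger(__name__)

DEFAULT_RHO_MAX = -0.3
ZERO_SHIFT_EPS = 1e-4


def select_imputable(
    markers,
    comp_a: MatchedCompendium,
    comp_b: MatchedCompendium,
    rho_max: float = DEFAULT_RHO_MAX,
) -> list[str]:
    """Select marker genes with anticorrelated promoter DNAm and expression.

    A gene is imputable when its Pearson correlation between promoter beta
    and expression is <= ``rho_max`` (default -0.3) in *both* compendia.
    Genes absent from a compendium are excluded with a logged reason.
    """
    if rho_max >= 0:
        raise ValueError("rho_max must be negative (anticorrelation threshold)")
    markers = list(markers)
    if not (set(markers) & set(comp_a.genes)) or not (set(markers) & set(comp_b.genes)):
        raise ValueError("markers do not overlap one of the compendia")
    keep = []
    for g in markers:
        rs = []
        absent = False
        for comp in (comp_a, comp_b):
            if g not in comp.genes:
                logger.info("gene %s absent from %s; not imputable", g, comp.name)
                absent = True
                break
            e = comp.expression.loc[g].to_numpy(dtype=float)
            b = comp.beta.loc[g].to_numpy(dtype=float)
            ok = ~(np.isnan(e) | np.isnan(b))
            if ok.sum() < 3 or np.std(e[ok]) == 0 or np.std(b[ok]) == 0:
                logger.info("gene %s: degenerate compendium values in %s", g, comp.name)
                absent = True
                break
            rs.append(float(np.corrcoef(e[ok], b[ok])[0, 1]))
        if not absent and all(r <= rho_max for r in rs):
            keep.append(g)
    return keep


def _gene_betas(gene: str, compendia: list[MatchedCompendium]) -> np.ndarray:
    """Pool a gene's promoter beta values across the compendia.

    The full cross-sample distribution is what the two-state mixture
    needs: samples expressing the gene contribute the low-methylation
    state, silent samples the high-methylation state.
    """
    pools = []
    for comp in compendia:
        if gene not in comp.genes:
            continue
        b = comp.beta.loc[gene].to_numpy(dtype=float)
        pools.append(b[~np.isnan(b)])
    if not pools:
        return np.empty(0)
    return np.concatenate(pools)


def impute_dnam_reference(
    expr_ref: ExpressionReference,
    imputable,
    compendia,
    min_samples: int = 20,
    seed: int = 0,
    em_max_iter: int = 500,
    em_tol: float = 1e-8,
) -> DNAmReference:
    """Impute the promoter-DNAm reference for the imputable markers.

    Entry (g, k) is exactly 0 where the expression reference has g
    expressed in k; otherwise it is the mean of the high-methylation
    component of a two-state gamma mixture fitted to g's pooled
    cross-sample compendium betas, clipped to [0, 1]. Markers with too
    few compendium samples for the mixture fit are dropped with a logged
    reason. Weights are attached by :func:`compute_weights`.
    """
    imputable = [g for g in imputable if g in expr_ref.values.index]
    if not imputable:
        raise ValueError("imputable marker set is empty")
    compendia = list(compendia)
    rows: dict[str, np.ndarray] = {}
    types = expr_ref.cell_types
    for g in imputable:
        expressed = expr_ref.values.loc[g].to_numpy(dtype=float) > 0
        if expressed.all():
            # expressed everywhere: all-zero row, no mixture fit needed
            rows[g] = np.zeros(len(types))
            continue
        betas = _gene_betas(g, compendia)
        betas = np.clip(betas, 0.0, 1.0) + ZERO_SHIFT_EPS  # gamma support is (0, inf)
        if betas.size < min_samples:
            logger.info(
                "marker %s dropped: only %d compendium samples for mixture fit",
                g,
                betas.size,
            )
            continue
        try:
            fit = TwoGammaMixture(
                max_iter=em_max_iter, tol=em_tol, random_state=seed
            ).fit(betas)
            silent = float(np.clip(fit.means_[1], 0.0, 1.0))
        except ValueError as exc:
            logger.info("marker %s dropped: mixture fit failed (%s)", g, exc)
            continue
        row = np.where(expressed, 0.0, silent)
        rows[g] = row
    if not rows:
        raise ValueError("no marker survived imputation")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=types)
    values = values.loc[[g for g in imputable if g in rows]]
    ref = DNAmReference(
        values=values,
        weights=None,
        target_type=expr_ref.target_type.reindex(values.index),
    )
    ref.weights = compute_weights(ref, expr_ref)
    return ref


def compute_weights(dnam_ref: DNAmReference, expr_ref: ExpressionReference) -> pd.Series:
    """Per-marker confidence weights from the imputed silent-state betas.

    weight(g) = mean imputed beta over the cell types where g is not
    expressed, clipped to [0, 1]; markers expressed in every type carry
    weight 1 (there is no silent state to judge them by).
    """
    weights = {}
    for g in dnam_ref.values.index:
        expressed = expr_ref.values.loc[g].reindex(dnam_ref.cell_types) > 0
        silent = dnam_ref.values.loc[g][~expressed]
        weights[g] = 1.0 if silent.empty else float(np.clip(silent.mean(), 0.0, 1.0))
    return pd.Series(weights).reindex(dnam_ref.values.index)


class DNAmImputer(BaseEstimator):
    """Impute a weighted promoter-DNAm reference from an expression reference.

    Parameters mirror :func:`select_imputable` and
    :func:`impute_dnam_reference`.

    Attributes
    ----------
    imputable_ : list of str
        Markers passing the anticorrelation screen in both compendia.
    reference_ : DNAmReference
        Imputed reference with per-marker confidence weights.
    """

    def __init__(
        self,
        rho_max: float = DEFAULT_RHO_MAX,
        min_samples: int = 20,
        em_max_iter: int = 500,
        em_tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.rho_max = rho_max
        self.min_samples = min_samples
        self.em_max_iter = em_max_iter
        self.em_tol = em_tol
        self.random_state = random_state

    def fit(
        self,
        expr_ref: ExpressionReference,
        comp_a: MatchedCompendium,
        comp_b: MatchedCompendium,
    ) -> "DNAmImputer":
        self.imputable_ = select_imputable(
            expr_ref.values.index, comp_a, comp_b, rho_max=self.rho_max
        )
        self.reference_ = impute_dnam_reference(
            expr_ref,
            self.imputable_,
            [comp_a, comp_b],
            min_samples=self.min_samples,
            seed=self.random_state,
            em_max_iter=self.em_max_iter,
            em_tol=self.em_tol,
        )
        return self
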
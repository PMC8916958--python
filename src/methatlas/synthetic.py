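"""Synthetic data with known ground truth for every input kind.

The default regime mirrors a brain-like deconvolution study: K = 6 cell
types, 100 markers per type (600 total), bulk mixtures with Dirichlet(1)
fractions and truncated-Gaussian beta noise (sd 0.05), matched
DNAm/expression compendia where a fraction of genes is anticorrelated
with a high-methylation silent state, single-nucleus methylomes with 90%
missing calls, and an interaction-model EWAS with planted cell-type-
specific effects. Every generator is a pure function of its config and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import DNAmReference, MatchedCompendium, SingleNucleusMethylome


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; all generators take one of these.

    ``seed`` is mandatory: generators are deterministic given the config.
    """

    seed: int
    n_cell_types: int = 6
    markers_per_type: int = 100
    n_background_genes: int = 400
    cells_per_type: int = 100
    n_mixtures: int = 200
    dirichlet_alpha: float = 1.0
    beta_noise_sd: float = 0.05
    coverage: float = 0.1               # single-nucleus call rate -> 90% missing
    nuclei_per_type: int = 300
    cpgs_per_gene: int = 3
    n_compendium_samples: int = 120
    own_type_beta: float = 0.1          # marker promoter beta in its own type
    other_type_beta: float = 0.9        # ... and in the other types
    silent_state_beta: float = 0.8      # compendium high-methylation state mean
    n_ewas_samples: int = 200
    n_ewas_sites: int = 1000
    n_effect_sites: int = 50
    interaction_effect: float = 0.2
    ewas_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "n_cell_types",
            "markers_per_type",
            "n_background_genes",
            "cells_per_type",
            "n_mixtures",
            "nuclei_per_type",
            "cpgs_per_gene",
            "n_compendium_samples",
            "n_ewas_samples",
            "n_ewas_sites",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{k + 1}" for k in range(self.n_cell_types)]

    @property
    def marker_genes(self) -> list[str]:
        return [
            f"M{k + 1}_{i + 1}"
            for k in range(self.n_cell_types)
            for i in range(self.markers_per_type)
        ]

    @property
    def background_genes(self) -> list[str]:
        return [f"BG{i + 1}" for i in range(self.n_background_genes)]

    def marker_truth(self) -> pd.Series:
        """Planted marker gene -> its cell type."""
        return pd.Series(
            {
                f"M{k + 1}_{i + 1}": self.cell_types[k]
                for k in range(self.n_cell_types)
                for i in range(self.markers_per_type)
            }
        )


def simulate_sc_counts(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate an annotated scRNA-seq count matrix with planted markers.

    Planted markers are negative-binomial expressed only in their own
    type and exactly zero elsewhere, so their cross-type median vector
    has K - 1 zeros by construction (true MSS = K - 1); background genes
    are expressed in every type.

    Returns (counts genes x cells, cell labels, marker truth).
    """
    rng = np.random.default_rng(cfg.seed)
    types = cfg.cell_types
    cells = [
        f"C{k + 1}_{i + 1}"
        for k in range(cfg.n_cell_types)
        for i in range(cfg.cells_per_type)
    ]
    labels = pd.Series(
        np.repeat(types, cfg.cells_per_type), index=cells, name="cell_type"
    )
    genes = cfg.marker_genes + cfg.background_genes
    counts = np.zeros((len(genes), len(cells)), dtype=np.int64)

    def nb(mean: float, size) -> np.ndarray:
        # dispersion r = 2; p = r / (r + mean)
        r = 2.0
        return rng.negative_binomial(r, r / (r + mean), size=size)

    for k in range(cfg.n_cell_types):
        rows = slice(k * cfg.markers_per_type, (k + 1) * cfg.markers_per_type)
        cols = slice(k * cfg.cells_per_type, (k + 1) * cfg.cells_per_type)
        counts[rows, cols] = nb(5.0, (cfg.markers_per_type, cfg.cells_per_type))
    n_markers = cfg.n_cell_types * cfg.markers_per_type
    counts[n_markers:, :] = nb(2.0, (cfg.n_background_genes, len(cells)))
    sc = pd.DataFrame(counts, index=genes, columns=cells)
    return sc, labels, cfg.marker_truth()


def simulate_compendium(
    cfg: SimulationConfig,
    frac_anticorrelated: float = 0.2,
    genes: list[str] | None = None,
) -> tuple[MatchedCompendium, MatchedCompendium, pd.DataFrame]:
    """Simulate two matched DNAm/expression compendia.

    A fraction of genes is *anticorrelated*: roughly half the samples are
    transcriptionally off with promoter betas drawn from a concentrated
    high-methylation gamma state (mean ``silent_state_beta``) while the
    expressed half has near-zero promoter betas, yielding strong negative
    expression-methylation correlation. The remaining genes have
    expression-independent mid-range betas. The two compendia are drawn
    independently with the same gene truth.

    Returns (compendium A, compendium B, truth) where truth has per-gene
    columns ``anticorrelated`` and ``silent_beta``.
    """
    if genes is None:
        genes = cfg.marker_genes
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(genes)
    n_anti = int(round(frac_anticorrelated * n))
    anti = np.zeros(n, dtype=bool)
    anti[rng.choice(n, size=n_anti, replace=False)] = True
    truth = pd.DataFrame(
        {"anticorrelated": anti, "silent_beta": np.where(anti, cfg.silent_state_beta, np.nan)},
        index=genes,
    )

    def one(name: str, sub_rng: np.random.Generator) -> MatchedCompendium:
        m = cfg.n_compendium_samples
        expr = np.empty((n, m))
        beta = np.empty((n, m))
        for i in range(n):
            if anti[i]:
                off = np.zeros(m, dtype=bool)
                off[sub_rng.choice(m, size=m // 2, replace=False)] = True
                expr[i, off] = sub_rng.exponential(0.05, size=off.sum())
                expr[i, ~off] = sub_rng.lognormal(np.log(5.0), 0.3, size=(~off).sum())
                # silent state: concentrated gamma around silent_state_beta
                shape = 80.0
                beta[i, off] = sub_rng.gamma(
                    shape, cfg.silent_state_beta / shape, size=off.sum()
                )
                beta[i, ~off] = sub_rng.gamma(4.0, 0.1 / 4.0, size=(~off).sum())
            else:
                expr[i] = sub_rng.lognormal(np.log(2.0), 0.5, size=m)
                beta[i] = sub_rng.beta(2.0, 2.0, size=m)
        beta = np.clip(beta, 0.0, 1.0)
        cols = [f"{name}_S{j + 1}" for j in range(m)]
        return MatchedCompendium(
            expression=pd.DataFrame(expr, index=genes, columns=cols),
            beta=pd.DataFrame(beta, index=genes, columns=cols),
            name=name,
        )

    comp_a = one("compA", np.random.default_rng(cfg.seed + 2))
    comp_b = one("compB", np.random.default_rng(cfg.seed + 3))
    return comp_a, comp_b, truth


def planted_dnam_reference(
    cfg: SimulationConfig, include_background: bool = False
) -> DNAmReference:
    """Block-structured ground-truth DNAm reference.

    Marker promoters have beta ``own_type_beta`` (default 0.1) in their
    own cell type and ``other_type_beta`` (default 0.9) elsewhere.
    Optionally append background genes with a per-gene constant beta
    across types (hypomethylated nowhere), used by the single-nucleus
    simulations.
    """
    K = cfg.n_cell_types
    types = cfg.cell_types
    values = np.full((K * cfg.markers_per_type, K), cfg.other_type_beta)
    for k in range(K):
        rows = slice(k * cfg.markers_per_type, (k + 1) * cfg.markers_per_type)
        values[rows, k] = cfg.own_type_beta
    index = cfg.marker_genes
    target = cfg.marker_truth()
    if include_background:
        rng = np.random.default_rng(cfg.seed + 4)
        bg = np.repeat(
            rng.uniform(0.3, 0.7, size=cfg.n_background_genes)[:, None], K, axis=1
        )
        values = np.vstack([values, bg])
        index = index + cfg.background_genes
        target = pd.concat(
            [target, pd.Series(np.nan, index=cfg.background_genes)]
        )
    return DNAmReference(
        values=pd.DataFrame(values, index=index, columns=types),
        weights=None,
        target_type=target,
    )


def simulate_bulk_mixtures(
    ref: DNAmReference, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mix reference profiles with Dirichlet fractions plus beta noise.

    Returns (bulk genes x samples, true fractions samples x types); the
    noise is additive Gaussian (sd ``beta_noise_sd``) truncated to the
    unit interval by clipping.
    """
    rng = np.random.default_rng(cfg.seed + 5)
    K = ref.values.shape[1]
    f = rng.dirichlet(np.full(K, cfg.dirichlet_alpha), size=cfg.n_mixtures)
    mix = ref.values.to_numpy(dtype=float) @ f.T
    if cfg.beta_noise_sd > 0:
        mix = mix + rng.normal(0.0, cfg.beta_noise_sd, size=mix.shape)
    mix = np.clip(mix, 0.0, 1.0)
    samples = [f"Mix{j + 1}" for j in range(cfg.n_mixtures)]
    bulk = pd.DataFrame(mix, index=ref.values.index, columns=samples)
    fractions = pd.DataFrame(f, index=samples, columns=ref.values.columns)
    return bulk, fractions


def simulate_snm(
    ref: DNAmReference, cfg: SimulationConfig
) -> tuple[SingleNucleusMethylome, pd.DataFrame]:
    """Simulate sparse single-nucleus Bernoulli methylation calls.

    Each gene gets ``cpgs_per_gene`` TSS200 CpGs; for a nucleus of type
    k, each CpG call is Bernoulli(reference beta of the gene in k) and is
    observed with probability ``coverage`` (default 0.1, i.e. 90%
    missingness).

    Returns (methylome, CpG-to-gene map).
    """
    rng = np.random.default_rng(cfg.seed + 6)
    genes = list(ref.values.index)
    types = list(ref.values.columns)
    n_sites = len(genes) * cfg.cpgs_per_gene
    site_ids = np.array(
        [f"{g}_cpg{j + 1}" for g in genes for j in range(cfg.cpgs_per_gene)]
    )
    site_gene = np.repeat(genes, cfg.cpgs_per_gene)
    nuclei = [
        f"N{k + 1}_{i + 1}"
        for k in range(len(types))
        for i in range(cfg.nuclei_per_type)
    ]
    labels = pd.Series(np.repeat(types, cfg.nuclei_per_type), index=nuclei)

    beta_site = ref.values.to_numpy(dtype=float)[
        np.repeat(np.arange(len(genes)), cfg.cpgs_per_gene)
    ]  # sites x K
    type_idx = np.repeat(np.arange(len(types)), cfg.nuclei_per_type)
    prob = beta_site[:, type_idx]  # sites x nuclei
    observed = rng.random((n_sites, len(nuclei))) < cfg.coverage
    calls = (rng.random((n_sites, len(nuclei))) < prob).astype(np.int8)
    si, ni = np.nonzero(observed)
    long = pd.DataFrame(
        {
            "site_id": site_ids[si],
            "nucleus_id": np.asarray(nuclei, dtype=object)[ni],
            "call": calls[si, ni].astype(np.int64),
        }
    )
    cpg_map = pd.DataFrame({"site_id": site_ids, "gene": site_gene})
    snm = SingleNucleusMethylome(calls=long, labels=labels)
    return snm, cpg_map


@dataclass
class EWASDataset:
    """Aligned inputs for the interaction-model differential analysis."""

    betas: pd.DataFrame              # sites x samples
    fractions: pd.DataFrame          # samples x cell types
    y: pd.Series                     # binary phenotype
    covariates: pd.DataFrame | None = None


def simulate_ewas(
    true_fractions: pd.DataFrame | None,
    cfg: SimulationConfig,
    effect_type: int = 0,
) -> tuple[EWASDataset, pd.DataFrame]:
    """Simulate an EWAS from the interaction generative model.

    Betas follow beta_c = sum_k mu_ck f_k + sum_k b_ck f_k y + gamma*age
    + eps with i.i.d. Gaussian eps (sd ``ewas_noise_sd``), clipped to
    [0, 1]. The first ``n_effect_sites`` sites carry a planted
    interaction effect ``interaction_effect`` in cell type
    ``effect_type`` only; with ``n_effect_sites = 0`` the truth table is
    empty (a null simulation).

    Returns (dataset, truth) where truth lists (site, cell_type, effect).
    """
    rng = np.random.default_rng(cfg.seed + 7)
    K = cfg.n_cell_types
    types = cfg.cell_types
    n = cfg.n_ewas_samples
    samples = [f"S{j + 1}" for j in range(n)]
    if true_fractions is None:
        f = rng.dirichlet(np.full(K, cfg.dirichlet_alpha), size=n)
        fractions = pd.DataFrame(f, index=samples, columns=types)
    else:
        fractions = true_fractions.iloc[:n].copy()
        fractions.index = samples[: len(fractions)]
        samples = list(fractions.index)
        n = len(samples)
    y = np.zeros(n)
    y[rng.permutation(n)[: n // 2]] = 1.0
    age = rng.uniform(20.0, 70.0, size=n)
    gamma = 0.0005  # beta units per year; a small but estimable confounder

    sites = [f"cg{j + 1:05d}" for j in range(cfg.n_ewas_sites)]
    mu = rng.uniform(0.2, 0.8, size=(cfg.n_ewas_sites, K))
    b = np.zeros((cfg.n_ewas_sites, K))
    n_eff = min(cfg.n_effect_sites, cfg.n_ewas_sites)
    b[:n_eff, effect_type] = cfg.interaction_effect
    F = fractions.to_numpy(dtype=float)
    signal = mu @ F.T + b @ (F * y[:, None]).T + gamma * (age - age.mean())[None, :]
    betas = signal + rng.normal(0.0, cfg.ewas_noise_sd, size=signal.shape)
    betas = np.clip(betas, 0.0, 1.0)
    truth = pd.DataFrame(
        {
            "site": sites[:n_eff],
            "cell_type": [types[effect_type]] * n_eff,
            "effect": [cfg.interaction_effect] * n_eff,
        }
    )
    ds = EWASDataset(
        betas=pd.DataFrame(betas, index=sites, columns=samples),
        fractions=fractions,
        y=pd.Series(y, index=samples, name="y"),
        covariates=pd.DataFrame({"age": age}, index=samples),
    )
    return ds, truth


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of the config with a different seed."""
    return replace(cfg, seed=seed)
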
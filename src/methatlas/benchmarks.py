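"""Simulation benchmarks of the deconvolution framework.

The central claim these benchmarks probe is robustness: because the
constrained multivariate regression acts like a voting scheme over
hundreds of markers, fraction estimation keeps working even when a
substantial share of the reference entries is wrong. The corruption
benchmark replaces a fraction q of reference entries with Uniform(0,1)
noise and reports how far q can grow before the per-cell-type agreement
(Pearson R between true and estimated fractions) drops below a floor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DNAmReference
from .deconvolve import estimate_fractions
from .synthetic import SimulationConfig, planted_dnam_reference, simulate_bulk_mixtures


def corrupt_reference(
    ref: DNAmReference, q: float, rng: np.random.Generator
) -> DNAmReference:
    """Replace a fraction q of reference entries with Uniform(0,1) draws."""
    values = ref.values.to_numpy(dtype=float).copy()
    n_total = values.size
    n_corrupt = int(round(q * n_total))
    if n_corrupt:
        flat = rng.choice(n_total, size=n_corrupt, replace=False)
        values.ravel()[flat] = rng.uniform(0.0, 1.0, size=n_corrupt)
    return DNAmReference(
        values=pd.DataFrame(values, index=ref.values.index, columns=ref.values.columns),
        weights=ref.weights,
        target_type=ref.target_type,
    )


def min_per_type_correlation(
    true_fractions: pd.DataFrame, est_fractions: pd.DataFrame
) -> float:
    """Minimum over cell types of Pearson R(true, estimated) across samples."""
    rs = []
    for c in true_fractions.columns:
        t = true_fractions[c].to_numpy(dtype=float)
        e = est_fractions[c].to_numpy(dtype=float)
        if np.std(e) == 0 or np.std(t) == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(t, e)[0, 1]))
    return min(rs)


def corruption_tolerance(
    cfg: SimulationConfig | None = None,
    q_grid=None,
    n_replicates: int = 10,
    r_floor: float = 0.8,
    seed: int = 1,
) -> dict:
    """Largest corruption rate the deconvolution tolerates.

    For each q on the grid and each replicate, build the planted
    block-structured reference, draw noiseless Dirichlet(1) mixtures,
    corrupt q of the reference entries with Uniform(0,1) values, estimate
    fractions with Huber loss and unit weights, and record the minimum
    per-cell-type Pearson R between true and estimated fractions. The
    tolerated rate is the largest q whose minimum R across types and
    replicates stays at or above ``r_floor``.

    Returns a dict with ``tolerated_q``, the per-q minimum correlations
    (``min_r_by_q``), and the grid.
    """
    if cfg is None:
        cfg = SimulationConfig(seed=seed, beta_noise_sd=0.0)
    if q_grid is None:
        q_grid = np.round(np.arange(0.0, 0.501, 0.05), 2)
    min_r_by_q = {}
    for q in q_grid:
        worst = np.inf
        for rep in range(n_replicates):
            rep_seed = seed + rep
            rep_cfg = SimulationConfig(
                seed=rep_seed,
                n_cell_types=cfg.n_cell_types,
                markers_per_type=cfg.markers_per_type,
                n_mixtures=cfg.n_mixtures,
                dirichlet_alpha=cfg.dirichlet_alpha,
                beta_noise_sd=0.0,
                own_type_beta=cfg.own_type_beta,
                other_type_beta=cfg.other_type_beta,
            )
            ref = planted_dnam_reference(rep_cfg)
            bulk, true_f = simulate_bulk_mixtures(ref, rep_cfg)
            rng = np.random.default_rng(rep_seed + 10_000 + int(round(q * 100)))
            corrupted = corrupt_reference(ref, float(q), rng)
            est = estimate_fractions(bulk, corrupted, weights=None, robust=True)
            worst = min(worst, min_per_type_correlation(true_f, est))
        min_r_by_q[float(q)] = float(worst)
    tolerated = 0.0
    for q in sorted(min_r_by_q):
        if min_r_by_q[q] >= r_floor:
            tolerated = q
        else:
            break
    return {
        "tolerated_q": float(tolerated),
        "min_r_by_q": min_r_by_q,
        "q_grid": [float(q) for q in q_grid],
        "r_floor": float(r_floor),
        "n_replicates": int(n_replicates),
    }


def fraction_recovery_rmse(
    seed: int = 1, beta_noise_sd: float = 0.0, robust: bool = False
) -> float:
    """Per-type RMSE of recovered fractions on the default mixture benchmark.

    200 Dirichlet(1) mixtures of the planted 6-type, 600-marker
    reference; the returned value is the maximum RMSE over cell types.
    """
    cfg = SimulationConfig(seed=seed, beta_noise_sd=beta_noise_sd)
    ref = planted_dnam_reference(cfg)
    bulk, true_f = simulate_bulk_mixtures(ref, cfg)
    est = estimate_fractions(bulk, ref, robust=robust)
    rmse = np.sqrt(((est - true_f) ** 2).mean(axis=0))
    return float(rmse.max())
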
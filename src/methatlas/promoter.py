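"""Probe-level to gene-promoter-level summarization of DNAm beta matrices.

Promoter methylation of a gene is the average beta over the probes mapping
to its TSS200 region (the 200 bp immediately upstream of the transcription
start site); when a gene has no TSS200 probe with data, the first-exon
probes are used instead. Genes with neither are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validation import check_beta_range, check_unique_index

TSS200 = "TSS200"
FIRST_EXON = "FirstExon"
OTHER = "Other"

# Illumina 450k/EPIC manifests use "1stExon"; tolerate common spellings.
_GROUP_ALIASES = {
    "TSS200": TSS200,
    "1STEXON": FIRST_EXON,
    "FIRSTEXON": FIRST_EXON,
    "1ST_EXON": FIRST_EXON,
}


def normalize_region_group(group: str) -> str:
    return _GROUP_ALIASES.get(str(group).strip().upper(), OTHER)


@dataclass
class PromoterBetaMatrix:
    """Gene-promoter beta matrix plus the region class used per gene."""

    values: pd.DataFrame          # genes x samples, beta in [0,1], NaN = missing
    provenance: pd.Series         # gene -> TSS200 | FirstExon

    def __post_init__(self) -> None:
        check_beta_range(self.values, "promoter beta matrix")
        self.provenance = pd.Series(self.provenance).reindex(self.values.index)


def tidy_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Normalize a probe manifest to one (probe_id, gene, region_group) per row.

    Accepts either the tidy three-column layout or an Illumina-style layout
    with semicolon-separated multi-valued gene/group columns, which is
    exploded so that a probe annotated to several genes contributes a row
    per gene. When a probe maps to the same gene under both TSS200 and
    FirstExon, the TSS200 assignment wins.
    """
    cols = {c.lower(): c for c in manifest.columns}
    if "probe_id" in cols and "gene" in cols and "region_group" in cols:
        df = manifest.rename(
            columns={cols["probe_id"]: "probe_id", cols["gene"]: "gene",
                     cols["region_group"]: "region_group"}
        )[["probe_id", "gene", "region_group"]].copy()
        multi = df["gene"].astype(str).str.contains(";").any()
        if multi:
            df = _explode_multivalued(df, "probe_id", "gene", "region_group")
    else:
        probe_col = next(
            (cols[c] for c in ("ilmnid", "name") if c in cols), None
        )
        gene_col = next(
            (cols[c] for c in ("ucsc_refgene_name", "gene_name") if c in cols), None
        )
        group_col = next(
            (cols[c] for c in ("ucsc_refgene_group", "gene_group") if c in cols), None
        )
        if probe_col is None or gene_col is None or group_col is None:
            raise ValueError(
                "manifest needs columns (probe_id, gene, region_group) or "
                "Illumina-style (IlmnID/Name, UCSC_RefGene_Name, UCSC_RefGene_Group)"
            )
        df = manifest.rename(
            columns={probe_col: "probe_id", gene_col: "gene", group_col: "region_group"}
        )[["probe_id", "gene", "region_group"]].copy()
        df = _explode_multivalued(df, "probe_id", "gene", "region_group")
    if df.empty:
        raise ValueError("manifest is empty")
    df["region_group"] = df["region_group"].map(normalize_region_group)
    df = df.dropna(subset=["gene"])
    df = df[df["gene"].astype(str).str.len() > 0]
    # resolve duplicated (probe, gene) pairs in strict TSS200 > FirstExon > Other order
    order = pd.CategoricalDtype([TSS200, FIRST_EXON, OTHER], ordered=True)
    df["region_group"] = df["region_group"].astype(order)
    df = (
        df.sort_values(["probe_id", "gene", "region_group"])
        .drop_duplicates(["probe_id", "gene"], keep="first")
        .reset_index(drop=True)
    )
    df["region_group"] = df["region_group"].astype(str)
    return df


def _explode_multivalued(df: pd.DataFrame, probe: str, gene: str, group: str) -> pd.DataFrame:
    df = df.copy()
    df[gene] = df[gene].astype(str).str.split(";")
    df[group] = df[group].astype(str).str.split(";")
    bad = df[gene].str.len() != df[group].str.len()
    if bad.any():
        raise ValueError(
            f"manifest probe {df.loc[bad, probe].iloc[0]!r}: gene and "
            "region-group lists have different lengths"
        )
    return df.explode([gene, group], ignore_index=True)


def summarize_promoter_dnam(
    probes: pd.DataFrame, manifest: pd.DataFrame
) -> PromoterBetaMatrix:
    """Summarize a probe-level beta matrix to gene-promoter level.

    Parameters
    ----------
    probes : DataFrame
        Probe x sample beta matrix; values in [0, 1], NaN allowed.
    manifest : DataFrame
        Probe annotation (see :func:`tidy_manifest`). Probes in the manifest
        but absent from ``probes`` (or all-missing) are simply unavailable.

    Returns
    -------
    PromoterBetaMatrix
        Per gene and sample, the mean beta over the gene's TSS200 probes
        with data, falling back to first-exon probes for genes without any
        TSS200 coverage. Missing values are excluded from means (never
        imputed as zero). Genes with neither region class are omitted.
    """
    check_unique_index(probes, "probe beta matrix")
    check_beta_range(probes, "probe beta matrix")
    if probes.shape[1] < 1:
        raise ValueError("probe beta matrix must have at least one sample")
    man = tidy_manifest(manifest)
    man = man[man["region_group"].isin([TSS200, FIRST_EXON])]

    # probes with at least one observed value
    observed = probes.index[probes.notna().any(axis=1)]
    man = man[man["probe_id"].isin(observed)]

    rows: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for gene, sub in man.groupby("gene", sort=True):
        tss = sub.loc[sub["region_group"] == TSS200, "probe_id"]
        if len(tss):
            use, prov = tss, TSS200
        else:
            use, prov = sub.loc[sub["region_group"] == FIRST_EXON, "probe_id"], FIRST_EXON
        if not len(use):
            continue
        rows[gene] = probes.loc[use].mean(axis=0, skipna=True).to_numpy()
        provenance[gene] = prov
    if not rows:
        values = pd.DataFrame(columns=probes.columns, dtype=float)
    else:
        values = pd.DataFrame.from_dict(rows, orient="index", columns=probes.columns)
        values = values.sort_index()
    return PromoterBetaMatrix(values=values, provenance=pd.Series(provenance, dtype=object))
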
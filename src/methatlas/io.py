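"""Readers and writers for the tabular formats used across the package.

TSV is the canonical dialect (tab-separated, UTF-8, '.' decimal; gzip
accepted transparently by pandas). Sparse expression is accepted as an
MTX triplet with gene/barcode index files; genomic loci as BED with
0-based half-open intervals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._validation import check_beta_range, check_nonnegative, check_unique_index

MATRIX_KINDS = ("beta", "expression", "fractions")


def read_matrix(path: str | Path, kind: str = "beta") -> pd.DataFrame:
    """Read a TSV/CSV matrix (rows x samples, header row) and validate it.

    ``kind`` selects the invariants enforced: ``beta`` values must lie in
    [0, 1] (NaN allowed), ``expression`` values must be non-negative and
    ``fractions`` rows must be non-negative and sum to one (an all-zero
    row, the degenerate deconvolution output, is tolerated).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input matrix not found: {path}")
    sep = "," if path.name.replace(".gz", "").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    check_unique_index(df, f"{kind} matrix {path.name}")
    if kind == "beta":
        check_beta_range(df, f"beta matrix {path.name}")
    elif kind == "expression":
        check_nonnegative(df, f"expression matrix {path.name}")
    elif kind == "fractions":
        check_nonnegative(df, f"fraction matrix {path.name}")
        sums = df.sum(axis=1).to_numpy(dtype=float)
        bad = ~np.isclose(sums, 1.0, atol=1e-6) & (sums != 0.0)
        if bad.any():
            raise ValueError(
                f"fraction matrix {path.name}: row {df.index[np.argmax(bad)]!r} "
                f"sums to {sums[np.argmax(bad)]:.6g}, not 1"
            )
    else:
        raise ValueError(f"unknown matrix kind {kind!r}; one of {MATRIX_KINDS}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a matrix as TSV with 10 significant digits (round-trip safe)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)


def read_mtx_expression(
    mtx_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> pd.DataFrame:
    """Load an MTX triplet (matrix + gene and barcode index files) densely."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes"
        )
    df = pd.DataFrame(mat, index=genes, columns=barcodes)
    check_unique_index(df, "expression matrix")
    check_nonnegative(df, "expression matrix")
    return df


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (id, label) -> Series indexed by id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs two columns (id, label)")
    return pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str)
    )


def read_grouping(path: str | Path) -> dict[str, list[str]]:
    """YAML mapping of group name -> list of cell types."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"grouping file {path} must be a mapping")
    return {str(k): [str(v) for v in vals] for k, vals in cfg.items()}


def read_loci_table(path: str | Path) -> dict[str, set]:
    """Two-column TSV (locus_name, gene_or_site_id) -> name -> member set."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"loci file {path} needs two columns (locus, member)")
    out: dict[str, set] = {}
    for name, sub in df.groupby(df.columns[0]):
        out[str(name)] = set(sub.iloc[:, 1].astype(str))
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals (0-based half-open) with optional name column."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = cols[: df.shape[1]]
    if df.shape[1] >= 4:
        df = df.rename(columns={"col3": "name"})
    return df


def sites_in_intervals(sites: pd.DataFrame, bed: pd.DataFrame) -> set:
    """Site ids whose 1-based position falls in any BED interval.

    ``sites`` needs columns (site_id, chrom, pos) with pos 1-based;
    BED intervals are 0-based half-open, so position p overlaps
    [start, end) when start < p <= end.
    """
    hits: set = set()
    for chrom, sub in sites.groupby("chrom"):
        iv = bed[bed["chrom"] == chrom]
        if iv.empty:
            continue
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        pos = sub["pos"].to_numpy()
        inside = ((pos[:, None] > starts[None, :]) & (pos[:, None] <= ends[None, :])).any(
            axis=1
        )
        hits.update(sub.loc[inside, "site_id"].astype(str))
    return hits
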
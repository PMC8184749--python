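"""Readers and writers for the plain-text interchange formats used across the pipeline.

Counts / TPM / expression matrices are TSV with a leading ``gene_id`` column and
one column per sample.  Genomic positions in summary-statistic tables are
1-based (converted at this boundary); intervals (genes, loci) are 0-based
half-open, as in BED.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

ASSOC_COLUMNS = ["snp", "chr", "bp", "beta", "se", "maf", "n"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return df.set_index("sample_id")


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return df.set_index("gene_id")


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_bone_genes(path: str | Path) -> set[str]:
    """Newline-delimited gene ids; ``#`` starts a comment."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return genes


def write_bone_genes(genes, path: str | Path, note: str | None = None) -> None:
    lines = []
    if note:
        lines.append(f"# {note}")
    lines.extend(sorted(genes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_assoc(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str})
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table {path} missing columns {missing}")
    return df


def write_assoc(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ASSOC_COLUMNS)


def read_leads(path: str | Path) -> pd.DataFrame:
    """Lead-SNP table: ``chrom, pos, snp_id`` (pos 0-based point position)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})


def write_leads(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["chrom", "pos", "snp_id"])


def read_loci_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label"], dtype={"chrom": str, "label": str},
    )
    return df


def write_loci_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=["chrom", "start", "end", "label"])


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, stable float repr, trailing newline."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
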
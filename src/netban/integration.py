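"""Locus-level integration: proximity flags, enrichment, overlap nulls, report.

Coordinates are 0-based half-open internally (BED convention); lead SNPs are
points.  A gene is "near" a lead when the minimum distance from its interval
to the lead position is at most ``max_dist`` (1 Mbp by default, inclusive).
Enrichment of 2x2 tables uses the cross-product odds ratio with a two-sided
Fisher exact p.  The locus-overlap null places length-matched intervals
uniformly at random (chromosome chosen proportional to placeable length) and
reports the percentile of the observed overlap count under the <= convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def genes_near_leads(
    genes: pd.DataFrame,
    leads: pd.DataFrame,
    max_dist: int = 1_000_000,
) -> pd.Series:
    """Boolean per gene: interval within ``max_dist`` of any lead SNP.

    ``genes`` is indexed by gene_id with columns chrom/start/end; ``leads``
    has columns chrom/pos.  Lead chromosomes absent from the gene table
    raise (naming-convention mismatch), except when the lead table is empty.
    """
    out = pd.Series(False, index=genes.index)
    if leads.empty:
        return out
    gene_chroms = set(genes["chrom"].astype(str))
    lead_chroms = set(leads["chrom"].astype(str))
    unknown = sorted(lead_chroms - gene_chroms)
    if unknown:
        raise ValueError(
            f"lead-SNP chromosomes {unknown} not present in the gene table; "
            "check chromosome naming conventions"
        )
    for chrom, sub in leads.groupby(leads["chrom"].astype(str)):
        gsel = genes["chrom"].astype(str) == chrom
        if not gsel.any():
            continue
        starts = genes.loc[gsel, "start"].to_numpy()[:, None]
        ends = genes.loc[gsel, "end"].to_numpy()[:, None]
        pos = sub["pos"].to_numpy()[None, :]
        dist = np.where(pos < starts, starts - pos, np.where(pos >= ends, pos - (ends - 1), 0))
        out.loc[genes.index[gsel]] |= (dist.min(axis=1) <= max_dist)
    return out


def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Cross-product odds ratio (a*d)/(b*c) and two-sided Fisher exact p.

    A zero table margin makes the OR not estimable: returns (nan, 1.0).
    b*c = 0 with a*d > 0 reports OR = inf.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    if b * c == 0:
        or_ = float("inf") if a * d > 0 else float("nan")
    else:
        or_ = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(or_), float(p)


def interval_overlap_null(
    loci: pd.DataFrame,
    leads: pd.DataFrame,
    chrom_sizes: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Observed count of loci containing a lead SNP, and its null percentile.

    Null draws re-place each locus (length preserved) uniformly on the
    supplied chromosomes, chromosome chosen proportional to placeable length;
    intervals may overlap each other.  Percentile = 100 * P(null <= observed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(41,)))
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    lead_pos = {
        c: np.sort(sub["pos"].to_numpy())
        for c, sub in leads.groupby(leads["chrom"].astype(str))
    } if not leads.empty else {}

    def count_overlaps(rows) -> int:
        n = 0
        for chrom, start, end in rows:
            pos = lead_pos.get(str(chrom))
            if pos is None:
                continue
            i = np.searchsorted(pos, start, side="left")
            if i < len(pos) and pos[i] < end:
                n += 1
        return n

    obs_rows = list(zip(loci["chrom"], loci["start"], loci["end"]))
    lengths = (loci["end"] - loci["start"]).to_numpy(dtype=np.int64)
    if (lengths <= 0).any():
        raise ValueError("loci must have positive length")
    for L in lengths:
        if not (sizes >= L).any():
            raise ValueError(f"locus of length {L} fits on no chromosome")
    observed = count_overlaps(obs_rows)

    null_counts = np.empty(n_perm, dtype=np.int64)
    for it in range(n_perm):
        rows = []
        for L in lengths:
            placeable = np.maximum(sizes - L + 1, 0)
            p = placeable / placeable.sum()
            ci = rng.choice(len(chroms), p=p)
            start = int(rng.integers(0, sizes[ci] - L + 1))
            rows.append((chroms[ci], start, start + L))
        null_counts[it] = count_overlaps(rows)
    percentile = 100.0 * float((null_counts <= observed).mean())
    return int(observed), percentile


def candidate_report(
    ban_table: pd.DataFrame,
    coloc_table: pd.DataFrame,
    proximity: pd.Series,
) -> pd.DataFrame:
    """Ranked causal-gene candidates: BAN and GWAS-proximal and colocalizing.

    ``coloc_table`` needs columns gene_id, lead_snp, n_snps, pph0..pph4,
    colocalizing.  The output keeps all audit columns and sorts by pph4
    descending, then BAN p ascending, then gene id.
    """
    ban = ban_table.copy()
    ban["near_lead"] = ban["gene_id"].map(proximity).fillna(False).astype(bool)
    merged = ban.merge(coloc_table, on="gene_id", how="left")
    merged["colocalizing"] = merged["colocalizing"].astype("boolean").fillna(False).astype(bool)
    cand = merged[merged["is_ban"] & merged["near_lead"] & merged["colocalizing"]]
    cand = cand.sort_values(
        by=["pph4", "p_value", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return cand
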
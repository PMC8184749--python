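"""Bone-associated-node (BAN) statistics on learned module networks.

A gene's neighborhood is every node reachable within ``steps`` edges of its
module's Bayesian network, ignoring edge direction and including the gene
itself (default step size 3).  Candidate genes are pruned in two stages —
neighborhood size <= 2 (unconnected or a single neighbor), then size more
than one sample standard deviation below the pooled mean — and each retained
gene is scored by the upper-tail hypergeometric probability of its bone-gene
overlap:

    p = P(X >= overlap),  X ~ Hypergeom(m bone genes, n_bg non-bone, k drawn)

with k the neighborhood size and n_bg the pre-pruning network universe minus
m (the q = overlap - 1, lower.tail = FALSE convention).  A gene is a BAN at
nominal p <= 0.05; no multiplicity correction is applied.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def ego_nodes(graph: nx.Graph | nx.DiGraph, gene: str, steps: int = 3) -> set[str]:
    """Nodes within ``steps`` undirected edges of ``gene``, including itself."""
    if gene not in graph:
        raise KeyError(f"gene {gene!r} not in graph")
    g = graph.to_undirected(as_view=True) if graph.is_directed() else graph
    return set(nx.single_source_shortest_path_length(g, gene, cutoff=steps))


def ego_size(graph: nx.Graph | nx.DiGraph, gene: str, steps: int = 3) -> int:
    return len(ego_nodes(graph, gene, steps))


def prune_candidates(size_table: dict[str, int] | pd.Series) -> set[str]:
    """Two-stage neighborhood-size pruning.

    Stage 1 drops genes with size <= 2; stage 2 drops genes whose size lies
    more than one sample standard deviation (n-1 denominator, over the
    stage-1 survivors) below the survivors' mean.
    """
    sizes = pd.Series(size_table, dtype=float)
    if sizes.empty:
        raise ValueError("size table is empty")
    stage1 = sizes[sizes > 2]
    if stage1.empty:
        logger.warning("all genes removed by neighborhood-size pruning")
        return set()
    mean = stage1.mean()
    sd = stage1.std(ddof=1) if len(stage1) > 1 else 0.0
    if np.isnan(sd):
        sd = 0.0
    keep = stage1[stage1 >= mean - sd]
    return set(keep.index)


def ban_pvalue(overlap: int, m: int, n_bg: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    if min(overlap, m, n_bg, k) < 0 or overlap > min(k, m) or k > m + n_bg:
        raise ValueError(f"impossible hypergeometric counts: overlap={overlap}, m={m}, n_bg={n_bg}, k={k}")
    return float(stats.hypergeom.sf(overlap - 1, m + n_bg, m, k))


def run_ban(
    networks: dict[str, dict[str, nx.DiGraph]],
    bone_genes: set[str],
    universe_size_pre_prune: dict[str, int] | None = None,
    steps: int = 3,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """BAN table across network sets.

    ``networks`` maps network label -> {module label -> DAG}.  Per network
    set, neighborhood sizes are computed within each module's network, the
    two-stage pruning is applied over the pooled genes of the set, and each
    retained gene is tested for bone-gene enrichment of its neighborhood.
    ``universe_size_pre_prune`` defaults to the gene count of the set's
    networks prior to pruning.
    """
    if not networks:
        raise ValueError("no networks supplied")
    bone_genes = set(bone_genes)
    rows = []
    for label in sorted(networks):
        mods = networks[label]
        if not mods:
            raise ValueError(f"network set {label!r} is empty")
        sizes: dict[str, int] = {}
        hoods: dict[str, set[str]] = {}
        module_of: dict[str, str] = {}
        for mod in sorted(mods):
            g = mods[mod]
            und = g.to_undirected(as_view=True)
            for gene in g.nodes():
                hood = set(nx.single_source_shortest_path_length(und, gene, cutoff=steps))
                hoods[gene] = hood
                sizes[gene] = len(hood)
                module_of[gene] = mod
        universe = (
            universe_size_pre_prune[label]
            if universe_size_pre_prune is not None
            else len(sizes)
        )
        m = len(bone_genes & set(sizes))
        n_bg = universe - m
        retained = prune_candidates(sizes)
        for gene in sorted(retained):
            k = sizes[gene]
            overlap = len(hoods[gene] & bone_genes)
            p = ban_pvalue(overlap, m, n_bg, k) if m > 0 else 1.0
            rows.append(
                (gene, label, module_of[gene], k, overlap, m, n_bg, p, p <= p_threshold)
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "network", "module", "k", "overlap", "m", "n_bg", "p_value", "is_ban"],
    )


def connectivity_test(
    size_table: dict[str, int] | pd.Series,
    bone_flags: dict[str, bool] | pd.Series,
) -> float:
    """One-sided Wilcoxon rank-sum p: bone genes more connected than the rest.

    Ties are handled by the tie-corrected normal approximation; the fully
    degenerate all-equal case (zero rank variance) returns p = 1.
    """
    sizes = pd.Series(size_table, dtype=float)
    flags = pd.Series(bone_flags).reindex(sizes.index)
    if flags.isna().any():
        raise ValueError("bone flags missing for some genes")
    bone = sizes[flags.astype(bool)]
    other = sizes[~flags.astype(bool)]
    if bone.empty or other.empty:
        raise ValueError("both classes must be nonempty")
    if sizes.nunique() == 1:
        return 1.0
    res = stats.mannwhitneyu(bone, other, alternative="greater", method="asymptotic")
    return float(res.pvalue)
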
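"""Signed weighted co-expression networks and topological-overlap modules.

The adjacency is the signed transform a_ij = ((1 + cor_ij)/2)^beta with
Pearson correlation and soft-thresholding power beta (4 for the combined and
female presets, 5 for male).  Topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,  k_i = sum_u a_iu,

defines the clustering dissimilarity 1 - TOM.  Modules come from
average-linkage hierarchical clustering with a static height cut, a minimum
module size, and iterative merging of modules whose eigengenes are closer
than the merge height (0.15).  A module eigengene is the first principal
component of the gene-standardized member submatrix, sign-aligned with the
module's mean expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

NETWORK_POWERS = {"combined": 4.0, "female": 4.0, "male": 5.0}


@dataclass
class ModulePartition:
    """Gene-to-module assignment with per-module eigengenes."""

    network_label: str
    module_of_gene: pd.Series  # gene_id -> module label ("unassigned" allowed)
    eigengenes: pd.DataFrame  # samples x modules, unit-norm columns
    module_sizes: dict[str, int] = field(default_factory=dict)

    def modules(self) -> list[str]:
        return [m for m in self.module_sizes if m != UNASSIGNED]

    def genes_in(self, module: str) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])


def signed_adjacency(expr: pd.DataFrame, power: float = 4.0) -> pd.DataFrame:
    """Signed adjacency ((1+cor)/2)^power over genes (rows of ``expr``)."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0][:5])
        raise ValueError(f"constant gene(s) have undefined correlation: {bad}")
    c = np.corrcoef(x)
    a = ((1.0 + c) / 2.0) ** power
    np.clip(a, 0.0, 1.0, out=a)
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a (hollow, symmetric) adjacency."""
    a = adj.to_numpy(dtype=float)
    l = a @ a  # diagonal of ``a`` is zero, so this is sum_{u != i,j} a_iu a_uj
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (x - mu) / sd


def _eigengene(expr_sub: np.ndarray, first_gene_col: int = 0) -> tuple[np.ndarray, float]:
    """First PC (unit norm, over samples) of a samples x genes block.

    Sign convention: positive correlation with the mean member profile; if
    that correlation is exactly zero (e.g. two perfectly anticorrelated
    genes), align with the first gene in id order instead.
    Returns (eigengene, variance_explained).
    """
    xs = _standardize(expr_sub)
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    e = u[:, 0]
    var_expl = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 1.0
    ref = xs.mean(axis=1)
    align = float(e @ ref)
    if abs(align) < 1e-12:
        align = float(e @ xs[:, first_gene_col])
    if align < 0:
        e = -e
    return e, var_expl


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Samples x modules eigengene matrix (unassigned genes are skipped)."""
    labels = labels.reindex(expr.index)
    mods = sorted(m for m in labels.dropna().unique() if m != UNASSIGNED)
    out = {}
    for m in mods:
        genes = labels.index[labels == m]
        sub = expr.loc[genes].to_numpy().T  # samples x genes
        e, _ = _eigengene(sub)
        out[m] = e
    return pd.DataFrame(out, index=expr.columns)


def _default_cut_height(z: np.ndarray, min_module_size: int) -> float:
    """Static cut height for the dendrogram.

    The cut is placed at the center of the height interval that maximizes the
    number of clusters meeting ``min_module_size``: low cuts fragment modules
    below the size threshold, high cuts fuse modules with each other and with
    unclustered noise genes, and the count of size-qualified clusters peaks on
    a plateau of heights in between.  For homogeneous data (every height
    yields one qualifying cluster) this reduces to a cut near the dendrogram
    top, giving a single module.
    """
    heights = np.unique(z[:, 2])
    best = -1
    best_ts: list[float] = []
    for t in heights:
        labels = fcluster(z, t=t, criterion="distance")
        count = int((np.bincount(labels) >= min_module_size).sum())
        if count > best:
            best = count
            best_ts = [float(t)]
        elif count == best:
            best_ts.append(float(t))
    return (best_ts[0] + best_ts[-1]) / 2.0 if best_ts else float(heights[-1])


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    network_label: str = "combined",
    min_module_size: int = 30,
    merge_height: float = 0.15,
    cut_height: float | None = None,
) -> ModulePartition:
    """Cluster 1 - TOM by average linkage, cut, enforce size, merge eigengenes.

    ``cut_height`` defaults to 0.99 x the maximum merge height of the
    dendrogram.  Clusters below ``min_module_size`` become "unassigned".
    Modules whose eigengene dissimilarity (1 - cor) falls below
    ``merge_height`` are merged iteratively, closest pair first.  Final
    labels are M1, M2, ... by decreasing size.
    """
    if not tom.index.equals(expr.index):
        expr = expr.reindex(tom.index)
        if expr.isna().any().any():
            raise ValueError("TOM and expression gene sets differ")
    genes = tom.index
    n = len(genes)
    if n < min_module_size:
        logger.warning("fewer genes (%d) than min_module_size; all unassigned", n)
        labels = pd.Series(UNASSIGNED, index=genes)
        return ModulePartition(network_label, labels, pd.DataFrame(index=expr.columns),
                               {UNASSIGNED: n})

    d = 1.0 - tom.to_numpy()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, None, out=d)
    z = linkage(squareform(d, checks=False), method="average")
    if cut_height is None:
        cut_height = _default_cut_height(z, min_module_size)
    raw = fcluster(z, t=cut_height, criterion="distance")

    members: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        members.setdefault(int(c), []).append(g)
    clusters = [v for v in members.values() if len(v) >= min_module_size]
    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    for i, cl in enumerate(clusters):
        labels.loc[cl] = f"tmp{i}"

    # eigengene merging: closest pair first, while below merge height
    def current_modules() -> list[str]:
        return sorted(set(labels) - {UNASSIGNED})

    while True:
        mods = current_modules()
        if len(mods) < 2:
            break
        me = module_eigengenes(expr, labels)
        cors = np.corrcoef(me.to_numpy().T)
        diss = 1.0 - cors
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_height:
            break
        a, b = me.columns[i], me.columns[j]
        labels[labels == b] = a

    mods = current_modules()
    sizes = {m: int((labels == m).sum()) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], m))
    rename = {m: f"M{i + 1}" for i, m in enumerate(order)}
    labels = labels.map(lambda m: rename.get(m, UNASSIGNED))
    eig = module_eigengenes(expr, labels)
    module_sizes = {rename[m]: sizes[m] for m in order}
    n_un = int((labels == UNASSIGNED).sum())
    if n_un:
        module_sizes[UNASSIGNED] = n_un
    return ModulePartition(network_label, labels, eig, module_sizes)


def eigengene_trait_assoc(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho and asymptotic two-sided p per (module, trait), nominal.

    Missing trait values are dropped pairwise; fewer than 4 complete pairs
    flags the entry as not estimable (rho/p NaN).
    """
    common = eigengenes.index.intersection(traits.index)
    rows = []
    for m in eigengenes.columns:
        e = eigengenes.loc[common, m]
        for t in traits.columns:
            y = traits.loc[common, t]
            ok = y.notna() & e.notna()
            if ok.sum() < 4:
                rows.append((m, t, np.nan, np.nan, int(ok.sum()), False))
                continue
            rho, p = stats.spearmanr(e[ok], y[ok])
            rows.append((m, t, float(rho), float(p), int(ok.sum()), True))
    return pd.DataFrame(rows, columns=["module", "trait", "rho", "p", "n", "estimable"])
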
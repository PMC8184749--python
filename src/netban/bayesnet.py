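"""Per-module Bayesian network structure learning via Max-Min Hill Climbing.

MMHC is a hybrid learner: a constraint phase (MMPC) builds an undirected
candidate skeleton from Fisher-z conditional-independence tests, then a
score phase greedily orients it by hill climbing on the Gaussian BIC, with
edge additions restricted to skeleton pairs and every intermediate state
acyclic.  Both phases are deterministic: genes are processed in sorted order
and score ties break lexicographically by (operator, source, target).

The Gaussian BIC of a DAG decomposes over nodes as

    score(G) = sum_j [ loglik_j(parents_j) - (|parents_j| + 2)/2 * log n ],

where loglik_j is the maximized Gaussian log-likelihood of node j regressed
on its parents (per-node parameters: coefficients, intercept, residual
variance).  Higher is better.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12


@dataclass
class BayesNetConfig:
    alpha: float = 0.01
    max_sepset: int = 3
    max_iterations: int = 10_000
    ridge: float = 1e-8
    max_module_size: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.max_sepset < 0 or self.max_iterations < 1 or self.ridge < 0:
            raise ValueError("invalid BayesNetConfig")


@dataclass
class Skeleton:
    nodes: list[str]
    edges: set[frozenset]
    sepsets: dict[frozenset, tuple[str, ...]] = field(default_factory=dict)

    def has_edge(self, i: str, j: str) -> bool:
        return frozenset((i, j)) in self.edges


@dataclass
class DirectedNetwork:
    graph: nx.DiGraph
    score: float = np.nan
    hit_iteration_cap: bool = False


class _GaussianData:
    """Correlation/covariance cache over a fixed sample of continuous genes."""

    def __init__(self, data: pd.DataFrame, ridge: float = 1e-8):
        self.columns = list(data.columns)
        self.index = {c: i for i, c in enumerate(self.columns)}
        self.n = data.shape[0]
        x = data.to_numpy(dtype=float)
        self.cov = np.cov(x, rowvar=False, ddof=0)  # MLE covariance
        if self.cov.ndim == 0:
            self.cov = self.cov.reshape(1, 1)
        sd = np.sqrt(np.diag(self.cov))
        sd = np.where(sd < 1e-15, 1.0, sd)
        self.corr = self.cov / np.outer(sd, sd)
        self.ridge = ridge

    def partial_corr(self, i: int, j: int, S: tuple[int, ...]) -> float:
        c = self.corr
        if not S:
            return float(c[i, j])
        if len(S) == 1:
            k = S[0]
            denom = (1.0 - c[i, k] ** 2) * (1.0 - c[j, k] ** 2)
            if denom <= 0:
                return 0.0 if abs(c[i, j] - c[i, k] * c[j, k]) < 1e-12 else np.sign(c[i, j])
            return float((c[i, j] - c[i, k] * c[j, k]) / np.sqrt(denom))
        idx = [i, j, *S]
        sub = c[np.ix_(idx, idx)] + self.ridge * np.eye(len(idx))
        try:
            p = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            p = np.linalg.pinv(sub)
        denom = np.sqrt(p[0, 0] * p[1, 1])
        if denom <= 0:
            return 0.0
        return float(np.clip(-p[0, 1] / denom, -1.0, 1.0))


def fisher_z_pcor_test(
    data: pd.DataFrame | _GaussianData,
    i: str,
    j: str,
    S: tuple[str, ...] | list[str] = (),
    ridge: float = 1e-8,
) -> tuple[float, float]:
    """Fisher-z test of partial correlation of genes i, j given set S.

    Statistic z = atanh(r) * sqrt(n - |S| - 3) with a two-sided normal p.
    |r| numerically 1 yields p = 0 (degenerate, flagged via the value).
    """
    gd = data if isinstance(data, _GaussianData) else _GaussianData(data, ridge)
    S = tuple(S)
    if gd.n <= len(S) + 3:
        raise ValueError("need n > |S| + 3 samples for the Fisher-z test")
    r = gd.partial_corr(gd.index[i], gd.index[j], tuple(gd.index[s] for s in S))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-15:
        return r, 0.0
    z = np.arctanh(r) * np.sqrt(gd.n - len(S) - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    return r, float(p)


def _pcor_pvalue(gd: _GaussianData, i: int, j: int, S: tuple[int, ...]) -> float:
    r = gd.partial_corr(i, j, S)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-15:
        return 0.0
    z = np.arctanh(r) * np.sqrt(gd.n - len(S) - 3)
    return float(2.0 * stats.norm.sf(abs(z)))


def _mmpc_one(gd: _GaussianData, t: int, others: list[int], cfg: BayesNetConfig):
    """Candidate parent/child set of target t with dismissal sepsets."""
    cpc: list[int] = []
    sepset: dict[int, tuple[int, ...]] = {}
    # max over tested conditioning subsets of the test p-value, per candidate
    maxp = {x: _pcor_pvalue(gd, t, x, ()) for x in others}
    cand = {x for x in others if maxp[x] <= cfg.alpha}
    for x in set(others) - cand:
        sepset[x] = ()

    while cand:
        # new conditioning subsets: those containing the last-added member
        if cpc:
            last = cpc[-1]
            rest = [m for m in cpc if m != last]
            new_subsets = [
                (*s, last)
                for r in range(0, min(cfg.max_sepset - 1, len(rest)) + 1)
                for s in itertools.combinations(rest, r)
            ]
        else:
            new_subsets = []
        dropped = []
        for x in sorted(cand):
            for s in new_subsets:
                p = _pcor_pvalue(gd, t, x, s)
                if p > maxp[x]:
                    maxp[x] = p
                if p > cfg.alpha:
                    sepset[x] = s
                    dropped.append(x)
                    break
        cand.difference_update(dropped)
        if not cand:
            break
        best = min(sorted(cand), key=lambda x: maxp[x])
        cpc.append(best)
        cand.discard(best)

    # backward: remove members independent given a subset of the others
    changed = True
    while changed:
        changed = False
        for y in list(cpc):
            rest = [m for m in cpc if m != y]
            found = False
            for r in range(0, min(cfg.max_sepset, len(rest)) + 1):
                for s in itertools.combinations(rest, r):
                    if _pcor_pvalue(gd, t, y, s) > cfg.alpha:
                        sepset[y] = s
                        found = True
                        break
                if found:
                    break
            if found:
                cpc.remove(y)
                changed = True
    return cpc, sepset


def mmpc_skeleton(data: pd.DataFrame, config: BayesNetConfig | None = None) -> Skeleton:
    """Max-Min Parents-and-Children skeleton with AND-symmetrization."""
    cfg = config or BayesNetConfig()
    cols = sorted(data.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 genes")
    if len(cols) > cfg.max_module_size:
        raise ValueError(
            f"module has {len(cols)} genes, above the configured cap "
            f"{cfg.max_module_size}; refusing rather than subsampling"
        )
    gd = _GaussianData(data[cols], cfg.ridge)
    idx_of = gd.index
    pc: dict[int, set[int]] = {}
    sepsets: dict[frozenset, tuple[str, ...]] = {}
    for t_name in cols:
        t = idx_of[t_name]
        others = [idx_of[c] for c in cols if c != t_name]
        cpc, seps = _mmpc_one(gd, t, others, cfg)
        pc[t] = set(cpc)
        for x, s in seps.items():
            key = frozenset((t_name, gd.columns[x]))
            if key not in sepsets:
                sepsets[key] = tuple(gd.columns[k] for k in s)
    edges = {
        frozenset((gd.columns[i], gd.columns[j]))
        for i in pc
        for j in pc[i]
        if i in pc[j] and i < j
    }
    return Skeleton(nodes=cols, edges=edges, sepsets=sepsets)


def _node_loglik(gd: _GaussianData, j: int, parents: tuple[int, ...], ridge: float) -> float:
    c = gd.cov
    if parents:
        cpp = c[np.ix_(parents, parents)] + ridge * np.eye(len(parents))
        cjp = c[np.ix_([j], parents)][0]
        try:
            beta = np.linalg.solve(cpp, cjp)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(cpp, cjp, rcond=None)[0]
        sigma2 = float(c[j, j] - cjp @ beta)
    else:
        sigma2 = float(c[j, j])
    sigma2 = max(sigma2, 1e-12)
    n = gd.n
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def gaussian_bic(
    data: pd.DataFrame | _GaussianData,
    dag: nx.DiGraph,
    ridge: float = 1e-8,
) -> float:
    """Decomposable Gaussian BIC score of a DAG (higher is better)."""
    gd = data if isinstance(data, _GaussianData) else _GaussianData(data, ridge)
    total = 0.0
    for v in dag.nodes():
        j = gd.index[v]
        parents = tuple(sorted(gd.index[u] for u in dag.predecessors(v)))
        total += _node_loglik(gd, j, parents, ridge)
        total -= (len(parents) + 2) / 2.0 * np.log(gd.n)
    return float(total)


def _has_path(adj: dict[int, set[int]], src: int, dst: int) -> bool:
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def hill_climb(
    data: pd.DataFrame,
    skeleton: Skeleton,
    config: BayesNetConfig | None = None,
) -> DirectedNetwork:
    """Greedy BIC hill climbing restricted to skeleton pairs.

    Starts from the empty graph; per iteration takes the single best
    score-improving move among {add, delete, reverse}, keeping the graph
    acyclic.  Deterministic tie-break: lexicographic (operator, source,
    target) with operators ordered add < delete < reverse.
    """
    cfg = config or BayesNetConfig()
    cols = sorted(data.columns)
    gd = _GaussianData(data[cols], cfg.ridge)
    idx_of = gd.index
    names = gd.columns
    nodes = [idx_of[c] for c in cols]
    parents: dict[int, set[int]] = {v: set() for v in nodes}
    children: dict[int, set[int]] = {v: set() for v in nodes}

    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def node_score(j: int, ps) -> float:
        key = (j, tuple(sorted(ps)))
        if key not in cache:
            cache[key] = _node_loglik(gd, j, key[1], cfg.ridge) - (
                (len(key[1]) + 2) / 2.0
            ) * np.log(gd.n)
        return cache[key]

    skel_pairs = sorted(
        (idx_of[a], idx_of[b])
        for e in skeleton.edges
        for a, b in itertools.permutations(sorted(e), 2)
    )

    hit_cap = False
    for _it in range(cfg.max_iterations):
        best_delta = _TIE_EPS
        best_move = None
        # additions (restricted to skeleton pairs), in lexicographic order
        for u, v in skel_pairs:
            if v in children[u] or u in children[v]:
                continue
            if _has_path(children, v, u):
                continue
            delta = node_score(v, parents[v] | {u}) - node_score(v, parents[v])
            if delta > best_delta:
                best_delta, best_move = delta, ("add", u, v)
        # deletions
        for u in nodes:
            for v in sorted(children[u]):
                delta = node_score(v, parents[v] - {u}) - node_score(v, parents[v])
                if delta > best_delta:
                    best_delta, best_move = delta, ("delete", u, v)
        # reversals
        for u in nodes:
            for v in sorted(children[u]):
                children[u].discard(v)
                creates_cycle = _has_path(children, u, v)
                children[u].add(v)
                if creates_cycle:
                    continue
                delta = (
                    node_score(v, parents[v] - {u})
                    - node_score(v, parents[v])
                    + node_score(u, parents[u] | {v})
                    - node_score(u, parents[u])
                )
                if delta > best_delta:
                    best_delta, best_move = delta, ("reverse", u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            parents[v].add(u)
            children[u].add(v)
        elif op == "delete":
            parents[v].discard(u)
            children[u].discard(v)
        else:
            parents[v].discard(u)
            children[u].discard(v)
            parents[u].add(v)
            children[v].add(u)
    else:
        hit_cap = True
        logger.warning("hill climb reached max_iterations; returning current DAG")

    g = nx.DiGraph()
    g.add_nodes_from(names)
    for v in nodes:
        for u in parents[v]:
            g.add_edge(names[u], names[v])
    assert nx.is_directed_acyclic_graph(g)
    score = sum(node_score(v, parents[v]) for v in nodes)
    return DirectedNetwork(graph=g, score=float(score), hit_iteration_cap=hit_cap)


def mmhc(data: pd.DataFrame, config: BayesNetConfig | None = None) -> DirectedNetwork:
    """Max-Min Hill Climbing: MMPC skeleton, then restricted hill climbing."""
    cfg = config or BayesNetConfig()
    skel = mmpc_skeleton(data, cfg)
    return hill_climb(data, skel, cfg)
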
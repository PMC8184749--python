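"""Synthetic study generators with planted ground truth.

Every downstream stage of the pipeline (expression filtering, module
detection, Bayesian-network learning, bone-associated-node statistics,
colocalization, locus overlap) is exercised on data produced here, so each
generator plants a known truth object alongside its outputs:

* :func:`gen_expression_study` — over-dispersed RNA-seq counts with planted
  co-expression modules (shared-factor or DAG-structured latents), batch
  shifts and bone-gene labels.
* :func:`gen_sem_data` — linear-Gaussian structural-equation samples from a
  known DAG, the substrate for structure-learning tests.
* :func:`gen_assoc_pair` — paired GWAS/eQTL summary statistics under the five
  colocalization hypotheses, with AR(1) linkage disequilibrium on a latent
  liability scale calibrated so adjacent-dosage correlation matches the
  requested value where feasible.
* :func:`gen_gene_landscape` — uniform gene intervals and lead-SNP positions.

All generators are pure functions of their arguments (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "SimTruth",
    "CyclicGraphError",
    "gen_expression_study",
    "gen_module_dag",
    "gen_sem_data",
    "gen_assoc_pair",
    "gen_gene_landscape",
]

SCENARIOS = ("H0", "H1", "H2", "H3", "H4")


class CyclicGraphError(ValueError):
    """Raised when a DAG-requiring operation receives a cyclic graph."""


@dataclass
class SimConfig:
    """Parameters of a planted-module expression study.

    ``module_structure`` selects the latent model for module genes:
    ``"factor"`` draws gene g in module m as lambda*e_m + sqrt(1-lambda^2)*eps
    with a per-module standard-normal eigengene e_m and loading lambda from
    ``loading_range``; ``"dag"`` generates module latents from a planted
    layered DAG (see :func:`gen_module_dag`), which also plants one driver
    gene per bone module.  Counts are negative binomial with mean
    exp(baseline + latent_scale * latent) and shared dispersion.
    """

    n_samples: int = 200
    n_modules: int = 5
    genes_per_module: int = 40
    n_background_genes: int = 100
    loading_range: tuple[float, float] = (0.6, 0.9)
    count_dispersion: float = 0.05
    n_batches: int = 2
    batch_shift_sd: float = 0.3
    bone_gene_fraction: float = 0.25
    seed: int = 0
    # latent / observation layer details
    module_structure: str = "factor"
    n_bone_modules: int = 3
    latent_scale: float = 0.7
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.0
    dag_weight_range: tuple[float, float] = (0.9, 1.2)

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_modules", "genes_per_module", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.genes_per_module < 2:
            raise ValueError("genes_per_module must be >= 2")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("loading_range must lie within (0, 1)")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if not (0.0 <= self.bone_gene_fraction <= 1.0):
            raise ValueError("bone_gene_fraction must be in [0, 1]")
        if self.module_structure not in ("factor", "dag"):
            raise ValueError("module_structure must be 'factor' or 'dag'")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a synthetic study."""

    module_of_gene: dict[str, str] = field(default_factory=dict)
    planted_dags: dict[str, nx.DiGraph] = field(default_factory=dict)
    bone_genes: set[str] = field(default_factory=set)
    driver_genes: set[str] = field(default_factory=set)
    coloc_scenario: str | None = None
    causal_snp_indices: dict[str, list[int]] = field(default_factory=dict)
    # latent (pre-count) expression, kept for diagnostics; not serialized
    latent: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def to_json_dict(self) -> dict:
        dags = {}
        for mod, g in self.planted_dags.items():
            dags[mod] = [
                [u, v, float(d.get("weight", 1.0))] for u, v, d in sorted(g.edges(data=True))
            ]
        return {
            "module_of_gene": dict(sorted(self.module_of_gene.items())),
            "planted_dags": dags,
            "bone_genes": sorted(self.bone_genes),
            "driver_genes": sorted(self.driver_genes),
            "coloc_scenario": self.coloc_scenario,
            "causal_snp_indices": {k: list(map(int, v)) for k, v in sorted(self.causal_snp_indices.items())},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimTruth":
        dags: dict[str, nx.DiGraph] = {}
        for mod, edges in d.get("planted_dags", {}).items():
            g = nx.DiGraph()
            for u, v, w in edges:
                g.add_edge(u, v, weight=w)
            dags[mod] = g
        return cls(
            module_of_gene=d.get("module_of_gene", {}),
            planted_dags=dags,
            bone_genes=set(d.get("bone_genes", [])),
            driver_genes=set(d.get("driver_genes", [])),
            coloc_scenario=d.get("coloc_scenario"),
            causal_snp_indices={k: list(v) for k, v in d.get("causal_snp_indices", {}).items()},
        )


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------

def gen_module_dag(
    n_genes: int,
    n_bone: int,
    seed: int,
    weight_range: tuple[float, float] = (0.9, 1.2),
    n_hub_children: int | None = None,
) -> tuple[nx.DiGraph, int, set[int]]:
    """Planted layered DAG over integer nodes 0..n_genes-1.

    Node 0 is the driver: the root of a depth-<=3 tree whose first-layer
    children are preferentially labelled bone genes, so the driver sits within
    three undirected steps of every bone gene by construction.  Edge weights
    are positive (drawn from ``weight_range``) so member genes are mutually
    positively correlated and form a detectable signed co-expression module.

    Returns (dag, driver_node, bone_nodes).
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if n_bone > n_genes - 1:
        raise ValueError("n_bone must leave room for the driver")
    rng = _spawn(seed, 91)
    g = nx.DiGraph()
    g.add_nodes_from(range(n_genes))
    driver = 0
    if n_hub_children is None:
        n_hub_children = max(n_bone, min(4, n_genes - 1))
    n_hub_children = min(n_hub_children, n_genes - 1)
    layer1 = list(range(1, 1 + n_hub_children))
    for v in layer1:
        g.add_edge(driver, v, weight=rng.uniform(*weight_range))
    # remaining genes extend a few long chains below the first layer, so the
    # driver's 3-step neighborhood stays dominated by its direct children
    n_chains = min(4, n_hub_children)
    tips = layer1[:n_chains]
    for i, v in enumerate(range(1 + n_hub_children, n_genes)):
        c = i % n_chains
        g.add_edge(tips[c], v, weight=rng.uniform(*weight_range))
        tips[c] = v
    bone = set(layer1[:n_bone])
    return g, driver, bone


def gen_sem_data(
    dag: nx.DiGraph,
    weights: dict | None,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Sample a linear-Gaussian SEM: each node = sum(weight * parent) + N(0,1).

    ``weights`` maps (parent, child) to a coefficient; if None, the graph's
    ``weight`` edge attributes are used (default 1.0).  Columns are returned
    in sorted node order; generation follows a topological order so results
    are a pure function of (graph, weights, n, seed).
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise CyclicGraphError("SEM generation requires an acyclic graph")
    rng = _spawn(seed, 17)
    nodes = sorted(dag.nodes())
    noise = {v: rng.standard_normal(n) for v in nodes}
    values: dict = {}
    for v in nx.lexicographical_topological_sort(dag, key=str):
        x = noise[v].copy()
        for u in dag.predecessors(v):
            if weights is not None:
                w = weights[(u, v)]
            else:
                w = dag.edges[u, v].get("weight", 1.0)
            x += w * values[u]
        values[v] = x
    data = pd.DataFrame({v: values[v] for v in nodes})
    return data


def gen_expression_study(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (counts, covariates, gene_table, truth) for a planted study.

    Counts are genes x samples nonnegative integers from a negative-binomial
    layer over log-scale latents; a parallel TPM matrix can be derived with
    :func:`tpm_from_counts` and the lengths in the gene table.
    """
    cfg = config
    n_mod_genes = cfg.n_modules * cfg.genes_per_module
    n_genes = n_mod_genes + cfg.n_background_genes
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    samples = [f"S{j:04d}" for j in range(cfg.n_samples)]
    module_labels = [f"M{m + 1}" for m in range(cfg.n_modules)]

    truth = SimTruth()
    latent = np.zeros((n_genes, cfg.n_samples))
    bone_modules = module_labels[: min(cfg.n_bone_modules, cfg.n_modules)]

    for m, mod in enumerate(module_labels):
        idx = slice(m * cfg.genes_per_module, (m + 1) * cfg.genes_per_module)
        mod_genes = genes[idx]
        for gid in mod_genes:
            truth.module_of_gene[gid] = mod
        n_bone = int(round(cfg.bone_gene_fraction * cfg.genes_per_module)) if mod in bone_modules else 0
        if cfg.module_structure == "factor":
            rng = _spawn(cfg.seed, 1, m)
            e = rng.standard_normal(cfg.n_samples)
            lam = rng.uniform(*cfg.loading_range, size=cfg.genes_per_module)
            eps = rng.standard_normal((cfg.genes_per_module, cfg.n_samples))
            latent[idx] = lam[:, None] * e[None, :] + np.sqrt(1.0 - lam[:, None] ** 2) * eps
            if n_bone:
                truth.bone_genes.update(mod_genes[:n_bone])
        else:
            dag, driver, bone_nodes = gen_module_dag(
                cfg.genes_per_module, n_bone, seed=cfg.seed * 1000 + m,
                weight_range=cfg.dag_weight_range,
            )
            sem = gen_sem_data(dag, None, cfg.n_samples, seed=cfg.seed * 1000 + m)
            vals = sem[sorted(dag.nodes())].to_numpy().T  # genes x samples
            vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
            latent[idx] = vals
            relabel = {i: mod_genes[i] for i in dag.nodes()}
            truth.planted_dags[mod] = nx.relabel_nodes(dag, relabel)
            truth.bone_genes.update(relabel[i] for i in bone_nodes)
            if n_bone:
                truth.driver_genes.add(relabel[driver])

    if cfg.n_background_genes:
        rng = _spawn(cfg.seed, 2)
        latent[n_mod_genes:] = rng.standard_normal((cfg.n_background_genes, cfg.n_samples))
        for gid in genes[n_mod_genes:]:
            truth.module_of_gene[gid] = "background"

    rng = _spawn(cfg.seed, 3)
    sex = np.array(["F", "M"])[np.arange(cfg.n_samples) % 2]
    # balanced batches crossed with sex (permuted so neither confounds the other)
    batch_idx = rng.permutation(np.arange(cfg.n_samples) % cfg.n_batches)
    batch = np.array([f"B{b + 1}" for b in batch_idx])
    age = rng.integers(90, 400, size=cfg.n_samples)
    covariates = pd.DataFrame(
        {"sex": sex, "batch": batch, "age_days": age}, index=pd.Index(samples, name="sample_id")
    )

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_genes)
    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, size=(n_genes, cfg.n_batches))
    log_mu = baseline[:, None] + cfg.latent_scale * latent + batch_shift[:, batch_idx]
    mu = np.exp(log_mu)
    r = 1.0 / cfg.count_dispersion  # NB size parameter; var = mu + phi*mu^2
    counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth.latent = pd.DataFrame(latent, index=counts_df.index, columns=samples)

    lengths = rng.integers(500, 5000, size=n_genes)
    chroms = [str(c) for c in range(1, 20)] + ["X"]
    gene_chrom = rng.choice(chroms, size=n_genes)
    gene_start = rng.integers(0, 100_000_000, size=n_genes)
    gene_table = pd.DataFrame(
        {
            "chrom": gene_chrom,
            "start": gene_start,
            "end": gene_start + lengths,
            "length": lengths,
            "human_homolog": [g.upper() for g in genes],
            "is_known_bone": [g in truth.bone_genes for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return counts_df, covariates, gene_table, truth


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and per-gene lengths (bp)."""
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


# ---------------------------------------------------------------------------
# GWAS / eQTL summary-statistic pairs
# ---------------------------------------------------------------------------

def _bvn_lower_cdf(a: np.ndarray, b: np.ndarray, rho: np.ndarray, n_quad: int = 64) -> np.ndarray:
    """P(Z1 < a, Z2 < b) for standard bivariate normals, vectorized over pairs.

    Gauss-Legendre quadrature of the conditional normal CDF over z1 in
    (-8, a); accurate to ~1e-6, ample for liability calibration.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rho = np.clip(np.asarray(rho, dtype=float), -0.999999, 0.999999)
    lo = -8.0
    xs, ws = np.polynomial.legendre.leggauss(n_quad)
    # map nodes to (lo, a) per pair
    half = (a - lo) / 2.0
    mid = (a + lo) / 2.0
    z = mid[..., None] + half[..., None] * xs  # (..., n_quad)
    denom = np.sqrt(1.0 - rho[..., None] ** 2)
    cond = stats.norm.cdf((b[..., None] - rho[..., None] * z) / denom)
    integrand = stats.norm.pdf(z) * cond
    return half * (integrand * ws).sum(axis=-1)


def _calibrate_liability_rho(f1: np.ndarray, f2: np.ndarray, target: float) -> np.ndarray:
    """Latent AR(1) coefficients giving allele (dosage) correlation ~ target.

    Alleles are indicators 1{Z < Phi^-1(f)} of correlated standard normals;
    the implied Bernoulli correlation is attenuated relative to the latent
    one, so we invert it by bisection.  Where the target exceeds the
    Frechet-feasible correlation for the pair of frequencies, the latent
    coefficient saturates near 1.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if target == 0.0:
        return np.zeros_like(f1)
    a = stats.norm.ppf(f1)
    b = stats.norm.ppf(f2)
    sd = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
    lo = np.zeros_like(f1)
    hi = np.full_like(f1, 0.999999)
    for _ in range(40):
        mid = (lo + hi) / 2.0
        corr = (_bvn_lower_cdf(a, b, mid) - f1 * f2) / sd
        too_low = corr < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return (lo + hi) / 2.0


def _gen_dosages(
    rng: np.random.Generator, n: int, maf: np.ndarray, ld_rho: float
) -> np.ndarray:
    """n x n_snps dosage matrix: two haplotypes from thresholded AR(1) liabilities."""
    n_snps = maf.size
    rho_z = _calibrate_liability_rho(maf[:-1], maf[1:], ld_rho) if n_snps > 1 else np.empty(0)
    thresh = stats.norm.ppf(maf)
    dosage = np.zeros((n, n_snps), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n, n_snps))
        z[:, 0] = rng.standard_normal(n)
        eps = rng.standard_normal((n, n_snps - 1)) if n_snps > 1 else None
        for j in range(1, n_snps):
            r = rho_z[j - 1]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j - 1]
        dosage += (z < thresh[None, :]).astype(np.int8)
    return dosage


def _marginal_stats(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP simple-regression beta and SE (intercept included, exact OLS)."""
    n = y.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = (gc * yc[:, None]).sum(axis=0) / sxx
    rss = (yc**2).sum() - beta**2 * sxx
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def gen_assoc_pair(
    scenario: str,
    n_snps: int,
    ld_rho: float,
    n1: int,
    n2: int,
    var_explained: float,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    chrom: str = "1",
    start_bp: int = 1_000_000,
    spacing_bp: int = 2_000,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate summary statistics for a GWAS/eQTL pair under one hypothesis.

    Two independent cohorts share SNP positions and generating allele
    frequencies.  H4 plants one causal SNP shared by both traits; H3 two
    well-separated causal SNPs; H1/H2 one trait only; H0 none.  Returned
    tables carry per-SNP marginal beta, SE, empirical MAF and N.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if not (0.0 < var_explained < 1.0):
        raise ValueError("var_explained must be in (0, 1)")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")

    rng = _spawn(seed, 7)
    maf = rng.uniform(*maf_range, size=n_snps)

    c_shared = n_snps // 2
    c_alt = min(n_snps - 1, (3 * n_snps) // 4)
    c1_list: list[int] = []
    c2_list: list[int] = []
    if scenario == "H1":
        c1_list = [c_shared]
    elif scenario == "H2":
        c2_list = [c_shared]
    elif scenario == "H3":
        c1_list = [n_snps // 4]
        c2_list = [c_alt]
    elif scenario == "H4":
        c1_list = [c_shared]
        c2_list = [c_shared]

    b = np.sqrt(var_explained / (1.0 - var_explained))

    def one_cohort(n: int, causal: list[int], key: int) -> tuple[np.ndarray, np.ndarray]:
        crng = _spawn(seed, 7, key)
        g = _gen_dosages(crng, n, maf, ld_rho)
        y = crng.standard_normal(n)
        for c in causal:
            gc = g[:, c].astype(float)
            sd = gc.std()
            if sd > 0:
                y = y + b * (gc - gc.mean()) / sd
        return g, y

    g1, y1 = one_cohort(n1, c1_list, 1)
    g2, y2 = one_cohort(n2, c2_list, 2)

    frames = []
    for g, y, n in ((g1, y1, n1), (g2, y2, n2)):
        beta, se = _marginal_stats(g.astype(float), y)
        f = g.mean(axis=0) / 2.0
        emp_maf = np.clip(np.minimum(f, 1.0 - f), 1e-6, 0.5)
        frames.append(
            pd.DataFrame(
                {
                    "snp": [f"rs{j}" for j in range(n_snps)],
                    "chr": chrom,
                    "bp": start_bp + spacing_bp * np.arange(n_snps),
                    "beta": beta,
                    "se": se,
                    "maf": emp_maf,
                    "n": n,
                }
            )
        )
    truth = SimTruth(
        coloc_scenario=scenario,
        causal_snp_indices={"trait1": c1_list, "trait2": c2_list},
    )
    return frames[0], frames[1], truth


# ---------------------------------------------------------------------------
# genomic landscape
# ---------------------------------------------------------------------------

def gen_gene_landscape(
    n_genes: int,
    n_leads: int,
    chrom_sizes: dict[str, int],
    seed: int,
    gene_length_range: tuple[int, int] = (10_000, 200_000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random gene intervals and lead-SNP positions.

    Chromosomes are chosen proportional to length; a gene longer than every
    chromosome raises.  Returns (gene_table, lead_table).
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes must be nonempty")
    rng = _spawn(seed, 23)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()

    rows = []
    for i in range(n_genes):
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        fit = sizes >= length
        if not fit.any():
            raise ValueError(f"gene length {length} exceeds every chromosome")
        p = np.where(fit, probs, 0.0)
        p = p / p.sum()
        ci = rng.choice(len(chroms), p=p)
        start = int(rng.integers(0, chrom_sizes[chroms[ci]] - length + 1))
        rows.append((f"gene{i:05d}", chroms[ci], start, start + length))
    gene_table = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]).set_index("gene_id")

    lead_rows = []
    for j in range(n_leads):
        ci = rng.choice(len(chroms), p=probs)
        pos = int(rng.integers(0, chrom_sizes[chroms[ci]]))
        lead_rows.append((chroms[ci], pos, f"lead{j:04d}"))
    leads = pd.DataFrame(lead_rows, columns=["chrom", "pos", "snp_id"])
    return gene_table, leads


def truth_asdict(truth: SimTruth) -> dict:
    return truth.to_json_dict()


def gen_ban_testbed(
    seed: int,
    n_other_modules: int = 4,
    module_size: int = 40,
    bone_elsewhere: int = 18,
) -> tuple[dict[str, nx.DiGraph], set[str], str]:
    """Network set with one uniquely bone-enriched driver, for BAN checks.

    The driver module wires 12 bone genes onto the driver through branches of
    radius 1, 2 and 3 (four of each), so the driver's 3-step neighborhood
    holds all 12 while every other gene in the module sees strictly fewer at
    a comparable neighborhood size.  Remaining bone genes are spread over
    ``n_other_modules`` planted-DAG modules where no gene concentrates them.

    Returns (module -> DAG map, bone gene set, driver gene id).
    """
    rng = _spawn(seed, 77)
    g = nx.DiGraph()
    driver = "drv000"
    bone: set[str] = set()
    filler_root = None
    for b in range(4):  # radius-1 branches
        node = f"boneA{b}"
        g.add_edge(driver, node, weight=1.0)
        bone.add(node)
    for b in range(4):  # radius-2 branches
        mid = f"relB{b}"
        node = f"boneB{b}"
        g.add_edge(driver, mid, weight=1.0)
        g.add_edge(mid, node, weight=1.0)
        bone.add(node)
    for b in range(4):  # radius-3 branches
        m1, m2 = f"relC{b}a", f"relC{b}b"
        node = f"boneC{b}"
        g.add_edge(driver, m1, weight=1.0)
        g.add_edge(m1, m2, weight=1.0)
        g.add_edge(m2, node, weight=1.0)
        bone.add(node)
        filler_root = node
    # filler chain beyond the driver's 3-step horizon
    prev = filler_root
    for i in range(module_size - g.number_of_nodes()):
        node = f"fill{i:03d}"
        g.add_edge(prev, node, weight=1.0)
        prev = node
    networks = {"Mdriver": g}
    per_mod = int(np.ceil(bone_elsewhere / n_other_modules))
    placed = 0
    for m in range(n_other_modules):
        nb = min(per_mod, bone_elsewhere - placed)
        dag, _, mod_bone = gen_module_dag(module_size, nb, seed=int(rng.integers(2**31)))
        relabel = {v: f"m{m}g{v:03d}" for v in dag.nodes()}
        networks[f"M{m + 1}"] = nx.relabel_nodes(dag, relabel)
        bone.update(relabel[v] for v in mod_bone)
        placed += nb
    return networks, bone, driver
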
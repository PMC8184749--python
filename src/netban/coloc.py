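"""GWAS-eQTL colocalization with approximate Bayes factors.

Each SNP's evidence of association for one trait is summarized by the
Wakefield log approximate Bayes factor

    log ABF = 0.5 * (log(1 - r) + r * z^2),   r = W / (V + W),

with z = beta/se, V = se^2 and W the prior effect variance.  Under a
single-causal-variant-per-trait assumption, the five hypothesis posteriors
over a window of aligned SNPs are proportional to

    L0 = 1
    L1 = p1  * sum_i BF1_i
    L2 = p2  * sum_j BF2_j
    L3 = p1 * p2 * (sum_i BF1_i * sum_j BF2_j - sum_i BF1_i BF2_i)
    L4 = p12 * sum_i BF1_i BF2_i

(all sums log-sum-exp stabilized).  A pair is called colocalizing when
PPH4 >= 0.75; the analysis window is +/- 200 kb of the GWAS lead (inclusive).
Default priors p1 = p2 = 1e-4, p12 = 1e-5 and prior effect SD 0.15 are the
quantitative-trait convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats


@dataclass
class ColocPriors:
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_effect_sd: float = 0.15

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0 or self.prior_effect_sd <= 0:
            raise ValueError("priors must be positive")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")


@dataclass
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    colocalizing: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


class NoSnpOverlapError(ValueError):
    """No SNPs shared between the two datasets inside the analysis window."""


def log_abf(beta, se, prior_effect_sd: float = 0.15):
    """Wakefield log approximate Bayes factor (association vs null)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("beta and se must be finite")
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    v = se**2
    w = prior_effect_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def abf_from_pvalue_maf(p, maf, n, prior_effect_sd: float = 0.15):
    """log ABF when only p-value, MAF and N are available.

    |z| is reconstructed from the two-sided p-value and V approximated by
    1/(2 n maf (1-maf)) assuming unit trait variance; the ABF depends on z
    only through z^2, so the unknown sign is immaterial.
    """
    z = stats.norm.isf(np.asarray(p, dtype=float) / 2.0)
    v = 1.0 / (2.0 * np.asarray(n, float) * np.asarray(maf, float) * (1.0 - np.asarray(maf, float)))
    se = np.sqrt(v)
    return log_abf(z * se, se, prior_effect_sd)


def coloc_posteriors(
    labf1,
    labf2,
    priors: ColocPriors | None = None,
    pph4_threshold: float = 0.75,
) -> ColocResult:
    """Five-hypothesis posterior from aligned per-SNP log Bayes factors."""
    priors = priors or ColocPriors()
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1 or l1.size < 1:
        raise ValueError("labf1 and labf2 must be equal-length 1-D arrays of aligned SNPs")
    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    logl = np.empty(5)
    logl[0] = 0.0
    logl[1] = np.log(priors.p1) + ls1
    logl[2] = np.log(priors.p2) + ls2
    # L3 = p1 p2 (S1 S2 - S12), clamped at zero (exactly zero with one SNP)
    diff = ls12 - (ls1 + ls2)
    if diff >= 0.0:
        logl[3] = -np.inf
    else:
        logl[3] = np.log(priors.p1) + np.log(priors.p2) + ls1 + ls2 + np.log1p(-np.exp(diff))
    logl[4] = np.log(priors.p12) + ls12
    pp = np.exp(logl - logsumexp(logl))
    pp = pp / pp.sum()
    return ColocResult(*map(float, pp), n_snps=int(l1.size), colocalizing=bool(pp[4] >= pph4_threshold))


def run_coloc_scan(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    lead_position: int,
    window: int = 200_000,
    priors: ColocPriors | None = None,
    pph4_threshold: float = 0.75,
) -> ColocResult:
    """Colocalize GWAS and eQTL summary stats around a lead position.

    Both tables (columns ``snp, chr, bp, beta, se, maf, n``) are restricted
    to |bp - lead_position| <= window (inclusive boundary) and intersected on
    SNP id before computing per-trait log ABFs.
    """
    priors = priors or ColocPriors()
    chroms = set(gwas["chr"].astype(str)) | set(eqtl["chr"].astype(str))
    if len(chroms) > 1:
        raise ValueError(f"datasets span multiple chromosomes: {sorted(chroms)}")
    g = gwas[(gwas["bp"] - lead_position).abs() <= window]
    e = eqtl[(eqtl["bp"] - lead_position).abs() <= window]
    if g.empty or e.empty:
        raise NoSnpOverlapError(
            "no SNPs inside the window for "
            + ("both datasets" if g.empty and e.empty else ("the GWAS" if g.empty else "the eQTL"))
            + f" (lead {lead_position}, window {window}); widen the window or check positions"
        )
    merged = g.merge(e, on="snp", suffixes=("_g", "_e"))
    if merged.empty:
        raise NoSnpOverlapError(
            "window contains SNPs for both traits but their SNP ids do not "
            "intersect; check identifier harmonization"
        )
    la1 = log_abf(merged["beta_g"].to_numpy(), merged["se_g"].to_numpy(), priors.prior_effect_sd)
    la2 = log_abf(merged["beta_e"].to_numpy(), merged["se_e"].to_numpy(), priors.prior_effect_sd)
    return coloc_posteriors(la1, la2, priors, pph4_threshold)
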
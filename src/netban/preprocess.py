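"""Expression filtering, normalization and covariate adjustment.

Two filters mirror the study design: an expression filter (more than
``min_reads`` reads and more than ``min_tpm`` TPM in more than
``min_fraction`` of samples — strict inequalities throughout) and a network
filter (drop genes with fewer than 10 reads in more than 90% of samples, and
genes off the autosomes/X).  Normalization is log2(CPM + 1) followed by
per-gene linear-model residualization of nuisance covariates with protected
covariates retained — a deterministic, closed-form stand-in for
variance-stabilizing transforms plus empirical-Bayes batch correction that
preserves the correlation structure the downstream networks consume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOME_X = {str(i) for i in range(1, 23)} | {"X"}


class CollinearDesignError(ValueError):
    """Raised when adjustment covariates are confounded with protected ones."""


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def filter_expressed(
    counts: pd.DataFrame,
    tpm: pd.DataFrame | None = None,
    min_reads: int = 6,
    min_tpm: float = 0.1,
    min_fraction: float = 0.2,
) -> pd.Index:
    """Genes with > min_reads reads AND > min_tpm TPM in > min_fraction of samples."""
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must be in [0, 1]")
    if min_tpm > 0 and tpm is None:
        raise ValueError("TPM matrix required when min_tpm > 0")
    ok = counts.gt(min_reads)
    if tpm is not None:
        if not counts.index.equals(tpm.index) or not counts.columns.equals(tpm.columns):
            tpm = tpm.reindex(index=counts.index, columns=counts.columns)
        ok = ok & tpm.gt(min_tpm)
    frac = ok.mean(axis=1)
    return counts.index[frac > min_fraction]


def filter_network_genes(counts: pd.DataFrame, gene_table: pd.DataFrame) -> pd.Index:
    """Network-construction filter: minimum-count rule plus autosome/X rule."""
    low = counts.lt(10).mean(axis=1) > 0.9
    keep = counts.index[~low]
    missing = keep.difference(gene_table.index)
    if len(missing):
        logger.warning("%d genes missing from annotation; excluded", len(missing))
        keep = keep.intersection(gene_table.index)
    chroms = gene_table.loc[keep, "chrom"].map(_norm_chrom)
    return keep[chroms.isin(AUTOSOME_X).to_numpy()]


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1)."""
    lib = counts.sum(axis=0).astype(float)
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def _design_columns(cov: pd.DataFrame, names: list[str]) -> tuple[np.ndarray, list[str]]:
    cols, labels = [], []
    for name in names:
        s = cov[name]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(dtype=float)
            cols.append(x - x.mean())
            labels.append(name)
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=name, drop_first=True)
            for c in dummies.columns:
                x = dummies[c].to_numpy(dtype=float)
                cols.append(x - x.mean())
                labels.append(c)
    if cols:
        return np.column_stack(cols), labels
    return np.empty((len(cov), 0)), labels


def normalize_adjust(
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
    adjust_for: list[str] | tuple[str, ...] = (),
    protect: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """log2(CPM+1), then subtract fitted nuisance-covariate components per gene.

    The per-gene linear model includes an intercept, the protected covariates
    and the adjustment covariates (categoricals as centered dummies); only the
    fitted adjustment components are subtracted, so protected structure (e.g.
    a sex effect) survives.  A rank-deficient joint design (adjustment
    confounded with protection) raises :class:`CollinearDesignError`.
    """
    overlap = set(adjust_for) & set(protect)
    if overlap:
        raise ValueError(f"covariates cannot be both adjusted and protected: {sorted(overlap)}")
    missing = [c for c in (*adjust_for, *protect) if c not in covariates.columns]
    if missing:
        raise ValueError(f"unknown covariates: {missing}")
    cov = covariates.reindex(counts.columns)
    if cov.isna().any().any():
        raise ValueError("covariates missing for some samples")

    expr = log2_cpm(counts)
    x_adj, adj_labels = _design_columns(cov, list(adjust_for))
    if x_adj.shape[1] == 0:
        return expr
    x_prot, prot_labels = _design_columns(cov, list(protect))

    n = expr.shape[1]
    design = np.column_stack([np.ones(n), x_prot, x_adj])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise CollinearDesignError(
            "design is singular; adjustment columns "
            f"{adj_labels} are collinear with [intercept, {prot_labels}]"
        )
    coef, *_ = np.linalg.lstsq(design, expr.to_numpy().T, rcond=None)
    adj_start = 1 + x_prot.shape[1]
    fitted_adj = x_adj @ coef[adj_start:]
    out = expr.to_numpy() - fitted_adj.T
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
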
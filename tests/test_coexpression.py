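"""Signed adjacency, topological overlap, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from netban import coexpression as cx
from netban import preprocess as pp


def _expr_with_corr():
    """Four genes with exact pairwise correlations 1, -1 and 0 among them."""
    t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    x = np.cos(t)
    return pd.DataFrame(
        {"S%d" % i: v for i, v in enumerate(zip(x, x, -x, np.sin(t)))},
        index=["a", "dup", "neg", "orth"],
    )


class TestSignedAdjacency:
    def test_closed_form_values(self):
        a = cx.signed_adjacency(_expr_with_corr(), power=4)
        assert a.loc["a", "dup"] == pytest.approx(1.0)
        assert a.loc["a", "neg"] == pytest.approx(0.0, abs=1e-12)
        assert a.loc["a", "orth"] == pytest.approx(0.5**4, abs=1e-12)
        assert (np.diag(a) == 0).all()
        assert np.allclose(a, a.T)

    def test_constant_gene_rejected_by_name(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            cx.signed_adjacency(expr)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cx.signed_adjacency(pd.DataFrame([[1.0, 2.0], [2.0, 1.0]]))


class TestTom:
    def test_hand_computed_triangle(self):
        # a12 = a13 = 0.5, a23 = 0: TOM_12 = (0 + 0.5)/(min(1, .5) + 1 - .5)
        a = pd.DataFrame(
            [[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tom = cx.tom_similarity(a)
        assert tom.loc["a", "b"] == pytest.approx(0.5, abs=1e-12)

    def test_disconnected_pair_and_complete_triangle(self):
        z = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        assert cx.tom_similarity(z).loc["a", "b"] == 0.0
        ones = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        tom = cx.tom_similarity(ones)
        off = tom.to_numpy()[np.triu_indices(3, 1)]
        assert np.allclose(off, 1.0)

    def test_bounds_and_direct_adjacency_lower_bound(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(-1, 1, size=(15, 15))
        c = (c + c.T) / 2
        a = ((1 + np.clip(c, -1, 1)) / 2) ** 4
        np.fill_diagonal(a, 0)
        adf = pd.DataFrame(a)
        tom = cx.tom_similarity(adf).to_numpy()
        assert tom.min() >= 0 and tom.max() <= 1
        k = a.sum(axis=1)
        lower = a / (np.minimum.outer(k, k) + 1 - a)
        np.fill_diagonal(lower, 1.0)
        assert (tom - lower >= -1e-12).all()


class TestDetectModules:
    def test_identical_genes_form_one_module(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(10)
        expr = pd.DataFrame(np.tile(v, (35, 1)), index=[f"g{i}" for i in range(35)])
        tom = cx.tom_similarity(cx.signed_adjacency(expr))
        part = cx.detect_modules(tom, expr)
        assert part.module_sizes == {"M1": 35}

    def test_small_noise_set_all_unassigned(self, caplog):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.standard_normal((20, 30)),
                            index=[f"g{i}" for i in range(20)])
        tom = cx.tom_similarity(cx.signed_adjacency(expr))
        with caplog.at_level("WARNING"):
            part = cx.detect_modules(tom, expr, min_module_size=30)
        assert (part.module_of_gene == cx.UNASSIGNED).all()

    def test_planted_modules_recovered(self, factor_study):
        cfg, (counts, cov, gene_table, truth) = factor_study
        expr = pp.normalize_adjust(counts, cov, adjust_for=["batch"], protect=["sex"])
        part = cx.detect_modules(cx.tom_similarity(cx.signed_adjacency(expr, 4)), expr)
        ari = adjusted_rand_score(
            [truth.module_of_gene[g] for g in expr.index],
            part.module_of_gene.loc[expr.index],
        )
        assert ari >= 0.9

    def test_gene_order_invariance(self, factor_study):
        cfg, (counts, cov, gene_table, truth) = factor_study
        expr = pp.normalize_adjust(counts, cov, adjust_for=["batch"], protect=["sex"])
        tom = cx.tom_similarity(cx.signed_adjacency(expr, 4))
        part1 = cx.detect_modules(tom, expr)
        rng = np.random.default_rng(3)
        perm = rng.permutation(expr.index)
        tom2 = tom.loc[perm, perm]
        part2 = cx.detect_modules(tom2, expr.loc[perm])
        ari = adjusted_rand_score(
            part1.module_of_gene.loc[expr.index], part2.module_of_gene.loc[expr.index]
        )
        assert ari == pytest.approx(1.0)


class TestEigengenes:
    def test_common_profile_recovered_positively_aligned(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(30)
        expr = pd.DataFrame(np.outer(np.ones(5), v) * rng.uniform(1, 3, 5)[:, None],
                            index=[f"g{i}" for i in range(5)])
        labels = pd.Series("M1", index=expr.index)
        e = cx.module_eigengenes(expr, labels)["M1"].to_numpy()
        vs = (v - v.mean()) / v.std(ddof=1)
        corr = np.corrcoef(e, vs)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)
        assert e @ vs > 0
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_anticorrelated_pair_tie_breaks_toward_first_gene(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(20)
        expr = pd.DataFrame([v, -v], index=["g1", "g2"])
        e = cx.module_eigengenes(expr, pd.Series("M1", index=expr.index))["M1"]
        vs = (v - v.mean()) / v.std(ddof=1)
        assert np.corrcoef(e, vs)[0, 1] > 0  # aligned with g1, not g2

    def test_matches_independent_spectral_oracle(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.standard_normal((30, 50)),
                            index=[f"g{i}" for i in range(30)])
        labels = pd.Series("M1", index=expr.index)
        e = cx.module_eigengenes(expr, labels)["M1"].to_numpy()
        # oracle: leading eigenvector of the sample covariance of standardized genes
        xs = (expr.T - expr.T.mean()) / expr.T.std(ddof=1)
        cov_s = xs.to_numpy() @ xs.to_numpy().T
        w, vecs = np.linalg.eigh(cov_s)
        oracle = vecs[:, -1]
        oracle = oracle if oracle @ xs.to_numpy().mean(axis=1) > 0 else -oracle
        assert np.abs(e - oracle).max() < 1e-8


class TestTraitAssoc:
    def test_rank_correlation_properties(self):
        rng = np.random.default_rng(7)
        eig = pd.DataFrame({"M1": rng.standard_normal(40)},
                           index=[f"S{i}" for i in range(40)])
        traits = pd.DataFrame({
            "self": eig["M1"],
            "exp": np.exp(eig["M1"]),
        })
        out = cx.eigengene_trait_assoc(eig, traits).set_index("trait")
        assert out.loc["self", "rho"] == pytest.approx(1.0)
        assert out.loc["exp", "rho"] == pytest.approx(1.0)  # monotone invariance

    def test_insufficient_pairs_flagged(self):
        eig = pd.DataFrame({"M1": [1.0, 2.0, 3.0, 4.0, 5.0]},
                           index=[f"S{i}" for i in range(5)])
        traits = pd.DataFrame({"t": [1.0, 2.0, np.nan, np.nan, np.nan]},
                              index=eig.index)
        out = cx.eigengene_trait_assoc(eig, traits)
        assert not out["estimable"].iloc[0]
        assert np.isnan(out["rho"].iloc[0])

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(8)
        eig = pd.DataFrame({"M1": rng.standard_normal(60)},
                           index=[f"S{i}" for i in range(60)])
        ps = []
        for _ in range(100):
            traits = pd.DataFrame({"t": rng.standard_normal(60)}, index=eig.index)
            ps.append(cx.eigengene_trait_assoc(eig, traits)["p"].iloc[0])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.01 <= frac <= 0.10
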
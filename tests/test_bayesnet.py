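"""Fisher-z CI tests, MMPC skeletons, Gaussian BIC, hill climbing."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from netban import bayesnet as bn
from netban import synthetic_data as sd


def all_skeleton_dags(nodes, skeleton_edges):
    """Every DAG whose edges orient a subset of the skeleton (brute force)."""
    edges = [tuple(sorted(e)) for e in skeleton_edges]
    for r in range(len(edges) + 1):
        for sub in itertools.combinations(edges, r):
            for orient in itertools.product([0, 1], repeat=len(sub)):
                g = nx.DiGraph()
                g.add_nodes_from(nodes)
                for e, o in zip(sub, orient):
                    u, v = e if o == 0 else (e[1], e[0])
                    g.add_edge(u, v)
                if nx.is_directed_acyclic_graph(g):
                    yield g


def random_dag(n, seed, max_indeg=2, wlo=0.5, whi=1.5):
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    w = {}
    for pos in range(1, n):
        v = int(order[pos])
        k = int(rng.integers(0, max_indeg + 1))
        for u in rng.choice(order[:pos], size=min(k, pos), replace=False):
            w[(int(u), v)] = rng.uniform(wlo, whi) * rng.choice([-1, 1])
            g.add_edge(int(u), v)
    return g, w


class TestFisherZ:
    def test_zero_correlation_gives_unit_p(self):
        gd = bn._GaussianData(pd.DataFrame(np.eye(4), columns=list("abcd")))
        gd.corr[:] = np.eye(4)
        r, p = bn.fisher_z_pcor_test(gd, "a", "b")
        assert r == 0.0 and p == 1.0

    def test_closed_form_statistic(self):
        gd = bn._GaussianData(
            pd.DataFrame(np.random.default_rng(0).standard_normal((100, 2)),
                         columns=["a", "b"]))
        gd.corr[0, 1] = gd.corr[1, 0] = 0.5
        r, p = bn.fisher_z_pcor_test(gd, "a", "b")
        stat = np.arctanh(r) * np.sqrt(100 - 0 - 3)
        assert stat == pytest.approx(5.4100, abs=1e-4)
        assert p == pytest.approx(6.3e-8, rel=0.05)

    def test_degenerate_correlation_flags_zero_p(self):
        x = np.random.default_rng(1).standard_normal(50)
        data = pd.DataFrame({"a": x, "b": 2 * x})
        r, p = bn.fisher_z_pcor_test(data, "a", "b")
        assert abs(r) == pytest.approx(1.0) and p == 0.0

    def test_chain_conditional_independence(self, chain3):
        g, w = chain3
        data = sd.gen_sem_data(g, w, 50_000, seed=2)
        _, p = bn.fisher_z_pcor_test(data, "X", "Z", ["Y"])
        assert p > 0.05

    def test_sample_size_guard(self):
        data = pd.DataFrame(np.random.default_rng(2).standard_normal((4, 3)),
                            columns=list("abc"))
        with pytest.raises(ValueError):
            bn.fisher_z_pcor_test(data, "a", "b", ["c"])


class TestMmpc:
    def test_independent_variables_empty_skeleton(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.standard_normal((2000, 5)), columns=list("abcde"))
        sk = bn.mmpc_skeleton(data)
        assert sk.edges == set()

    def test_chain_skeleton_exact(self, chain3):
        g, w = chain3
        data = sd.gen_sem_data(g, w, 5000, seed=4)
        sk = bn.mmpc_skeleton(data)
        assert sk.edges == {frozenset(("X", "Y")), frozenset(("Y", "Z"))}

    def test_collider_skeleton_exact(self):
        g = nx.DiGraph([("X", "Z"), ("Y", "Z")])
        data = sd.gen_sem_data(g, {e: 1.0 for e in g.edges()}, 5000, seed=5)
        sk = bn.mmpc_skeleton(data)
        assert sk.edges == {frozenset(("X", "Z")), frozenset(("Y", "Z"))}

    def test_module_size_cap_refused(self):
        data = pd.DataFrame(np.random.default_rng(6).standard_normal((10, 5)),
                            columns=list("abcde"))
        cfg = bn.BayesNetConfig(max_module_size=3)
        with pytest.raises(ValueError, match="cap"):
            bn.mmpc_skeleton(data, cfg)


class TestGaussianBic:
    def test_single_node_closed_form(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100)
        x = (x - x.mean()) / x.std()  # MLE residual variance exactly 1
        g = nx.DiGraph()
        g.add_node("a")
        score = bn.gaussian_bic(pd.DataFrame({"a": x}), g)
        assert score == pytest.approx(-146.4991, abs=1e-4)

    def test_matches_ols_loglik_oracle(self):
        g, w = random_dag(6, seed=8)
        data = sd.gen_sem_data(g, w, 500, seed=8)
        data.columns = [f"n{c}" for c in data.columns]
        gr = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes()})
        expected = 0.0
        n = len(data)
        for v in gr.nodes():
            parents = sorted(gr.predecessors(v))
            X = sm.add_constant(data[parents]) if parents else np.ones((n, 1))
            fit = sm.OLS(data[v], X).fit()
            expected += fit.llf - (len(parents) + 2) / 2 * np.log(n)
        # tolerance covers the 1e-8 ridge used in the covariance solves
        assert bn.gaussian_bic(data, gr) == pytest.approx(expected, abs=1e-3)

    def test_null_parent_lowers_score(self):
        worse = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
            g0 = nx.DiGraph()
            g0.add_nodes_from(["a", "b"])
            g1 = nx.DiGraph([("a", "b")])
            if bn.gaussian_bic(data, g1) < bn.gaussian_bic(data, g0):
                worse += 1
        assert worse == 20


class TestHillClimb:
    def test_empty_skeleton_gives_empty_dag(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        sk = bn.Skeleton(nodes=list("abc"), edges=set())
        net = bn.hill_climb(data, sk)
        assert net.graph.number_of_edges() == 0
        g0 = nx.DiGraph()
        g0.add_nodes_from("abc")
        assert net.score == pytest.approx(bn.gaussian_bic(data, g0))

    def test_correlated_pair_single_edge_deterministic_direction(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(1000)
        data = pd.DataFrame({"a": x + 0.1 * rng.standard_normal(1000), "b": x})
        sk = bn.Skeleton(nodes=["a", "b"], edges={frozenset(("a", "b"))})
        net = bn.hill_climb(data, sk)
        # both orientations are score-equivalent; lexicographic tie-break
        assert list(net.graph.edges()) == [("a", "b")]

    def test_four_node_chain_attains_exhaustive_optimum(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "D")])
        data = sd.gen_sem_data(g, {e: 1.0 for e in g.edges()}, 2000, seed=11)
        sk = bn.mmpc_skeleton(data)
        net = bn.hill_climb(data, sk)
        best = max(bn.gaussian_bic(data, dag)
                   for dag in all_skeleton_dags(sorted(data.columns), sk.edges))
        assert net.score == pytest.approx(best, abs=1e-8)
        empty = nx.DiGraph()
        empty.add_nodes_from(data.columns)
        assert net.score >= bn.gaussian_bic(data, empty)

    def test_output_acyclic_and_within_skeleton(self):
        g, w = random_dag(8, seed=12)
        data = sd.gen_sem_data(g, w, 1500, seed=12)
        data.columns = [f"n{c}" for c in data.columns]
        sk = bn.mmpc_skeleton(data)
        net = bn.hill_climb(data, sk)
        assert nx.is_directed_acyclic_graph(net.graph)
        for u, v in net.graph.edges():
            assert frozenset((u, v)) in sk.edges

    def test_gene_order_permutation_same_skeleton(self):
        g, w = random_dag(7, seed=13)
        data = sd.gen_sem_data(g, w, 2000, seed=13)
        data.columns = [f"n{c}" for c in data.columns]
        net1 = bn.mmhc(data)
        perm = list(np.random.default_rng(13).permutation(list(data.columns)))
        net2 = bn.mmhc(data[perm])
        sk1 = {frozenset(e) for e in net1.graph.edges()}
        sk2 = {frozenset(e) for e in net2.graph.edges()}
        assert sk1 == sk2

    def test_iteration_cap_flagged(self):
        g, w = random_dag(6, seed=14)
        data = sd.gen_sem_data(g, w, 1000, seed=14)
        data.columns = [f"n{c}" for c in data.columns]
        sk = bn.mmpc_skeleton(data)
        cfg = bn.BayesNetConfig(max_iterations=1)
        net = bn.hill_climb(data, sk, cfg)
        assert net.hit_iteration_cap
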
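import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netban import synthetic_data as sd


@pytest.fixture(scope="session")
def factor_study():
    """Planted 5-module factor study used by several module-level tests."""
    cfg = sd.SimConfig(
        n_samples=200, n_modules=5, genes_per_module=40, n_background_genes=100,
        loading_range=(0.8, 0.8), seed=11,
    )
    return cfg, sd.gen_expression_study(cfg)


@pytest.fixture
def chain3():
    """X -> Y -> Z linear SEM with unit weights."""
    g = nx.DiGraph([("X", "Y"), ("Y", "Z")])
    w = {("X", "Y"): 1.0, ("Y", "Z"): 1.0}
    return g, w


def sem_covariance(nodes, weights):
    """Closed-form SEM covariance (I - W)^-1 (I - W)^-T with unit noise."""
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for (u, v), wt in weights.items():
        W[idx[v], idx[u]] = wt
    A = np.linalg.inv(np.eye(len(nodes)) - W)
    return pd.DataFrame(A @ A.T, index=nodes, columns=nodes)
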
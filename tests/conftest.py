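import numpy as np
import pytest
import scipy.sparse as sp

import complexwalk as cw
from complexwalk.layers import BipartiteLinks, WeightedGraph
from complexwalk.network import assemble


@pytest.fixture
def tiny_profile():
    """Three diseases with s(1,2)=0.9, s(1,3)=0.2, s(2,3)=0.5."""
    vals = np.array(
        [
            [1.0, 0.9, 0.2],
            [0.9, 1.0, 0.5],
            [0.2, 0.5, 1.0],
        ]
    )
    return cw.SimilarityProfile(["da", "db", "dc"], vals)


@pytest.fixture
def worked_bundle():
    return cw.worked_example()


@pytest.fixture(scope="session")
def planted_bundle():
    """Default-scale planted-signal bundle, shared across tests."""
    return cw.generate(cw.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def planted_model(planted_bundle):
    return cw.DiseaseComplexModel(planted_bundle)


@pytest.fixture(scope="session")
def planted_runs(planted_model):
    return cw.run_loocv(planted_model)


def random_small_network(rng, max_nodes=60):
    """Random heterogeneous network for walk-oracle checks (l+m+n <= max)."""
    l = int(rng.integers(2, max_nodes // 3))
    m = int(rng.integers(2, max_nodes - l - 1))
    n = int(rng.integers(1, max_nodes - l - m + 1))
    diseases = [f"d{i}" for i in range(l)]
    proteins = [f"p{i}" for i in range(m)]
    complexes = [f"c{i}" for i in range(n)]

    def graph(ids, density, role):
        k = len(ids)
        a = np.where(rng.random((k, k)) < density, rng.random((k, k)), 0.0)
        a = np.triu(a, 1)
        return WeightedGraph(ids, sp.csr_matrix(a + a.T), role=role)

    D = graph(diseases, 0.4, "D")
    P = graph(proteins, 0.3, "P")
    a_pairs = {
        (d, p)
        for d in diseases
        for p in proteins
        if rng.random() < min(1.0, 3.0 / m)
    }
    if not a_pairs:
        a_pairs = {(diseases[0], proteins[0])}
    b_pairs = set()
    for c in complexes:
        size = int(rng.integers(1, min(4, m) + 1))
        for j in rng.choice(m, size=size, replace=False):
            b_pairs.add((proteins[int(j)], c))
    A = BipartiteLinks(diseases, proteins, a_pairs, float(rng.uniform(0.2, 2.0)))
    B = BipartiteLinks(proteins, complexes, b_pairs, float(rng.uniform(0.2, 2.0)))
    return assemble(D, P, A, B)
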
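"""Synthetic six-table input bundles with planted disease-complex signal.

The generator emulates the structure of the real data sources without any
download: diseases fall into phenotype clusters (high within-cluster
similarity, low between), protein complexes are partitioned among the same
clusters and draw their members from a cluster-specific protein pool
(complexes of one functional module share subunits; unrelated complexes
rarely do), and each disease's protein annotations are drawn from the
complexes of its own cluster with probability ``signal_strength`` (and
uniformly from all proteins otherwise).  The PPI layer is an Erdos-Renyi
background at a configurable mean degree, densified inside every complex.
Expression calls are independent Bernoulli draws per (tissue, gene), and
each cluster has one planted tissue on which its diseases' association
scores peak.

All randomness flows from a single master seed through named substreams,
so regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import (
    DiseaseTissueScores,
    InputBundle,
    SimilarityProfile,
    TissueTable,
    edge_table_from_pairs,
)

_STREAMS = {
    "similarity": 0,
    "complexes": 1,
    "ppi": 2,
    "associations": 3,
    "expression": 4,
    "tissues": 5,
}


@dataclass
class SynthConfig:
    """Sizes and signal levels of a synthetic bundle.

    Defaults mirror a desk-scale version of the real study: ~4.6 members
    per complex (CORUM-core like), PPI mean degree ~8 (HPRD like), two
    annotated proteins per disease, and a strong (0.9) planted
    disease-to-own-cluster-complex signal.
    """

    l_diseases: int = 120
    m_proteins: int = 400
    n_complexes: int = 60
    n_tissues: int = 6
    n_disease_clusters: int = 6
    complex_size_range: tuple[int, int] = (4, 6)
    ppi_mean_degree: float = 8.0
    assoc_per_disease: int = 2
    signal_strength: float = 0.9
    expression_density: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("l_diseases", "m_proteins", "n_complexes", "n_tissues",
                     "n_disease_clusters", "assoc_per_disease"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        lo, hi = self.complex_size_range
        if lo < 1 or hi < lo:
            raise ValidationError("complex_size_range must satisfy 1 <= min <= max")
        if hi > self.m_proteins:
            raise ValidationError("complex size exceeds number of proteins")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValidationError("signal_strength must lie in [0, 1]")
        if not 0.0 < self.expression_density <= 1.0:
            raise ValidationError("expression_density must lie in (0, 1]")
        if self.n_disease_clusters > self.l_diseases:
            raise ValidationError("more clusters than diseases")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


def _cluster_of(i: int, total: int, clusters: int) -> int:
    return i * clusters // total


def generate(config: SynthConfig) -> InputBundle:
    """Generate the six tables of one synthetic study."""
    l, m, n = config.l_diseases, config.m_proteins, config.n_complexes
    diseases = [f"d{i + 1:04d}" for i in range(l)]
    proteins = [f"p{i + 1:04d}" for i in range(m)]
    complexes = [f"c{i + 1:04d}" for i in range(n)]
    tissues = [f"t{i + 1:02d}" for i in range(config.n_tissues)]
    d_cluster = [_cluster_of(i, l, config.n_disease_clusters) for i in range(l)]
    c_cluster = [_cluster_of(i, n, config.n_disease_clusters) for i in range(n)]

    # --- similarity profile: clustered block structure -------------------
    rng = _rng(config.seed, "similarity")
    sim = np.eye(l)
    for i in range(l):
        for j in range(i + 1, l):
            if d_cluster[i] == d_cluster[j]:
                s = rng.uniform(0.6, 0.9)
            else:
                s = rng.uniform(0.0, 0.3)
            sim[i, j] = sim[j, i] = s
    similarity = SimilarityProfile(diseases, sim)

    # --- complexes: member sets drawn from each cluster's protein pool ---
    rng = _rng(config.seed, "complexes")
    lo, hi = config.complex_size_range
    p_cluster = [_cluster_of(i, m, config.n_disease_clusters) for i in range(m)]
    pools = {
        g: [i for i in range(m) if p_cluster[i] == g]
        for g in range(config.n_disease_clusters)
    }
    members: dict[str, list[str]] = {}
    for ci, cid in enumerate(complexes):
        pool = pools[c_cluster[ci]]
        size = int(rng.integers(lo, min(hi, len(pool)) + 1))
        chosen = rng.choice(len(pool), size=size, replace=False)
        members[cid] = sorted(proteins[pool[j]] for j in chosen)
    membership = edge_table_from_pairs(
        [(c, p) for c in complexes for p in members[c]], weight=1.0
    )

    # --- PPI: Erdos-Renyi background + densified complex subgraphs -------
    rng = _rng(config.seed, "ppi")
    p_bg = min(1.0, config.ppi_mean_degree / (m - 1))
    iu, ju = np.triu_indices(m, k=1)
    mask = rng.random(iu.size) < p_bg
    pairs = {(int(a), int(b)) for a, b in zip(iu[mask], ju[mask])}
    prot_index = {p: i for i, p in enumerate(proteins)}
    for cid in complexes:
        ms = [prot_index[p] for p in members[cid]]
        for x in range(len(ms)):
            for y in range(x + 1, len(ms)):
                if rng.random() < 0.7:
                    a, b = sorted((ms[x], ms[y]))
                    pairs.add((a, b))
    ppi = edge_table_from_pairs(
        [(proteins[a], proteins[b]) for a, b in sorted(pairs)], weight=1.0
    )

    # --- disease-protein associations with planted signal ----------------
    rng = _rng(config.seed, "associations")
    assoc_pairs: list[tuple[str, str]] = []
    for di, did in enumerate(diseases):
        own = [ci for ci in range(n) if c_cluster[ci] == d_cluster[di]]
        chosen: set[str] = set()
        while len(chosen) < config.assoc_per_disease:
            if own and rng.random() < config.signal_strength:
                cid = complexes[own[int(rng.integers(len(own)))]]
                ms = members[cid]
                chosen.add(ms[int(rng.integers(len(ms)))])
            else:
                chosen.add(proteins[int(rng.integers(m))])
        assoc_pairs.extend((did, p) for p in sorted(chosen))
    disease_protein = edge_table_from_pairs(assoc_pairs, weight=1.0)

    # --- expression calls -------------------------------------------------
    rng = _rng(config.seed, "expression")
    expr = (rng.random((config.n_tissues, m)) < config.expression_density).astype(
        float
    )
    expression = TissueTable(tissues, proteins, expr)

    # --- disease-tissue scores peaked on one tissue per cluster -----------
    rng = _rng(config.seed, "tissues")
    scores = rng.uniform(0.0, 0.5, size=(l, config.n_tissues))
    for di in range(l):
        planted = d_cluster[di] % config.n_tissues
        scores[di, planted] = rng.uniform(0.7, 1.0)
    disease_tissue = DiseaseTissueScores(diseases, tissues, scores)

    return InputBundle(
        similarity=similarity,
        ppi=ppi,
        expression=expression,
        disease_tissue=disease_tissue,
        disease_protein=disease_protein,
        membership=membership,
    )


def shuffled_signal(config: SynthConfig) -> SynthConfig:
    """Null variant of *config*: associations carry no cluster signal."""
    from dataclasses import replace

    return replace(config, signal_strength=0.0)


def worked_example() -> InputBundle:
    """Fixed miniature bundle (4 diseases, 6 proteins, 3 complexes).

    Small enough that the steady state of the walk can be verified by a
    dense linear solve by hand or in a test.  d1/d2 form one phenotype
    pair annotated to proteins of complexes c1/c2; d3/d4 form another
    annotated to c3's members.
    """
    diseases = ["d1", "d2", "d3", "d4"]
    proteins = ["p1", "p2", "p3", "p4", "p5", "p6"]
    sim = np.array(
        [
            [1.0, 0.8, 0.2, 0.1],
            [0.8, 1.0, 0.3, 0.15],
            [0.2, 0.3, 1.0, 0.7],
            [0.1, 0.15, 0.7, 1.0],
        ]
    )
    ppi = edge_table_from_pairs(
        [("p1", "p2"), ("p2", "p3"), ("p3", "p4"), ("p4", "p5"), ("p5", "p6"),
         ("p2", "p5")],
        weight=1.0,
    )
    membership = edge_table_from_pairs(
        [("c1", "p1"), ("c1", "p2"), ("c2", "p3"), ("c2", "p4"),
         ("c3", "p5"), ("c3", "p6")],
        weight=1.0,
    )
    disease_protein = edge_table_from_pairs(
        [("d1", "p1"), ("d2", "p2"), ("d3", "p5"), ("d4", "p6")], weight=1.0
    )
    expression = TissueTable(
        ["t1", "t2"],
        proteins,
        np.array(
            [
                [1, 1, 1, 1, 0, 0],
                [0, 0, 1, 1, 1, 1],
            ],
            dtype=float,
        ),
    )
    disease_tissue = DiseaseTissueScores(
        diseases,
        ["t1", "t2"],
        np.array(
            [
                [0.9, 0.1],
                [0.8, 0.2],
                [0.1, 0.9],
                [0.2, 0.8],
            ]
        ),
    )
    return InputBundle(
        similarity=SimilarityProfile(diseases, sim),
        ppi=ppi,
        expression=expression,
        disease_tissue=disease_tissue,
        disease_protein=disease_protein,
        membership=membership,
    )
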
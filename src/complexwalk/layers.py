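"""Builders for the three network layers and the two bipartite connectors.

The heterogeneous network has a disease-disease similarity layer on top
(built from the phenotype similarity profile with either a k-nearest-
neighbour or a similarity-threshold rule), a tissue-specific protein-protein
interaction layer in the middle (node removal or edge reweighting against
expression calls), and a protein-complex membership layer at the bottom.
Disease-protein association edges (uniform weight alpha) connect the top two
layers; membership edges (uniform weight beta) connect the bottom two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import DiseaseLookupError, ParameterError, ValidationError
from .io import DiseaseTissueScores, EdgeTable, SimilarityProfile

logger = logging.getLogger(__name__)


@dataclass
class WeightedGraph:
    """One intra-layer network: ordered node ids + symmetric adjacency.

    ``role`` is ``"D"`` for the disease layer and ``"P"`` for the protein
    layer.  The adjacency is sparse, symmetric, nonnegative, with a zero
    diagonal; isolated nodes are legal (their rows are all-zero).
    """

    node_ids: list[str]
    adjacency: sp.csr_matrix
    role: str = "P"
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        self.adjacency = sp.csr_matrix(self.adjacency, shape=(n, n), dtype=float)
        if self.adjacency.diagonal().any():
            raise ValidationError("layer adjacency must have a zero diagonal")
        if (self.adjacency.data < 0).any():
            raise ValidationError("layer weights must be nonnegative")
        asym = abs(self.adjacency - self.adjacency.T)
        if asym.nnz and asym.max() > 1e-9:
            raise ValidationError("layer adjacency must be symmetric")
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return sp.triu(self.adjacency, k=1).nnz

    def index(self, node_id: str) -> int:
        return self._index[node_id]

    def edge_set(self) -> set[tuple[str, str]]:
        """Undirected edges as (min_id, max_id) pairs."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        out = set()
        for i, j in zip(coo.row, coo.col):
            a, b = self.node_ids[i], self.node_ids[j]
            out.add((min(a, b), max(a, b)))
        return out


@dataclass
class BipartiteLinks:
    """Uniformly weighted links between two layers.

    ``uniform_weight`` is alpha for disease-protein links and beta for
    protein-complex links.
    """

    left_ids: list[str]
    right_ids: list[str]
    pairs: set[tuple[str, str]]
    uniform_weight: float

    def __post_init__(self) -> None:
        if self.uniform_weight <= 0:
            raise ParameterError("bipartite link weight must be positive")
        known_l, known_r = set(self.left_ids), set(self.right_ids)
        for a, b in self.pairs:
            if a not in known_l or b not in known_r:
                raise ValidationError(f"link ({a}, {b}) references unknown id")


def _graph_from_edges(node_ids, edges) -> sp.csr_matrix:
    """Symmetric CSR from {(i, j): w} with i != j."""
    n = len(node_ids)
    if not edges:
        return sp.csr_matrix((n, n), dtype=float)
    rows, cols, data = [], [], []
    for (i, j), w in edges.items():
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n), dtype=float)


# ---------------------------------------------------------------------------
# disease layer
# ---------------------------------------------------------------------------


def _neighbour_order(sims: np.ndarray, ids: list[str], self_idx: int) -> list[int]:
    """Candidate neighbours of one disease by decreasing similarity.

    Ties at equal similarity break by lexicographic disease id so builds are
    reproducible regardless of input row order.
    """
    cand = [j for j in range(len(ids)) if j != self_idx]
    return sorted(cand, key=lambda j: (-sims[j], ids[j]))


def build_disease_layer_knn(
    profile: SimilarityProfile,
    k: int = 15,
    weighted: bool = True,
    mode: str = "union",
) -> WeightedGraph:
    """k-nearest-neighbour disease similarity layer.

    Each disease selects its ``k`` most similar other diseases.  In
    ``"union"`` mode (default) an undirected edge {i, j} exists when either
    endpoint selects the other; ``"mutual"`` requires both.  Edge weight is
    the similarity value, or 1 when ``weighted=False``.  ``k`` at or above
    the number of other diseases yields the complete graph with a warning.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if mode not in ("union", "mutual"):
        raise ParameterError(f"unknown knn mode {mode!r}")
    ids = profile.disease_ids
    l = len(ids)
    if k >= l:
        logger.warning("k=%d >= number of diseases %d: complete graph", k, l)
    selected: list[set[int]] = []
    for i in range(l):
        order = _neighbour_order(profile.values[i], ids, i)
        selected.append(set(order[:k]))
    edges: dict[tuple[int, int], float] = {}
    for i in range(l):
        for j in selected[i]:
            a, b = min(i, j), max(i, j)
            if mode == "mutual" and i not in selected[j]:
                continue
            w = float(profile.values[a, b]) if weighted else 1.0
            edges[(a, b)] = w
    return WeightedGraph(list(ids), _graph_from_edges(ids, edges), role="D")


def build_disease_layer_threshold(
    profile: SimilarityProfile, delta: float = 0.35, weighted: bool = True
) -> WeightedGraph:
    """Threshold disease layer: edge {i, j} iff similarity(i, j) >= delta."""
    if not 0.0 <= delta <= 1.0:
        raise ParameterError("delta must lie in [0, 1]")
    ids = profile.disease_ids
    vals = profile.values
    mask = np.triu(vals >= delta, k=1)
    edges = {
        (int(i), int(j)): (float(vals[i, j]) if weighted else 1.0)
        for i, j in zip(*np.nonzero(mask))
    }
    return WeightedGraph(list(ids), _graph_from_edges(ids, edges), role="D")


# ---------------------------------------------------------------------------
# tissue assignment and tissue-specific PPI
# ---------------------------------------------------------------------------


def assign_tissue(disease_id: str, scores: DiseaseTissueScores) -> str:
    """Tissue with the highest association score for *disease_id*.

    Ties break in favour of the tissue that appears first in the input
    table.  Unknown diseases raise :class:`DiseaseLookupError`; the caller
    may fall back to the generic PPI layer.
    """
    if disease_id not in scores.disease_ids:
        raise DiseaseLookupError(
            f"disease {disease_id!r} has no tissue association scores"
        )
    row = scores.scores[scores.disease_ids.index(disease_id)]
    row = np.where(np.isfinite(row), row, -np.inf)
    return scores.tissue_ids[int(np.argmax(row))]


def build_tissue_ppi_nr(
    generic: WeightedGraph, expressed_genes: set[str]
) -> WeightedGraph:
    """Node-removal tissue PPI: drop all edges touching non-expressed proteins.

    The returned graph keeps the full generic node set, with removed
    proteins left isolated, so indices into the heterogeneous matrix are
    identical across tissues.
    """
    if not expressed_genes:
        logger.warning("empty expressed-gene set: all proteins isolated")
    keep = np.array(
        [nid in expressed_genes for nid in generic.node_ids], dtype=float
    )
    d = sp.diags(keep)
    adj = (d @ generic.adjacency @ d).tocsr()
    adj.eliminate_zeros()
    return WeightedGraph(list(generic.node_ids), adj, role="P")


def build_tissue_ppi_erw(
    generic: WeightedGraph, expressed_genes: set[str], rw: float = 0.1
) -> WeightedGraph:
    """Edge-reweight tissue PPI.

    Every edge weight is multiplied by ``rw`` once per endpoint that is not
    expressed in the tissue: factor 1 when both endpoints are expressed,
    ``rw`` for exactly one, ``rw**2`` for neither.
    """
    if not 0.0 <= rw <= 1.0:
        raise ParameterError("rw must lie in [0, 1]")
    factors = np.array(
        [1.0 if nid in expressed_genes else rw for nid in generic.node_ids]
    )
    d = sp.diags(factors)
    adj = (d @ generic.adjacency @ d).tocsr()
    adj.eliminate_zeros()
    return WeightedGraph(list(generic.node_ids), adj, role="P")


def graph_from_edge_table(
    table: EdgeTable, node_ids: list[str] | None = None, role: str = "P"
) -> WeightedGraph:
    """Materialize an :class:`EdgeTable` as a symmetric :class:`WeightedGraph`.

    *node_ids* may extend the table's own nodes (extra ids become isolated
    nodes); table nodes missing from an explicit *node_ids* raise.
    """
    if node_ids is None:
        node_ids = table.node_ids()
    index = {v: i for i, v in enumerate(node_ids)}
    edges: dict[tuple[int, int], float] = {}
    for (a, b), w in zip(table.pairs(), table.records["weight"].tolist()):
        if a not in index or b not in index:
            raise ValidationError(f"edge ({a}, {b}) references unknown node id")
        i, j = index[a], index[b]
        edges[(min(i, j), max(i, j))] = float(w)
    return WeightedGraph(list(node_ids), _graph_from_edges(node_ids, edges), role=role)


# ---------------------------------------------------------------------------
# bipartite connectors
# ---------------------------------------------------------------------------


def build_disease_protein_links(
    pairs: EdgeTable,
    alpha: float = 1.0,
    disease_ids: list[str] | None = None,
    protein_ids: list[str] | None = None,
) -> BipartiteLinks:
    """Disease-protein association links, all weighted alpha (> 0).

    When *disease_ids*/*protein_ids* are given, pairs referencing ids
    outside those universes are dropped with a log message (mirrors
    restricting associations to diseases with similarity scores and
    proteins present in the PPI universe).
    """
    if alpha <= 0:
        raise ParameterError("alpha must be a positive real value")
    raw = [(d, p) for d, p in pairs.pairs()]
    if disease_ids is not None or protein_ids is not None:
        dset = set(disease_ids) if disease_ids is not None else None
        pset = set(protein_ids) if protein_ids is not None else None
        kept = [
            (d, p)
            for d, p in raw
            if (dset is None or d in dset) and (pset is None or p in pset)
        ]
        if len(kept) != len(raw):
            logger.info(
                "dropped %d disease-protein pairs outside the known universes",
                len(raw) - len(kept),
            )
        raw = kept
    left = disease_ids if disease_ids is not None else sorted({d for d, _ in raw})
    right = protein_ids if protein_ids is not None else sorted({p for _, p in raw})
    return BipartiteLinks(list(left), list(right), set(raw), alpha)


def build_protein_complex_links(
    membership: EdgeTable,
    beta: float = 1.0,
    protein_ids: list[str] | None = None,
) -> BipartiteLinks:
    """Protein-complex membership links, all weighted beta (> 0).

    *membership* rows are (complex id, protein id).  When *protein_ids* is
    given, membership rows whose protein lies outside that universe are
    dropped, and complexes left with zero mappable members are removed
    entirely with a warning (a complex is only a candidate if at least one
    member maps to the protein layer).
    """
    if beta <= 0:
        raise ParameterError("beta must be a positive real value")
    rows = [(c, p) for c, p in membership.pairs()]
    all_complexes = sorted({c for c, _ in rows})
    if protein_ids is not None:
        pset = set(protein_ids)
        rows = [(c, p) for c, p in rows if p in pset]
    kept_complexes = sorted({c for c, _ in rows})
    dropped = sorted(set(all_complexes) - set(kept_complexes))
    if dropped:
        logger.warning(
            "dropped %d complexes with no member in the protein layer: %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
    right = protein_ids if protein_ids is not None else sorted({p for _, p in rows})
    # left = proteins, right = complexes in the block layout; store as
    # (protein, complex) pairs for assembly.
    pairs = {(p, c) for c, p in rows}
    return BipartiteLinks(list(right), kept_complexes, pairs, beta)
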
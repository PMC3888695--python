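"""Assembly of the heterogeneous block weight matrix and its row
normalization.

With l diseases, m proteins and n complexes, the (l+m+n) x (l+m+n) weight
matrix has the block layout::

    H = [ D    A    0 ]
        [ A^T  P    B ]
        [ 0    B^T  0 ]

where D and P are the intra-layer weight matrices, A holds the uniform
disease-protein weights (alpha) and B the uniform protein-complex weights
(beta).  Complexes carry no edges among themselves and no direct edges to
diseases.  Node order is diseases, then proteins, then complexes, each
sorted by identifier, so that position l+m+i always addresses the i-th
complex.

Row-normalizing H yields the transition matrix T with
t_ij = h_ij / sum_j h_ij.  Rows that sum to zero (isolated nodes, e.g.
proteins removed by the node-removal tissue strategy) are left as zero rows
and reported as dangling: the walker's mass entering them is lost until the
restart term re-injects it, and the final complex-score normalization
cancels the global deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import AssemblyError
from .layers import BipartiteLinks, WeightedGraph


@dataclass
class HeterogeneousNetwork:
    disease_ids: list[str]
    protein_ids: list[str]
    complex_ids: list[str]
    H: sp.csr_matrix
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        size = self.n_nodes
        if self.H.shape != (size, size):
            raise AssemblyError(
                f"H shape {self.H.shape} does not match {size} nodes"
            )
        self._index = {
            v: i
            for i, v in enumerate(
                list(self.disease_ids) + list(self.protein_ids) + list(self.complex_ids)
            )
        }

    @property
    def l(self) -> int:  # noqa: E743 - matches the block-layout convention
        return len(self.disease_ids)

    @property
    def m(self) -> int:
        return len(self.protein_ids)

    @property
    def n(self) -> int:
        return len(self.complex_ids)

    @property
    def n_nodes(self) -> int:
        return self.l + self.m + self.n

    def node_index(self, node_id: str) -> int:
        return self._index[node_id]

    def complex_slice(self) -> slice:
        return slice(self.l + self.m, self.n_nodes)


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix plus the set of dangling rows."""

    T: sp.csr_matrix
    dangling: frozenset[int]


def _links_matrix(
    links: BipartiteLinks, left_ids: list[str], right_ids: list[str], what: str
) -> sp.csr_matrix:
    li = {v: i for i, v in enumerate(left_ids)}
    ri = {v: i for i, v in enumerate(right_ids)}
    rows, cols = [], []
    for a, b in sorted(links.pairs):
        if a not in li:
            raise AssemblyError(f"{what} link references unknown id {a!r}")
        if b not in ri:
            raise AssemblyError(f"{what} link references unknown id {b!r}")
        rows.append(li[a])
        cols.append(ri[b])
    data = np.full(len(rows), links.uniform_weight, dtype=float)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(left_ids), len(right_ids)), dtype=float
    )


def assemble(
    D: WeightedGraph,
    P: WeightedGraph,
    A: BipartiteLinks,
    B: BipartiteLinks,
) -> HeterogeneousNetwork:
    """Assemble the block matrix H from the two layers and two connectors.

    ``A`` links diseases to proteins; ``B`` links proteins to complexes.
    Node ids are taken from the layer graphs (diseases from ``D``, proteins
    from ``P``) and from ``B.right_ids`` (complexes), each sorted; links
    referencing ids outside those universes raise :class:`AssemblyError`.
    """
    d_order = np.argsort(np.array(D.node_ids, dtype=object), kind="stable")
    p_order = np.argsort(np.array(P.node_ids, dtype=object), kind="stable")
    disease_ids = [D.node_ids[i] for i in d_order]
    protein_ids = [P.node_ids[i] for i in p_order]
    complex_ids = sorted(B.right_ids)
    Dm = D.adjacency[d_order][:, d_order] if D.n_nodes else D.adjacency
    Pm = P.adjacency[p_order][:, p_order] if P.n_nodes else P.adjacency
    Am = _links_matrix(A, disease_ids, protein_ids, "disease-protein")
    Bm = _links_matrix(B, protein_ids, complex_ids, "protein-complex")
    n = len(complex_ids)
    H = sp.bmat(
        [
            [Dm, Am, sp.csr_matrix((len(disease_ids), n))],
            [Am.T, Pm, Bm],
            [sp.csr_matrix((n, len(disease_ids))), Bm.T, sp.csr_matrix((n, n))],
        ],
        format="csr",
    )
    return HeterogeneousNetwork(disease_ids, protein_ids, complex_ids, H)


def extract_blocks(net: HeterogeneousNetwork):
    """Return the (D, P, A, B) blocks of H (inverse of :func:`assemble`)."""
    l, m = net.l, net.m
    H = net.H.tocsr()
    return (
        H[:l, :l],
        H[l : l + m, l : l + m],
        H[:l, l : l + m],
        H[l : l + m, l + m :],
    )


def normalize(net: HeterogeneousNetwork) -> TransitionMatrix:
    """Row-normalize H: t_ij = h_ij / sum_j h_ij.

    All-zero rows cannot be normalized; they stay zero and are returned in
    ``dangling``.
    """
    H = net.H.tocsr()
    row_sums = np.asarray(H.sum(axis=1)).ravel()
    dangling = frozenset(int(i) for i in np.nonzero(row_sums == 0)[0])
    inv = np.zeros_like(row_sums)
    nz = row_sums > 0
    inv[nz] = 1.0 / row_sums[nz]
    T = (sp.diags(inv) @ H).tocsr()
    return TransitionMatrix(T, dangling)


def dump_sparse_tsv(net: HeterogeneousNetwork, path) -> None:
    """Debug dump of H as coordinate TSV (row_id, col_id, value)."""
    ids = list(net.disease_ids) + list(net.protein_ids) + list(net.complex_ids)
    coo = net.H.tocoo()
    with open(path, "w") as fh:
        fh.write("row_id\tcol_id\tvalue\n")
        order = np.lexsort((coo.col, coo.row))
        for k in order:
            fh.write(f"{ids[coo.row[k]]}\t{ids[coo.col[k]]}\t{coo.data[k]!r}\n")
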
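"""Model/Results surface for disease -> protein-complex prioritization.

:class:`DiseaseComplexModel` is constructed from an :class:`~.io.InputBundle`
plus the strategy and walk parameters; :meth:`DiseaseComplexModel.fit` runs
the full pipeline for one query disease (tissue assignment, layer
construction, block assembly, row normalization, restart walk, scoring,
ranking) and returns a :class:`PrioritizationResults` carrying the ranking,
the convergence diagnostics and a ``summary()`` table.

Layers that do not depend on the query (the disease similarity layer, the
per-tissue PPI layers, the membership links) are built once and cached, so
repeated fits — as in leave-one-out cross-validation — only rebuild the
disease-protein connector and the block matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import layers as _layers
from . import network as _network
from . import walk as _walk
from .errors import DiseaseLookupError, ParameterError
from .io import InputBundle

logger = logging.getLogger(__name__)

#: recommended defaults: k = 15 neighbours, unit connector weights,
#: restart probability 0.5, edge-reweight factor 0.1, tolerance 1e-5
DEFAULTS = {
    "disease_layer": "knn",
    "k": 15,
    "delta": 0.35,
    "weighted": True,
    "knn_mode": "union",
    "ppi": "erw",
    "rw": 0.1,
    "expr_cutoff": 0.5,
    "alpha": 1.0,
    "beta": 1.0,
    "gamma": 0.5,
    "epsilon": 1e-5,
    "max_iter": 10_000,
}

_GENERIC = "__generic__"


class DiseaseComplexModel:
    """Random-walk prioritization of protein complexes for query diseases.

    Parameters
    ----------
    bundle
        The six input tables.
    disease_layer
        ``"knn"`` (default) or ``"threshold"`` strategy for the disease
        similarity layer.
    k, delta, weighted, knn_mode
        Disease-layer parameters: number of nearest neighbours, similarity
        cut-off, whether edges carry similarity weights, and whether the
        k-NN rule is the union or mutual-selection variant.
    ppi, rw, expr_cutoff
        Middle-layer strategy: ``"erw"`` (edge reweight, default),
        ``"nr"`` (node removal) or ``"generic"`` (tissue-nonspecific);
        ``rw`` is the per-non-expressed-endpoint weight factor and
        ``expr_cutoff`` binarizes expression scores.
    tissue
        Explicit tissue override; by default the tissue with the highest
        association score for the query disease is used, falling back to
        the generic PPI when the query has no tissue scores.
    alpha, beta, gamma, epsilon, max_iter
        Connector weights, restart probability and convergence controls.
    """

    def __init__(
        self,
        bundle: InputBundle,
        *,
        disease_layer: str = DEFAULTS["disease_layer"],
        k: int = DEFAULTS["k"],
        delta: float = DEFAULTS["delta"],
        weighted: bool = DEFAULTS["weighted"],
        knn_mode: str = DEFAULTS["knn_mode"],
        ppi: str = DEFAULTS["ppi"],
        rw: float = DEFAULTS["rw"],
        expr_cutoff: float = DEFAULTS["expr_cutoff"],
        tissue: Optional[str] = None,
        alpha: float = DEFAULTS["alpha"],
        beta: float = DEFAULTS["beta"],
        gamma: float = DEFAULTS["gamma"],
        epsilon: float = DEFAULTS["epsilon"],
        max_iter: int = DEFAULTS["max_iter"],
    ):
        if disease_layer not in ("knn", "threshold"):
            raise ParameterError(f"unknown disease layer strategy {disease_layer!r}")
        if ppi not in ("erw", "nr", "generic"):
            raise ParameterError(f"unknown PPI strategy {ppi!r}")
        self.bundle = bundle
        self.disease_layer = disease_layer
        self.k = int(k)
        self.delta = float(delta)
        self.weighted = bool(weighted)
        self.knn_mode = knn_mode
        self.ppi = ppi
        self.rw = float(rw)
        self.expr_cutoff = float(expr_cutoff)
        self.tissue = tissue
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.gamma = float(gamma)
        self.epsilon = float(epsilon)
        self.max_iter = int(max_iter)

        # protein universe: PPI nodes plus any annotated or member protein,
        # so isolated-but-annotated proteins keep a stable index
        self.protein_ids: list[str] = sorted(
            set(bundle.ppi.node_ids())
            | {p for _, p in bundle.disease_protein.pairs()}
            | {p for _, p in bundle.membership.pairs()}
        )
        self.disease_ids: list[str] = sorted(bundle.similarity.disease_ids)

        self._disease_graph: Optional[_layers.WeightedGraph] = None
        self._disease_graph_override: Optional[_layers.WeightedGraph] = None
        self._generic_graph: Optional[_layers.WeightedGraph] = None
        self._tissue_graphs: dict[str, _layers.WeightedGraph] = {}
        self._b_links: Optional[_layers.BipartiteLinks] = None
        self._members: Optional[dict[str, list[str]]] = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_tables(cls, directory, **kwargs) -> "DiseaseComplexModel":
        """Build a model from a directory holding the six TSV tables."""
        return cls(InputBundle.load(directory), **kwargs)

    # -- cached layers ----------------------------------------------------

    def params(self) -> dict:
        return {
            "disease_layer": self.disease_layer,
            "k": self.k,
            "delta": self.delta,
            "weighted": self.weighted,
            "knn_mode": self.knn_mode,
            "ppi": self.ppi,
            "rw": self.rw,
            "expr_cutoff": self.expr_cutoff,
            "tissue": self.tissue,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "epsilon": self.epsilon,
            "max_iter": self.max_iter,
        }

    @property
    def disease_graph(self) -> _layers.WeightedGraph:
        if self._disease_graph_override is not None:
            return self._disease_graph_override
        if self._disease_graph is None:
            if self.disease_layer == "knn":
                self._disease_graph = _layers.build_disease_layer_knn(
                    self.bundle.similarity,
                    k=self.k,
                    weighted=self.weighted,
                    mode=self.knn_mode,
                )
            else:
                self._disease_graph = _layers.build_disease_layer_threshold(
                    self.bundle.similarity, delta=self.delta, weighted=self.weighted
                )
        return self._disease_graph

    def set_disease_graph(self, graph: _layers.WeightedGraph) -> None:
        """Install a pre-built (e.g. perturbed) disease layer."""
        self._disease_graph_override = graph

    @property
    def generic_graph(self) -> _layers.WeightedGraph:
        if self._generic_graph is None:
            self._generic_graph = _layers.graph_from_edge_table(
                self.bundle.ppi, node_ids=self.protein_ids, role="P"
            )
        return self._generic_graph

    def protein_graph(self, tissue: Optional[str]) -> _layers.WeightedGraph:
        """Tissue-specific (or generic) PPI layer, cached per tissue."""
        key = tissue if (tissue and self.ppi != "generic") else _GENERIC
        if key not in self._tissue_graphs:
            if key == _GENERIC:
                self._tissue_graphs[key] = self.generic_graph
            else:
                expressed = self.bundle.expression.expressed_genes(
                    tissue, cutoff=self.expr_cutoff
                )
                if self.ppi == "nr":
                    self._tissue_graphs[key] = _layers.build_tissue_ppi_nr(
                        self.generic_graph, expressed
                    )
                else:
                    self._tissue_graphs[key] = _layers.build_tissue_ppi_erw(
                        self.generic_graph, expressed, rw=self.rw
                    )
        return self._tissue_graphs[key]

    @property
    def complex_links(self) -> _layers.BipartiteLinks:
        if self._b_links is None:
            self._b_links = _layers.build_protein_complex_links(
                self.bundle.membership, beta=self.beta, protein_ids=self.protein_ids
            )
        return self._b_links

    @property
    def complex_ids(self) -> list[str]:
        return list(self.complex_links.right_ids)

    @property
    def complex_members(self) -> dict[str, list[str]]:
        if self._members is None:
            kept = set(self.complex_ids)
            members = self.bundle.complex_members()
            self._members = {c: ps for c, ps in members.items() if c in kept}
        return self._members

    # -- fitting ----------------------------------------------------------

    def tissue_for(self, query_disease: str) -> Optional[str]:
        """Tissue used for the query, or None for the generic network."""
        if self.ppi == "generic":
            return None
        if self.tissue is not None:
            return self.tissue
        try:
            return _layers.assign_tissue(query_disease, self.bundle.disease_tissue)
        except DiseaseLookupError:
            logger.info(
                "query %s has no tissue scores; using the generic PPI layer",
                query_disease,
            )
            return None

    def _disease_protein_links(
        self, mask_query: Optional[str]
    ) -> _layers.BipartiteLinks:
        pairs = self.bundle.disease_protein
        if mask_query is not None:
            kept = pairs.records[
                (pairs.records["node_a"] != mask_query)
                & (pairs.records["node_b"] != mask_query)
            ]
            pairs = type(pairs)(kept.reset_index(drop=True))
        return _layers.build_disease_protein_links(
            pairs,
            alpha=self.alpha,
            disease_ids=self.disease_ids,
            protein_ids=self.protein_ids,
        )

    def build_network(
        self,
        query_disease: str,
        *,
        mask_query_associations: bool = False,
        include_complex_layer: bool = True,
    ) -> _network.HeterogeneousNetwork:
        """Assemble the heterogeneous network for one query."""
        tissue = self.tissue_for(query_disease)
        P = self.protein_graph(tissue)
        D = self.disease_graph
        A = self._disease_protein_links(
            query_disease if mask_query_associations else None
        )
        if include_complex_layer:
            B = self.complex_links
        else:
            B = _layers.BipartiteLinks(self.protein_ids, [], set(), self.beta)
        return _network.assemble(D, P, A, B)

    def fit(
        self,
        query_disease: str,
        *,
        method: str = "rwr",
        mask_query_associations: bool = False,
    ) -> "PrioritizationResults":
        """Score and rank all candidate complexes for *query_disease*.

        ``method="rwr"`` (default) walks the full three-layer network and
        scores complexes by their normalized steady-state mass;
        ``method="naive"`` walks the two-layer disease-protein network and
        scores each complex by the plain sum of its members' mass.
        ``mask_query_associations=True`` removes every disease-protein edge
        of the query before building the network (the leave-one-out
        setting).
        """
        if method not in ("rwr", "naive"):
            raise ParameterError(f"unknown method {method!r}")
        if query_disease not in set(self.disease_ids):
            raise DiseaseLookupError(
                f"query disease {query_disease!r} not in the disease layer"
            )
        net = self.build_network(
            query_disease,
            mask_query_associations=mask_query_associations,
            include_complex_layer=(method == "rwr"),
        )
        tm = _network.normalize(net)
        q0 = _walk.RestartVector.for_query(
            net.n_nodes, net.node_index(query_disease)
        )
        q_inf, iters, delta = _walk.walk(
            tm, q0, gamma=self.gamma, epsilon=self.epsilon, max_iter=self.max_iter
        )
        if method == "rwr":
            scores = _walk.score_complexes(q_inf, net)
        else:
            protein_mass = {
                p: float(q_inf[net.node_index(p)]) for p in net.protein_ids
            }
            scores = _walk.naive_scores(protein_mass, self.complex_members)
        ranking = _walk.rank(scores)
        return PrioritizationResults(
            model=self,
            query_disease=query_disease,
            method=method,
            tissue=self.tissue_for(query_disease),
            masked=mask_query_associations,
            scores=scores,
            ranking=ranking,
            q_inf=q_inf,
            iterations=iters,
            final_delta=delta,
        )


@dataclass
class PrioritizationResults:
    """Ranked complexes plus walk diagnostics for one query disease."""

    model: DiseaseComplexModel
    query_disease: str
    method: str
    tissue: Optional[str]
    masked: bool
    scores: dict[str, float]
    ranking: pd.DataFrame
    q_inf: np.ndarray
    iterations: int
    final_delta: float

    @property
    def n_candidates(self) -> int:
        return len(self.ranking)

    def rank_of(self, complex_id: str) -> float:
        """Mid-rank of one candidate (ties average their positions)."""
        row = self.ranking[self.ranking["complex_id"] == complex_id]
        if row.empty:
            raise KeyError(complex_id)
        return float(row["midrank"].iloc[0])

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.ranking.head(n)

    def save(self, path) -> None:
        from .io import write_ranking

        write_ranking(path, self.query_disease, self.ranking)

    def summary(self, top: int = 10) -> str:
        p = self.model.params()
        lines = [
            "Disease-protein-complex prioritization",
            "=" * 54,
            f"query disease      : {self.query_disease}",
            f"method             : {self.method}",
            f"tissue             : {self.tissue or '(generic PPI)'}",
            f"candidates ranked  : {self.n_candidates}",
            f"masked associations: {self.masked}",
            (
                f"strategy           : {p['disease_layer']} "
                f"(k={p['k']}, delta={p['delta']}, weighted={p['weighted']}), "
                f"ppi={p['ppi']} (rw={p['rw']})"
            ),
            (
                f"walk               : gamma={p['gamma']}, alpha={p['alpha']}, "
                f"beta={p['beta']}, epsilon={p['epsilon']:g}"
            ),
            (
                f"convergence        : {self.iterations} iterations, "
                f"|dq| = {self.final_delta:.3e}"
            ),
            "-" * 54,
            f"top {min(top, self.n_candidates)} candidates:",
        ]
        head = self.ranking.head(top)
        for _, r in head.iterrows():
            tie = " (tie)" if r["tie"] else ""
            lines.append(
                f"  {int(r['rank']):>4d}  {r['complex_id']:<16s} "
                f"{r['score']:.6f}{tie}"
            )
        return "\n".join(lines)


def prioritize(
    query_disease: str, bundle: InputBundle, **model_kwargs
) -> PrioritizationResults:
    """One-call pipeline: build the model and fit the query."""
    return DiseaseComplexModel(bundle, **model_kwargs).fit(query_disease)
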
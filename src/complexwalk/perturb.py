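"""Edge addition/removal robustness experiments.

A perturbation targets one of the four edge types of the heterogeneous
network (disease-disease, disease-protein, protein-protein, protein-
complex) and a signed fraction: negative fractions delete that share of the
existing edges uniformly at random, positive fractions insert the same
count of uniformly random new pairs of the correct type.  Added edges get
the mean weight of the existing edges of their type, preserving the layer's
weight scale.

Disease-disease edges live in the constructed similarity layer (the inputs
only store the similarity profile), so that type is perturbed on the built
:class:`~.layers.WeightedGraph` and installed into the model as an
override; the other three types are perturbed on their source edge tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError, PerturbationError
from .evaluation import compute_metrics, run_loocv
from .io import EdgeTable, InputBundle
from .layers import WeightedGraph
from .model import DiseaseComplexModel

EDGE_TYPES = (
    "disease-disease",
    "disease-protein",
    "protein-protein",
    "protein-complex",
)


@dataclass
class PerturbationSpec:
    edge_type: str
    fraction: float  # negative = removal, positive = addition
    seed: int
    repeats: int = 5

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ParameterError(f"unknown edge type {self.edge_type!r}")
        if not -1.0 <= self.fraction <= 1.0:
            raise ParameterError("|fraction| must be <= 1")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")


def _sample_new_pairs(
    rng: np.random.Generator,
    count: int,
    left_pool: list[str],
    right_pool: list[str],
    existing: set[tuple[str, str]],
    undirected: bool,
) -> list[tuple[str, str]]:
    """Uniform non-edges of the given type; errors when too few exist."""
    if undirected:
        total = len(left_pool) * (len(left_pool) - 1) // 2
    else:
        total = len(left_pool) * len(right_pool)
    if total - len(existing) < count:
        raise PerturbationError(
            f"cannot add {count} edges: only {total - len(existing)} "
            "non-edges available"
        )
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < count:
        a = left_pool[int(rng.integers(len(left_pool)))]
        b = right_pool[int(rng.integers(len(right_pool)))]
        if undirected:
            if a == b:
                continue
            a, b = min(a, b), max(a, b)
        key = (a, b)
        if key in existing or key in chosen:
            continue
        chosen.add(key)
    return sorted(chosen)


def _perturb_edge_table(
    table: EdgeTable,
    fraction: float,
    rng: np.random.Generator,
    left_pool: list[str],
    right_pool: list[str],
    undirected: bool,
) -> EdgeTable:
    df = table.records
    n_edges = len(df)
    count = round(abs(fraction) * n_edges)
    if count == 0:
        return table
    if fraction < 0:
        drop = rng.choice(n_edges, size=count, replace=False)
        kept = df.drop(df.index[np.sort(drop)]).reset_index(drop=True)
        return EdgeTable(kept)
    existing = {
        (min(a, b), max(a, b)) if undirected else (a, b)
        for a, b in table.pairs()
    }
    mean_w = float(df["weight"].mean()) if n_edges else 1.0
    new = _sample_new_pairs(rng, count, left_pool, right_pool, existing, undirected)
    add = pd.DataFrame(
        {
            "node_a": [a for a, _ in new],
            "node_b": [b for _, b in new],
            "weight": mean_w,
        }
    )
    return EdgeTable(pd.concat([df, add], ignore_index=True))


def _perturb_graph(
    graph: WeightedGraph, fraction: float, rng: np.random.Generator
) -> WeightedGraph:
    """Remove/add undirected edges on a built layer graph."""
    upper = sp.triu(graph.adjacency, k=1).tocoo()
    n_edges = upper.nnz
    count = round(abs(fraction) * n_edges)
    if count == 0:
        return graph
    rows, cols, data = upper.row, upper.col, upper.data
    if fraction < 0:
        keep = np.ones(n_edges, dtype=bool)
        keep[rng.choice(n_edges, size=count, replace=False)] = False
        rows, cols, data = rows[keep], cols[keep], data[keep]
    else:
        n = graph.n_nodes
        total = n * (n - 1) // 2
        if total - n_edges < count:
            raise PerturbationError("graph too dense to add that many edges")
        existing = set(zip(rows.tolist(), cols.tolist()))
        mean_w = float(data.mean()) if n_edges else 1.0
        new: set[tuple[int, int]] = set()
        while len(new) < count:
            i = int(rng.integers(n))
            j = int(rng.integers(n))
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in existing or key in new:
                continue
            new.add(key)
        new_list = sorted(new)
        rows = np.concatenate([rows, [i for i, _ in new_list]])
        cols = np.concatenate([cols, [j for _, j in new_list]])
        data = np.concatenate([data, np.full(count, mean_w)])
    half = sp.csr_matrix(
        (data, (rows, cols)), shape=graph.adjacency.shape, dtype=float
    )
    return WeightedGraph(list(graph.node_ids), half + half.T, role=graph.role)


def perturb_edges(
    bundle: InputBundle,
    spec: PerturbationSpec,
    rng: np.random.Generator,
    disease_graph: WeightedGraph | None = None,
) -> tuple[InputBundle, WeightedGraph | None]:
    """Apply one perturbation.

    Returns ``(bundle', disease_graph')``: for the disease-disease type the
    bundle is unchanged and the perturbed built layer is returned (install
    it with :meth:`DiseaseComplexModel.set_disease_graph`); for the other
    types the corresponding bundle table is replaced and the layer override
    is None.  ``fraction=0`` returns the inputs unchanged.
    """
    if spec.fraction == 0:
        return bundle, disease_graph
    if spec.edge_type == "disease-disease":
        if disease_graph is None:
            raise ParameterError(
                "disease-disease perturbation needs the built disease layer"
            )
        return bundle, _perturb_graph(disease_graph, spec.fraction, rng)
    protein_pool = sorted(
        set(bundle.ppi.node_ids())
        | {p for _, p in bundle.disease_protein.pairs()}
        | {p for _, p in bundle.membership.pairs()}
    )
    if spec.edge_type == "protein-protein":
        new = _perturb_edge_table(
            bundle.ppi, spec.fraction, rng, protein_pool, protein_pool, True
        )
        return replace(bundle, ppi=new), None
    if spec.edge_type == "disease-protein":
        new = _perturb_edge_table(
            bundle.disease_protein,
            spec.fraction,
            rng,
            list(bundle.similarity.disease_ids),
            protein_pool,
            False,
        )
        return replace(bundle, disease_protein=new), None
    complex_pool = sorted({c for c, _ in bundle.membership.pairs()})
    new = _perturb_edge_table(
        bundle.membership, spec.fraction, rng, complex_pool, protein_pool, False
    )
    return replace(bundle, membership=new), None


def robustness_experiment(
    bundle: InputBundle,
    edge_types,
    fractions,
    seed: int,
    repeats: int = 5,
    one_run_per_complex: bool = True,
    **model_kwargs,
) -> pd.DataFrame:
    """LOOCV criteria on perturbed inputs, averaged over seeded repeats.

    One row per (edge_type, fraction) with PRE, MR, MRR and AUC averaged
    over ``repeats`` independently seeded perturbations.  The per-repeat
    random stream depends only on (master seed, edge type, fraction,
    repeat index), so the first repeat is identical whatever ``repeats``
    is, and a zero fraction reproduces the unperturbed baseline exactly.
    """
    from .evaluation import derive_test_cases

    base_model = DiseaseComplexModel(bundle, **model_kwargs)
    base_dgraph = base_model.disease_graph
    # ground truth is fixed: perturbation changes the network, never the
    # validation cases derived from the curated associations
    base_cases = derive_test_cases(
        bundle.disease_protein,
        bundle.membership,
        one_run_per_complex=one_run_per_complex,
    )
    rows = []
    edge_types = list(edge_types)
    fractions = list(fractions)
    for ti, edge_type in enumerate(edge_types):
        for fi, fraction in enumerate(fractions):
            metrics = []
            # the zero-fraction perturbation is the identity, so one run
            # reproduces the unperturbed baseline bit-exactly
            n_reps = 1 if fraction == 0 else repeats
            for rep in range(n_reps):
                child = np.random.SeedSequence(
                    seed, spawn_key=(ti, fi, rep)
                )
                rng = np.random.default_rng(child)
                spec = PerturbationSpec(edge_type, fraction, seed, repeats)
                b2, dg2 = perturb_edges(bundle, spec, rng, base_dgraph)
                model = DiseaseComplexModel(b2, **model_kwargs)
                if dg2 is not None:
                    model.set_disease_graph(dg2)
                report = compute_metrics(run_loocv(model, cases=base_cases))
                metrics.append(report.as_row())
            avg = pd.DataFrame(metrics).mean(numeric_only=True)
            rows.append(
                {
                    "edge_type": edge_type,
                    "fraction": fraction,
                    "PRE": float(avg["PRE"]),
                    "MR": float(avg["MR"]),
                    "MRR": float(avg["MRR"]),
                    "AUC": float(avg["AUC"]),
                    "repeats": repeats,
                }
            )
    return pd.DataFrame(rows)
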
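"""Readers and writers for the tabular inputs and outputs.

Every table is tab-separated with one header line; comment lines start with
``#``.  Identifiers are opaque strings throughout: no gene/protein symbol
mapping is attempted here, so any accession translation (e.g. between an
expression atlas and a PPI database) must happen upstream.

The six inputs of a full analysis are

* a disease phenotype similarity profile (square matrix, entries in [0, 1]),
* a generic protein-protein interaction network (edge list),
* per-tissue expression calls (tissue x gene matrix, 0/1 or scores),
* disease-tissue association scores (disease x tissue matrix),
* disease-protein association pairs (edge list), and
* complex membership pairs (complex id, protein id).

:class:`InputBundle` groups the six tables and round-trips them through a
directory of TSV files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: tolerance within which a similarity profile must be symmetric before the
#: averaging fallback kicks in
SYMMETRY_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class SimilarityProfile:
    """Symmetric disease-by-disease phenotype similarity matrix in [0, 1].

    The diagonal is carried but never used by the layer builders (a disease
    is not its own neighbour).
    """

    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        l = len(self.disease_ids)
        if self.values.shape != (l, l):
            raise FormatError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{l} disease ids"
            )
        if len(set(self.disease_ids)) != l:
            raise ValidationError("duplicate disease ids in similarity profile")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def similarity(self, a: str, b: str) -> float:
        i = self.disease_ids.index(a)
        j = self.disease_ids.index(b)
        return float(self.values[i, j])


@dataclass
class EdgeTable:
    """Undirected edge records ``(node_a, node_b, weight)``.

    Self-loops are dropped at load time and duplicate undirected pairs are
    collapsed to the maximum weight, so a validated table contains each
    unordered pair at most once.
    """

    records: pd.DataFrame  # columns: node_a, node_b, weight

    def __post_init__(self) -> None:
        expected = ["node_a", "node_b", "weight"]
        if list(self.records.columns) != expected:
            raise FormatError(f"edge table columns must be {expected}")

    @property
    def n_edges(self) -> int:
        return len(self.records)

    def node_ids(self) -> list[str]:
        nodes = set(self.records["node_a"]) | set(self.records["node_b"])
        return sorted(nodes)

    def pairs(self) -> list[tuple[str, str]]:
        return list(
            zip(self.records["node_a"].tolist(), self.records["node_b"].tolist())
        )


@dataclass
class TissueTable:
    """Expression calls, one row per tissue, one column per gene."""

    tissue_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (n_tissues, n_genes), nonnegative scores or 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tissue_ids), len(self.gene_ids)):
            raise FormatError("expression matrix shape does not match ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in expression table")
        if np.any(self.values < 0):
            raise ValidationError("expression scores must be nonnegative")

    def expressed_genes(self, tissue_id: str, cutoff: float = 0.5) -> set[str]:
        """Genes whose call/score in *tissue_id* is >= *cutoff*."""
        if tissue_id not in self.tissue_ids:
            raise ValidationError(f"unknown tissue id {tissue_id!r}")
        row = self.values[self.tissue_ids.index(tissue_id)]
        return {g for g, v in zip(self.gene_ids, row) if v >= cutoff}


@dataclass
class DiseaseTissueScores:
    """Disease-by-tissue association strengths (nonnegative)."""

    disease_ids: list[str]
    tissue_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.disease_ids), len(self.tissue_ids)):
            raise FormatError("disease-tissue matrix shape does not match ids")
        if np.any(self.scores < 0):
            raise ValidationError("disease-tissue scores must be nonnegative")
        finite = np.isfinite(self.scores)
        if not finite.any(axis=1).all():
            bad = [
                d for d, ok in zip(self.disease_ids, finite.any(axis=1)) if not ok
            ]
            raise ValidationError(
                f"diseases with no finite tissue score: {bad[:5]}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_similarity_profile(path, id_header: bool = True) -> SimilarityProfile:
    """Load a phenotype similarity profile from a matrix TSV.

    With ``id_header=True`` (default) the first row and the first column hold
    disease identifiers; otherwise the body is a bare numeric matrix and ids
    ``D0001..`` are synthesized.  Asymmetric input (beyond 1e-9) is
    symmetrized by averaging with a logged warning; entries outside [0, 1]
    raise :class:`ValidationError` naming the offending cell.
    """
    if id_header:
        df = _read_matrix_tsv(path)
        ids = list(df.index)
        if list(df.columns) != ids:
            raise FormatError(
                f"{path}: row and column disease ids differ or body is not square"
            )
        values = df.to_numpy(dtype=float)
    else:
        body = pd.read_csv(path, sep="\t", comment="#", header=None)
        values = body.to_numpy(dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise FormatError(f"{path}: similarity body is not square")
        ids = [f"D{i + 1:04d}" for i in range(values.shape[0])]
    if values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: similarity body is not square")
    bad = np.argwhere((values < 0) | (values > 1) | ~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: similarity({ids[i]}, {ids[j]}) = {values[i, j]} "
            "outside [0, 1]"
        )
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > SYMMETRY_TOL:
        logger.warning(
            "%s: similarity matrix asymmetric (max |s_ij - s_ji| = %.3g); "
            "symmetrized by averaging",
            path,
            asym,
        )
        values = (values + values.T) / 2.0
    return SimilarityProfile(ids, values)


def read_edge_table(path, weighted: bool | None = None) -> EdgeTable:
    """Load an undirected edge list (2 or 3 tab-separated columns).

    Two-column input gets unit weights.  ``weighted=False`` forces unit
    weights even when a third column is present.  Self-loops are dropped
    (count logged) and duplicate undirected pairs collapse to the maximum
    weight with a warning; the surviving record keeps its first-seen
    orientation.  Negative weights raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] == 2:
        df.columns = ["node_a", "node_b"]
        df["weight"] = 1.0
    elif df.shape[1] == 3:
        df.columns = ["node_a", "node_b", "weight"]
        df["weight"] = df["weight"].astype(float)
    else:
        raise FormatError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    if weighted is False:
        df["weight"] = 1.0
    if np.any(df["weight"].to_numpy() < 0):
        raise ValidationError(f"{path}: negative edge weight")
    return _normalize_edge_records(df, origin=str(path))


def _normalize_edge_records(df: pd.DataFrame, origin: str = "") -> EdgeTable:
    df = df[["node_a", "node_b", "weight"]].copy()
    df["node_a"] = df["node_a"].astype(str)
    df["node_b"] = df["node_b"].astype(str)
    loops = df["node_a"] == df["node_b"]
    if loops.any():
        logger.info("%s: dropped %d self-loop rows", origin, int(loops.sum()))
        df = df[~loops]
    lo = np.minimum(df["node_a"], df["node_b"])
    hi = np.maximum(df["node_a"], df["node_b"])
    df = df.assign(_lo=lo, _hi=hi)
    n_dup = int(df.duplicated(["_lo", "_hi"]).sum())
    if n_dup:
        logger.warning(
            "%s: collapsed %d duplicate undirected pairs (kept max weight)",
            origin,
            n_dup,
        )
    grouped = df.groupby(["_lo", "_hi"], sort=True)
    out = grouped.agg(
        node_a=("node_a", "first"),
        node_b=("node_b", "first"),
        weight=("weight", "max"),
    ).reset_index(drop=True)
    return EdgeTable(out)


def edge_table_from_pairs(
    pairs, weights=None, weight: float = 1.0
) -> EdgeTable:
    """Build a validated :class:`EdgeTable` from in-memory pairs."""
    pairs = list(pairs)
    if weights is None:
        weights = [weight] * len(pairs)
    df = pd.DataFrame(
        {
            "node_a": [str(a) for a, _ in pairs],
            "node_b": [str(b) for _, b in pairs],
            "weight": [float(w) for w in weights],
        }
    )
    if np.any(df["weight"].to_numpy() < 0):
        raise ValidationError("negative edge weight")
    return _normalize_edge_records(df, origin="<memory>")


def read_tissue_table(path) -> TissueTable:
    """Load expression calls: rows are tissues, columns are genes."""
    df = _read_matrix_tsv(path)
    return TissueTable(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def read_disease_tissue_scores(path) -> DiseaseTissueScores:
    """Load disease-tissue association scores: rows diseases, columns tissues."""
    df = _read_matrix_tsv(path)
    return DiseaseTissueScores(
        list(df.index), list(df.columns), df.to_numpy(dtype=float)
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_matrix_tsv(path, index, columns, values) -> None:
    pd.DataFrame(values, index=list(index), columns=list(columns)).to_csv(
        path, sep="\t"
    )


def write_similarity_profile(path, profile: SimilarityProfile) -> None:
    _write_matrix_tsv(path, profile.disease_ids, profile.disease_ids, profile.values)


def write_edge_table(path, table: EdgeTable) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def write_tissue_table(path, table: TissueTable) -> None:
    _write_matrix_tsv(path, table.tissue_ids, table.gene_ids, table.values)


def write_disease_tissue_scores(path, scores: DiseaseTissueScores) -> None:
    _write_matrix_tsv(path, scores.disease_ids, scores.tissue_ids, scores.scores)


def write_ranking(path, query_disease: str, ranking: pd.DataFrame) -> None:
    """Write a ranking list as TSV: rank, complex_id, score, tie.

    *ranking* is the frame produced by :func:`complexwalk.walk.rank`:
    display positions are 1..n in nonincreasing score order, ties broken by
    complex id, and the ``tie`` column flags score ties.  An empty frame
    yields a header-only file.
    """
    path = Path(path)
    cols = ["rank", "complex_id", "score", "tie"]
    out = ranking.copy()
    if out.empty:
        out = pd.DataFrame(columns=cols)
    else:
        if "rank" not in out.columns and "position" in out.columns:
            out = out.rename(columns={"position": "rank"})
        out = out[cols]
    with open(path, "w") as fh:
        fh.write(f"# query\t{query_disease}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_ranking(path) -> tuple[str, pd.DataFrame]:
    """Inverse of :func:`write_ranking`; returns (query, frame)."""
    query = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# query\t"):
            query = first.rstrip("\n").split("\t", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    if not df.empty:
        df["complex_id"] = df["complex_id"].astype(str)
        df["tie"] = df["tie"].astype(bool)
    return query, df


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "similarity": "similarity.tsv",
    "ppi": "ppi.tsv",
    "expression": "expression.tsv",
    "disease_tissue": "disease_tissue.tsv",
    "disease_protein": "disease_protein.tsv",
    "membership": "membership.tsv",
}


@dataclass
class InputBundle:
    """The six tables a full prioritization run consumes."""

    similarity: SimilarityProfile
    ppi: EdgeTable
    expression: TissueTable
    disease_tissue: DiseaseTissueScores
    disease_protein: EdgeTable
    membership: EdgeTable  # node_a = complex id, node_b = protein id

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_similarity_profile(directory / _BUNDLE_FILES["similarity"], self.similarity)
        write_edge_table(directory / _BUNDLE_FILES["ppi"], self.ppi)
        write_tissue_table(directory / _BUNDLE_FILES["expression"], self.expression)
        write_disease_tissue_scores(
            directory / _BUNDLE_FILES["disease_tissue"], self.disease_tissue
        )
        write_edge_table(
            directory / _BUNDLE_FILES["disease_protein"], self.disease_protein
        )
        write_edge_table(directory / _BUNDLE_FILES["membership"], self.membership)

    @classmethod
    def load(cls, directory) -> "InputBundle":
        directory = Path(directory)
        return cls(
            similarity=read_similarity_profile(directory / _BUNDLE_FILES["similarity"]),
            ppi=read_edge_table(directory / _BUNDLE_FILES["ppi"]),
            expression=read_tissue_table(directory / _BUNDLE_FILES["expression"]),
            disease_tissue=read_disease_tissue_scores(
                directory / _BUNDLE_FILES["disease_tissue"]
            ),
            disease_protein=read_edge_table(
                directory / _BUNDLE_FILES["disease_protein"]
            ),
            membership=read_edge_table(directory / _BUNDLE_FILES["membership"]),
        )

    def complex_members(self) -> dict[str, list[str]]:
        """Map complex id -> sorted member protein ids."""
        out: dict[str, list[str]] = {}
        for c, p in self.membership.pairs():
            out.setdefault(c, []).append(p)
        return {c: sorted(ps) for c, ps in sorted(out.items())}
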
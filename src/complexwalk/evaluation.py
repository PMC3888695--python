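"""Leave-one-out cross-validation and the rank-based evaluation criteria.

A complex counts as associated with a disease when at least one member
protein is annotated to that disease.  Each validation run takes one
associated (complex, disease) pair, removes every disease-protein edge of
the query disease, reruns the prioritization, and records the rank of the
test complex among all candidates.  Reported criteria:

* TOP / PRE — count and fraction of runs whose test complex ranks first;
* MR / MRR — mean rank and mean relative rank (rank / list length);
* rank-ROC / AUC — sensitivity is the fraction of test complexes whose
  relative rank is at or below a threshold, specificity the fraction of
  control complexes above it; the threshold sweeps 0 to 1 and the area is
  integrated by the trapezoid rule over every observed breakpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ScoringError, ValidationError
from .io import EdgeTable
from .model import DiseaseComplexModel

logger = logging.getLogger(__name__)

TOP_THRESHOLDS = (1, 5, 10, 20)


@dataclass
class ValidationRun:
    """Outcome of one leave-one-out run."""

    test_complex_id: str
    query_disease_id: str
    masked_pairs: tuple[tuple[str, str], ...]
    rank: float
    list_length: int
    flagged: bool = False
    control_relative_ranks: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.list_length:
            raise ValidationError(
                f"rank {self.rank} outside [1, {self.list_length}]"
            )

    @property
    def relative_rank(self) -> float:
        return self.rank / self.list_length


@dataclass
class EvaluationReport:
    """Aggregate criteria over N validation runs."""

    N: int
    top_counts: dict[int, int]
    PRE: float
    MR: float
    MRR: float
    roc_points: np.ndarray  # (k, 2): (1 - specificity, sensitivity)
    AUC: float
    runs: list[ValidationRun] = field(default_factory=list, repr=False)

    def as_row(self) -> dict:
        row = {"N": self.N, "PRE": self.PRE, "MR": self.MR, "MRR": self.MRR,
               "AUC": self.AUC}
        for t, c in self.top_counts.items():
            row[f"TOP{t}"] = c
        return row

    def summary(self) -> str:
        lines = [
            "Leave-one-out cross-validation",
            "=" * 40,
            f"runs (N)           : {self.N}",
        ]
        for t, c in sorted(self.top_counts.items()):
            lines.append(
                f"ranked in top {t:<4d} : {c}  ({100.0 * c / self.N:.2f}%)"
            )
        lines += [
            f"precision (PRE)    : {100.0 * self.PRE:.2f}%",
            f"mean rank (MR)     : {self.MR:.2f}",
            f"mean relative rank : {100.0 * self.MRR:.2f}%",
            f"rank-ROC AUC       : {100.0 * self.AUC:.2f}%",
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the rank-ROC curve (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_points[:, 0], self.roc_points[:, 1], "-")
        ax.plot([0, 1], [0, 1], ":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"rank-ROC (AUC = {100.0 * self.AUC:.2f}%)")
        return ax


# ---------------------------------------------------------------------------
# test-case derivation and single runs
# ---------------------------------------------------------------------------


def derive_test_cases(
    disease_protein: EdgeTable,
    membership: EdgeTable,
    one_run_per_complex: bool = True,
) -> list[tuple[str, str]]:
    """Associated (complex, query disease) pairs for validation.

    A complex is associated with a disease iff at least one member protein
    is annotated to it.  With ``one_run_per_complex`` (default) each test
    complex contributes a single run whose query is its lexicographically
    smallest associated disease; otherwise every associated pair becomes a
    run.
    """
    by_protein: dict[str, set[str]] = {}
    for d, p in disease_protein.pairs():
        by_protein.setdefault(p, set()).add(d)
    assoc: dict[str, set[str]] = {}
    for c, p in membership.pairs():
        for d in by_protein.get(p, ()):
            assoc.setdefault(c, set()).add(d)
    cases = []
    for c in sorted(assoc):
        diseases = sorted(assoc[c])
        if one_run_per_complex:
            cases.append((c, diseases[0]))
        else:
            cases.extend((c, d) for d in diseases)
    return cases


def loocv_run(
    case: tuple[str, str], model: DiseaseComplexModel, method: str = "rwr"
) -> ValidationRun:
    """One leave-one-out run: mask the query's associations, re-rank.

    If masking disconnects the query from the complex layer the run is kept
    with the test complex at the worst rank (flagged) and every control at
    the tied mid-rank — conservative, and N stays fixed.
    """
    complex_id, query = case
    masked = tuple(
        (a, b)
        for a, b in model.bundle.disease_protein.pairs()
        if a == query or b == query
    )
    n = len(model.complex_ids)
    try:
        res = model.fit(query, method=method, mask_query_associations=True)
        ranking = res.ranking.set_index("complex_id")["midrank"]
        rank_val = float(ranking[complex_id])
        controls = ranking.drop(complex_id).to_numpy() / n
        flagged = False
    except ScoringError:
        rank_val = float(n)
        controls = np.full(n - 1, (n + 1) / 2.0 / n)
        flagged = True
        logger.warning(
            "query %s disconnected after masking; test complex %s gets "
            "worst rank",
            query,
            complex_id,
        )
    return ValidationRun(
        test_complex_id=complex_id,
        query_disease_id=query,
        masked_pairs=masked,
        rank=rank_val,
        list_length=n,
        flagged=flagged,
        control_relative_ranks=controls,
    )


def run_loocv(
    model: DiseaseComplexModel,
    one_run_per_complex: bool = True,
    cases: list[tuple[str, str]] | None = None,
    method: str = "rwr",
) -> list[ValidationRun]:
    """Full leave-one-out sweep over all derived test cases.

    *cases* may be supplied explicitly — e.g. the test set of the
    unperturbed inputs when evaluating a perturbed network, so that edge
    noise changes the network but never the ground truth being recovered.
    """
    if cases is None:
        cases = derive_test_cases(
            model.bundle.disease_protein,
            model.bundle.membership,
            one_run_per_complex=one_run_per_complex,
        )
    cases = [(c, d) for c, d in cases if c in set(model.complex_ids)]
    return [loocv_run(case, model, method=method) for case in cases]


def shuffle_disease_labels(
    disease_protein: EdgeTable, rng: np.random.Generator
) -> EdgeTable:
    """Permute the disease column of the association pairs.

    Annotation counts per protein and per disease-slot are preserved while
    any alignment between phenotype neighbourhoods and complex membership
    is destroyed — the permutation null for the cross-validation.
    """
    recs = disease_protein.records.copy()
    perm = rng.permutation(len(recs))
    recs["node_a"] = recs["node_a"].to_numpy()[perm]
    from .io import _normalize_edge_records

    return _normalize_edge_records(recs, origin="<shuffled>")


def label_shuffled_loocv(
    model: DiseaseComplexModel,
    rng: np.random.Generator,
    one_run_per_complex: bool = True,
) -> list[ValidationRun]:
    """LOOCV under the label-shuffling null.

    Test cases are derived from the TRUE disease-protein pairs, but the
    network is built with the disease labels of those pairs permuted, so a
    truly associated complex is exchangeable with its controls and the
    expected AUC is 0.5.
    """
    from dataclasses import replace as _replace

    cases = derive_test_cases(
        model.bundle.disease_protein,
        model.bundle.membership,
        one_run_per_complex=one_run_per_complex,
    )
    shuffled = shuffle_disease_labels(model.bundle.disease_protein, rng)
    null_bundle = _replace(model.bundle, disease_protein=shuffled)
    null_model = DiseaseComplexModel(null_bundle, **model.params())
    cases = [(c, d) for c, d in cases if c in set(null_model.complex_ids)]
    return [loocv_run(case, null_model) for case in cases]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def rank_roc(
    test_relative_ranks, control_relative_ranks
) -> tuple[np.ndarray, float]:
    """Rank-ROC points and trapezoidal AUC.

    For each threshold theta (every distinct observed relative rank plus
    the endpoints 0 and 1), sensitivity is the fraction of test relative
    ranks <= theta and specificity the fraction of control relative ranks
    > theta.  Points are ((1 - specificity), sensitivity); the area is
    integrated with the trapezoid rule.
    """
    tests = np.asarray(list(test_relative_ranks), dtype=float)
    controls = np.asarray(list(control_relative_ranks), dtype=float)
    if tests.size == 0:
        raise ValidationError("empty test rank list")
    if controls.size == 0:
        raise ValidationError("empty control rank list")
    thresholds = np.unique(np.concatenate([[0.0, 1.0], tests, controls]))
    sens = np.array([(tests <= t).mean() for t in thresholds])
    fpr = np.array([(controls <= t).mean() for t in thresholds])
    points = np.column_stack([fpr, sens])
    auc = float(np.trapezoid(sens, fpr))
    return points, auc


def compute_metrics(
    runs: list[ValidationRun], top_thresholds=TOP_THRESHOLDS
) -> EvaluationReport:
    """TOP/PRE, MR/MRR and rank-ROC AUC from a list of validation runs."""
    if not runs:
        raise ValidationError("need at least one validation run")
    ranks = np.array([r.rank for r in runs], dtype=float)
    rel = np.array([r.relative_rank for r in runs], dtype=float)
    top_counts = {int(t): int((ranks <= t).sum()) for t in top_thresholds}
    controls = [
        r.control_relative_ranks for r in runs if r.control_relative_ranks.size
    ]
    if controls:
        roc_points, auc = rank_roc(rel, np.concatenate(controls))
    else:
        roc_points, auc = np.empty((0, 2)), float("nan")
    return EvaluationReport(
        N=len(runs),
        top_counts=top_counts,
        PRE=top_counts.get(1, int((ranks <= 1).sum())) / len(runs),
        MR=float(ranks.mean()),
        MRR=float(rel.mean()),
        roc_points=roc_points,
        AUC=auc,
        runs=list(runs),
    )


def random_guess_expectation(N: int, n: int, t: int) -> tuple[float, float]:
    """Expected (count, fraction) of runs ranked in the top *t* when ranks
    are assigned uniformly at random over *n* candidates."""
    if not 1 <= t <= n:
        raise ValidationError("threshold t must lie in [1, n]")
    if N < 1:
        raise ValidationError("N must be >= 1")
    return N * t / n, t / n


def compare_methods(
    runs_by_method: dict[str, list[ValidationRun]],
) -> pd.DataFrame:
    """Side-by-side criteria table; all methods must share the test cases."""
    case_sets = {
        name: sorted((r.test_complex_id, r.query_disease_id) for r in runs)
        for name, runs in runs_by_method.items()
    }
    ref = None
    for name, cases in case_sets.items():
        if ref is None:
            ref = cases
        elif cases != ref:
            raise ValidationError(
                f"method {name!r} was evaluated on a different test-case set"
            )
    rows = {
        name: compute_metrics(runs).as_row()
        for name, runs in runs_by_method.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")
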
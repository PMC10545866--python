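"""Cross-validated ranking evaluation: AUC, AUPR, precision, top-n.

Known associations (positive cells of the binary matrix) are split into
ten near-equal folds; each fold in turn is removed from the training
matrix *before* WKNN densification (so held-out positives cannot leak
through the neighbour profiles), the pipeline scores every pair, and the
held-out positives are ranked against all pairs that were never known
during training.  Negatives are never sampled down.

AUC uses the Mann-Whitney midrank formulation; AUPR is the step
integration of the precision-recall curve (average precision);
"precision" is R-precision: the fraction of true positives among the
top-N ranked candidates with N equal to the number of held-out
positives (cutoff configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .pipeline import predict
from .preprocessing import AssociationMatrix, SimilarityMatrix
from .solver import SolverConfig

__all__ = [
    "FoldPlan",
    "MetricReport",
    "make_folds",
    "rank_metrics",
    "cross_validate",
    "grid_search",
    "topn_validated",
]

Cell = tuple[int, int]


@dataclass(frozen=True)
class FoldPlan:
    """A partition of the positive cells into folds for one repeat."""

    folds: tuple[tuple[Cell, ...], ...]
    repeat: int
    seed: int

    def all_positives(self) -> set[Cell]:
        return {c for fold in self.folds for c in fold}


@dataclass
class MetricReport:
    """Per-fold metrics plus their means."""

    per_fold: list[dict[str, float]] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean([f[metric] for f in self.per_fold]))

    @property
    def auc(self) -> float:
        return self.mean("auc")

    @property
    def aupr(self) -> float:
        return self.mean("aupr")

    @property
    def precision(self) -> float:
        return self.mean("precision")

    def summary(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "precision": self.precision,
            "n_folds": len(self.per_fold),
        }


def make_folds(
    a: AssociationMatrix,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[FoldPlan]:
    """Seeded random partitions of the positive cells into near-equal folds."""
    if not a.binary_flag:
        raise ValueError("fold construction requires a binary association matrix")
    positives = [tuple(c) for c in np.argwhere(a.values == 1)]
    if len(positives) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positives to build {n_folds} folds, "
            f"got {len(positives)}"
        )
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(n_repeats):
        perm = rng.permutation(len(positives))
        chunks = np.array_split(perm, n_folds)
        folds = tuple(
            tuple(positives[i] for i in chunk) for chunk in chunks
        )
        plans.append(FoldPlan(folds=folds, repeat=rep, seed=seed))
    return plans


def _candidate_arrays(
    scores: np.ndarray, test_pos: set[Cell], train_pos: set[Cell]
) -> tuple[np.ndarray, np.ndarray]:
    n, m = scores.shape
    mask = np.ones((n, m), dtype=bool)
    for i, j in train_pos:
        mask[i, j] = False
    labels = np.zeros((n, m), dtype=bool)
    for i, j in test_pos:
        if not mask[i, j]:
            raise ValueError("test and train positives overlap")
        labels[i, j] = True
    return scores[mask], labels[mask]


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U statistic (midrank ties)."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rank_metrics(
    scores,
    test_pos: Iterable[Cell],
    train_pos: Iterable[Cell],
    precision_cutoff: int | None = None,
) -> dict[str, float]:
    """Ranking metrics for one evaluation split.

    Candidates are all cells outside ``train_pos``; held-out positives
    are labelled 1.  ``precision_cutoff`` defaults to the number of test
    positives (R-precision); top-n ties are broken by stable cell order.
    """
    score_arr = scores.scores if hasattr(scores, "scores") else np.asarray(scores)
    test_pos = set(map(tuple, test_pos))
    train_pos = set(map(tuple, train_pos))
    if not test_pos:
        raise ValueError("empty test-positive set")
    s, y = _candidate_arrays(score_arr, test_pos, train_pos)
    auc = mann_whitney_auc(s, y)
    aupr = float(average_precision_score(y, s))
    cutoff = precision_cutoff if precision_cutoff is not None else int(y.sum())
    order = np.argsort(-s, kind="stable")
    precision = float(y[order[:cutoff]].mean())
    return {"auc": auc, "aupr": aupr, "precision": precision}


def _per_drug_metrics(
    score_arr: np.ndarray, test_pos: set[Cell], train_pos: set[Cell]
) -> dict[str, float]:
    """Metrics averaged over drugs that hold at least one test positive."""
    per = []
    drugs = sorted({j for _, j in test_pos})
    for j in drugs:
        col_test = {(i, jj) for i, jj in test_pos if jj == j}
        col_train = {(i, jj) for i, jj in train_pos if jj == j}
        s, y = _candidate_arrays(
            score_arr[:, [j]],
            {(i, 0) for i, _ in col_test},
            {(i, 0) for i, _ in col_train},
        )
        if y.all() or not y.any():
            continue
        per.append(
            {
                "auc": mann_whitney_auc(s, y),
                "aupr": float(average_precision_score(y, s)),
                "precision": float(
                    y[np.argsort(-s, kind="stable")[: int(y.sum())]].mean()
                ),
            }
        )
    if not per:
        raise ValueError("no drug had both test positives and negatives")
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def cross_validate(
    a: AssociationMatrix,
    drug_sims: list[SimilarityMatrix],
    disease_sims: list[SimilarityMatrix],
    folds: Sequence[FoldPlan],
    k: int = 30,
    alpha: float = 0.95,
    solver_config: SolverConfig | None = None,
    mode: str = "full",
    ranking: str = "pooled",
    progress: bool = False,
) -> MetricReport:
    """Run the pipeline once per fold with held-out positives zeroed.

    Test positives are removed from the training matrix before WKNN so
    they cannot leak through densification.  ``ranking`` is ``pooled``
    (one ranking over all candidate cells) or ``per_drug`` (metrics per
    drug column, averaged).
    """
    if ranking not in ("pooled", "per_drug"):
        raise ValueError("ranking must be 'pooled' or 'per_drug'")
    report = MetricReport()
    for plan in folds:
        for fold_idx, fold in enumerate(plan.folds):
            train = a.values.copy()
            for i, j in fold:
                train[i, j] = 0.0
            a_train = AssociationMatrix(train, a.disease_ids, a.drug_ids)
            pred = predict(
                a_train,
                drug_sims,
                disease_sims,
                k=k,
                alpha=alpha,
                solver_config=solver_config,
                mode=mode,
            )
            train_pos = {tuple(c) for c in np.argwhere(train == 1)}
            if ranking == "pooled":
                metrics = rank_metrics(pred, set(fold), train_pos)
            else:
                metrics = _per_drug_metrics(pred.scores, set(fold), train_pos)
            metrics["repeat"] = plan.repeat
            metrics["fold"] = fold_idx
            report.per_fold.append(metrics)
            if progress:
                print(
                    f"repeat {plan.repeat} fold {fold_idx}: "
                    f"auc={metrics['auc']:.3f} aupr={metrics['aupr']:.3f}"
                )
    return report


def grid_search(
    a: AssociationMatrix,
    drug_sims: list[SimilarityMatrix],
    disease_sims: list[SimilarityMatrix],
    folds: Sequence[FoldPlan],
    k_grid: Sequence[int] = (10, 20, 30, 40, 50),
    p_grid: Sequence[float] = (0.6, 0.7, 0.8, 0.9, 1.0),
    alpha: float = 0.95,
    solver_config: SolverConfig | None = None,
    **cv_kwargs,
) -> tuple[list[dict[str, float]], dict[str, float]]:
    """Evaluate every ``(k, p)`` cell; select the max of AUC + AUPR.

    Returns the full table (one row per cell with auc, aupr and their
    sum) and the argmax row.
    """
    if not k_grid or not p_grid:
        raise ValueError("grids must be non-empty")
    base = solver_config or SolverConfig()
    table = []
    for k in k_grid:
        for p in p_grid:
            rep = cross_validate(
                a,
                drug_sims,
                disease_sims,
                folds,
                k=k,
                alpha=alpha,
                solver_config=base.with_(p=p),
                **cv_kwargs,
            )
            table.append(
                {
                    "k": k,
                    "p": p,
                    "auc": rep.auc,
                    "aupr": rep.aupr,
                    "precision": rep.precision,
                    "auc_plus_aupr": rep.auc + rep.aupr,
                }
            )
    best = max(table, key=lambda row: row["auc_plus_aupr"])
    return table, best


def topn_validated(
    scores,
    train_pos: Iterable[Cell],
    reference_pos: Iterable[Cell],
    n_values: Sequence[int] = (5, 10, 15, 20, 25, 30),
) -> dict[int, int]:
    """Count externally validated pairs within each drug's top-n candidates.

    For each drug, its non-training diseases are ranked by score
    (descending, stable ties); hits against ``reference_pos`` within the
    top n are summed over drugs.  ``reference_pos`` must not contain
    training positives.
    """
    score_arr = scores.scores if hasattr(scores, "scores") else np.asarray(scores)
    train_pos = set(map(tuple, train_pos))
    reference_pos = set(map(tuple, reference_pos))
    overlap = train_pos & reference_pos
    if overlap:
        raise ValueError(f"reference set contains training positives: {overlap}")
    n_dis, n_drugs = score_arr.shape
    counts = {n: 0 for n in n_values}
    for j in range(n_drugs):
        candidates = [i for i in range(n_dis) if (i, j) not in train_pos]
        order = sorted(candidates, key=lambda i: (-score_arr[i, j], i))
        for n in n_values:
            counts[n] += sum(1 for i in order[:n] if (i, j) in reference_pos)
    return counts
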
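"""Tensor construction and the end-to-end prediction pipeline.

Two third-order tensors are decomposed:

* the drug tensor, shape ``(m+n, m, 5)``: frontal slice ``i`` stacks the
  ``i``-th drug-drug similarity matrix on top of the densified
  association matrix;
* the disease tensor, shape ``(n, m+n, 2)``: frontal slice ``i`` places
  the densified association matrix left of the ``i``-th disease-disease
  similarity matrix.

Each tensor is split into a low-rank part and a sparse residual by the
box-constrained solver; the association block of the low-rank part,
averaged over frontal slices, is one side's prediction matrix, and the
final score matrix is the plain mean of the drug-side and disease-side
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import (
    AssociationMatrix,
    SimilarityMatrix,
    wknn_preprocess,
)
from .solver import SolverConfig, SolverResult, solve

__all__ = [
    "PredictionMatrix",
    "build_drug_tensor",
    "build_disease_tensor",
    "extract_prediction",
    "combine_predictions",
    "predict",
    "MODES",
]

MODES = ("full", "no_wknn", "only_wknn", "drug_only", "disease_only")


@dataclass(frozen=True)
class PredictionMatrix:
    """Real-valued score matrix over all drug-disease pairs.

    ``scores`` is ``n x m`` in [0, 1]; ``provenance`` records which
    pipeline mode produced it.
    """

    scores: np.ndarray
    disease_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]
    provenance: str = "full"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        if s.shape != (len(self.disease_ids), len(self.drug_ids)):
            raise ValueError("score shape does not match identifiers")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        if s.min() < -1e-9 or s.max() > 1 + 1e-9:
            raise ValueError("scores must lie in [0, 1]")


def _check_sims(
    sims: list[SimilarityMatrix], ids: tuple[str, ...], expected: int, what: str
) -> None:
    if len(sims) != expected:
        raise ValueError(f"expected {expected} {what} similarity matrices, "
                         f"got {len(sims)}")
    for s in sims:
        if s.ids != ids:
            raise ValueError(f"{what} similarity identifiers do not match the "
                             "association matrix")


def build_drug_tensor(
    sims: list[SimilarityMatrix], a_dr: AssociationMatrix
) -> np.ndarray:
    """Stack ``[similarity; association]`` per slice -> ``(m+n, m, n_sims)``."""
    _check_sims(sims, a_dr.drug_ids, 5, "drug")
    slices = [np.vstack([s.values, a_dr.values]) for s in sims]
    return np.stack(slices, axis=2)


def build_disease_tensor(
    sims: list[SimilarityMatrix], a_dr: AssociationMatrix
) -> np.ndarray:
    """Stack ``[association, similarity]`` per slice -> ``(n, m+n, n_sims)``."""
    _check_sims(sims, a_dr.disease_ids, 2, "disease")
    slices = [np.hstack([a_dr.values, s.values]) for s in sims]
    return np.stack(slices, axis=2)


def extract_prediction(
    x_star: np.ndarray,
    side: str,
    n: int,
    m: int,
    disease_ids: tuple[str, ...],
    drug_ids: tuple[str, ...],
    provenance: str | None = None,
) -> PredictionMatrix:
    """Average the association block of a recovered tensor over slices.

    Drug side: rows ``m .. m+n-1`` of the ``(m+n, m, 5)`` tensor;
    disease side: columns ``0 .. m-1`` of the ``(n, m+n, 2)`` tensor.
    """
    if side == "drug":
        if x_star.shape[:2] != (m + n, m):
            raise ValueError(f"drug tensor has shape {x_star.shape[:2]}, "
                             f"expected {(m + n, m)}")
        block = x_star[m:, :, :]
    elif side == "disease":
        if x_star.shape[:2] != (n, m + n):
            raise ValueError(f"disease tensor has shape {x_star.shape[:2]}, "
                             f"expected {(n, m + n)}")
        block = x_star[:, :m, :]
    else:
        raise ValueError("side must be 'drug' or 'disease'")
    scores = block.mean(axis=2)
    return PredictionMatrix(
        np.clip(scores, 0.0, 1.0),
        disease_ids,
        drug_ids,
        provenance or f"{side}_only",
    )


def combine_predictions(p1: PredictionMatrix, p2: PredictionMatrix) -> PredictionMatrix:
    """Elementwise mean of the drug-side and disease-side score matrices."""
    if p1.disease_ids != p2.disease_ids or p1.drug_ids != p2.drug_ids:
        raise ValueError("prediction matrices have mismatched identifiers")
    return PredictionMatrix(
        (p1.scores + p2.scores) / 2.0, p1.disease_ids, p1.drug_ids, "full"
    )


def predict(
    a: AssociationMatrix,
    drug_sims: list[SimilarityMatrix],
    disease_sims: list[SimilarityMatrix],
    k: int = 30,
    alpha: float = 0.95,
    solver_config: SolverConfig | None = None,
    mode: str = "full",
    return_diagnostics: bool = False,
) -> PredictionMatrix | tuple[PredictionMatrix, dict[str, SolverResult]]:
    """End-to-end prediction of drug-disease association scores.

    Modes: ``full`` (WKNN -> both tensors -> solve -> average),
    ``no_wknn`` (skip densification), ``only_wknn`` (return the fused
    WKNN matrix without solving), ``drug_only`` / ``disease_only``
    (single-tensor predictions).  The same solver configuration is
    applied to both tensors; ``full`` equals the exact mean of
    ``drug_only`` and ``disease_only``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if solver_config is None:
        solver_config = SolverConfig()
    n, m = a.shape

    if mode == "no_wknn":
        a_dr = a
    else:
        a_dr = wknn_preprocess(a, drug_sims, disease_sims, k=k, alpha=alpha)
    if mode == "only_wknn":
        pred = PredictionMatrix(a_dr.values, a.disease_ids, a.drug_ids, "only_wknn")
        return (pred, {}) if return_diagnostics else pred

    diagnostics: dict[str, SolverResult] = {}
    drug_pred = disease_pred = None
    if mode in ("full", "no_wknn", "drug_only"):
        res = solve(build_drug_tensor(drug_sims, a_dr), solver_config)
        diagnostics["drug"] = res
        drug_pred = extract_prediction(
            res.X, "drug", n, m, a.disease_ids, a.drug_ids
        )
    if mode in ("full", "no_wknn", "disease_only"):
        res = solve(build_disease_tensor(disease_sims, a_dr), solver_config)
        diagnostics["disease"] = res
        disease_pred = extract_prediction(
            res.X, "disease", n, m, a.disease_ids, a.drug_ids
        )

    if mode == "drug_only":
        pred = drug_pred
    elif mode == "disease_only":
        pred = disease_pred
    else:
        pred = combine_predictions(drug_pred, disease_pred)
        if mode == "no_wknn":
            object.__setattr__(pred, "provenance", "no_wknn")
    return (pred, diagnostics) if return_diagnostics else pred
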
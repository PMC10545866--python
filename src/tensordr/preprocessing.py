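"""Association/similarity containers and WKNN densification.

The drug-disease association matrix ``A`` (diseases in rows, drugs in
columns) is extremely sparse: a novel drug or disease has an all-zero
profile and cannot be ranked.  The weighted k-nearest-neighbour (WKNN)
preprocessing fills in soft associations for every entity from the
profiles of its most similar *known* entities (those with at least one
validated association), weighted by similarity and a geometric decay,
then fuses the drug-side and disease-side estimates with the original
binary matrix by an elementwise maximum so no validated association is
ever lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "jaccard_similarity",
    "mean_similarity",
    "wknn_update",
    "fuse_associations",
    "wknn_preprocess",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-12


def _check_ids(ids) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if any(not i for i in ids):
        raise ValueError("identifiers must be non-empty strings")
    if len(set(ids)) != len(ids):
        raise ValueError("identifiers must be unique")
    return ids


@dataclass(frozen=True)
class AssociationMatrix:
    """Disease x drug association matrix with identifiers.

    ``values`` is ``n x m`` with entries in [0, 1]; ``binary_flag``
    records whether every entry is exactly 0 or 1 (true for raw
    validated associations, false after WKNN densification).
    """

    values: np.ndarray
    disease_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "disease_ids", _check_ids(self.disease_ids))
        object.__setattr__(self, "drug_ids", _check_ids(self.drug_ids))
        if v.ndim != 2:
            raise ValueError("association values must be a matrix")
        if v.shape != (len(self.disease_ids), len(self.drug_ids)):
            raise ValueError(
                f"shape {v.shape} does not match {len(self.disease_ids)} diseases "
                f"x {len(self.drug_ids)} drugs"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("association values must be finite")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("association values must lie in [0, 1]")

    @property
    def binary_flag(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric similarity matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", _check_ids(self.ids))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity values must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("similarity shape does not match identifier count")
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity values must be finite")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("similarity values must lie in [0, 1]")
        if np.max(np.abs(np.diag(v) - 1.0)) > _SYM_TOL:
            raise ValueError("similarity diagonal must be 1")

    @property
    def n(self) -> int:
        return len(self.ids)


def jaccard_similarity(profiles: np.ndarray, ids=None) -> SimilarityMatrix:
    """Jaccard similarity between the rows of a binary profile matrix.

    Entry ``(i, j)`` is ``|S_i & S_j| / |S_i | S_j|`` over the support
    sets of rows ``i`` and ``j`` (e.g. side-effect, interaction or
    target profiles); the diagonal is forced to 1 and a pair of empty
    profiles scores 0 off-diagonal.
    """
    profiles = np.asarray(profiles)
    if not np.all((profiles == 0) | (profiles == 1)):
        raise ValueError("profiles must be binary")
    profiles = profiles.astype(float)
    inter = profiles @ profiles.T
    sizes = profiles.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    if ids is None:
        ids = [f"e{i}" for i in range(profiles.shape[0])]
    return SimilarityMatrix(sim, tuple(ids))


def mean_similarity(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Elementwise arithmetic mean of similarity matrices with equal ids."""
    if not mats:
        raise ValueError("need at least one similarity matrix")
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValueError("similarity matrices have mismatched identifiers")
    mean = np.mean([m.values for m in mats], axis=0)
    return SimilarityMatrix(mean, ids)


def wknn_update(
    a: AssociationMatrix,
    s: SimilarityMatrix,
    k: int,
    alpha: float = 0.95,
    axis: str = "drugs",
) -> AssociationMatrix:
    """Similarity-weighted neighbour estimate of every association profile.

    For each query entity ``q`` (drug column or disease row), the
    ``k`` most similar *known* entities (>= 1 validated association in
    the original binary matrix, the query itself excluded) are taken in
    descending similarity order, ties broken towards the lower index,
    and the query's profile is replaced by

        (1/Q) * sum_j alpha^(j-1) * s(n_j, q) * profile(n_j),
        Q = sum_j s(n_j, q)

    over the ORIGINAL binary profiles.  Fewer than ``k`` eligible
    neighbours means all of them are used; if every neighbour
    similarity is zero the profile is set to zeros (logged).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if axis not in ("drugs", "diseases"):
        raise ValueError("axis must be 'drugs' or 'diseases'")
    # work on profiles-as-columns; for diseases transpose in and out
    if axis == "drugs":
        if s.ids != a.drug_ids:
            raise ValueError("similarity ids do not match drug ids")
        profiles = a.values  # column q = profile of drug q
    else:
        if s.ids != a.disease_ids:
            raise ValueError("similarity ids do not match disease ids")
        profiles = a.values.T

    n_entities = profiles.shape[1]
    known = np.flatnonzero(profiles.sum(axis=0) > 0)
    new = np.zeros_like(profiles, dtype=float)
    for q in range(n_entities):
        pool = known[known != q]
        if pool.size == 0:
            logger.warning("entity %d has no known neighbours; profile left zero", q)
            continue
        sims = s.values[pool, q]
        # stable sort on -sims keeps lower indices first among ties
        order = np.argsort(-sims, kind="stable")[:k]
        nbrs = pool[order]
        nbr_sims = sims[order]
        q_norm = float(nbr_sims.sum())
        if q_norm == 0.0:
            logger.warning(
                "entity %d: all neighbour similarities are zero; profile set to 0", q
            )
            continue
        decay = alpha ** np.arange(len(nbrs))
        new[:, q] = profiles[:, nbrs] @ (decay * nbr_sims) / q_norm
    new = np.clip(new, 0.0, 1.0)
    values = new if axis == "drugs" else new.T
    return AssociationMatrix(values, a.disease_ids, a.drug_ids)


def fuse_associations(
    a: AssociationMatrix, a_r: AssociationMatrix, a_d: AssociationMatrix
) -> AssociationMatrix:
    """Fuse drug-side and disease-side estimates with the original matrix.

    ``A_DR = max(A, (A_r + A_d) / 2)`` elementwise; every validated
    association (``A = 1``) survives unchanged.
    """
    for other in (a_r, a_d):
        if other.disease_ids != a.disease_ids or other.drug_ids != a.drug_ids:
            raise ValueError("association matrices have mismatched identifiers")
    fused = np.maximum(a.values, (a_r.values + a_d.values) / 2.0)
    return AssociationMatrix(fused, a.disease_ids, a.drug_ids)


def wknn_preprocess(
    a: AssociationMatrix,
    drug_sims: list[SimilarityMatrix],
    disease_sims: list[SimilarityMatrix],
    k: int = 30,
    alpha: float = 0.95,
) -> AssociationMatrix:
    """Full WKNN densification.

    Averages the drug similarities into ``R`` and the disease
    similarities into ``D``, computes the drug-side estimate ``A_r``
    (columns) and the disease-side estimate ``A_d`` (rows), and fuses
    them with the original matrix.
    """
    r_mean = mean_similarity(drug_sims)
    d_mean = mean_similarity(disease_sims)
    a_r = wknn_update(a, r_mean, k, alpha, axis="drugs")
    a_d = wknn_update(a, d_mean, k, alpha, axis="diseases")
    return fuse_associations(a, a_r, a_d)
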
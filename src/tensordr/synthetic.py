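"""Seeded generators for drug-repositioning-shaped synthetic data.

Two fixtures:

* a full dataset (sparse binary association matrix plus five drug and
  two disease similarity matrices) in which both the associations and
  the similarities derive from the same low-rank latent factors, so the
  method's premise - similar drugs treat similar diseases - holds by
  construction and recovery of the planted structure is expected;
* planted low-tubal-rank + sparse tensors for direct solver tests.

Defaults mirror the shape of curated drug-indication benchmarks: a few
hundred entities with roughly 1-2% association density; the default
80 diseases x 120 drugs at density 0.02 is a desk-scale rendition of
that regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import AssociationMatrix, SimilarityMatrix
from .tensor_algebra import t_product

__all__ = [
    "SyntheticDataset",
    "generate_dataset",
    "generate_lowrank_sparse_tensor",
    "DRUG_SIM_NAMES",
    "DISEASE_SIM_NAMES",
]

#: slice order of the drug and disease similarity stacks
DRUG_SIM_NAMES = ("chem", "atc", "se", "ddi", "targ")
DISEASE_SIM_NAMES = ("ph", "do")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated benchmark with its ground truth.

    ``truth`` is the full latent association propensity in [0, 1];
    ``A`` holds 1 exactly at the top ``density * n * m`` propensity
    cells.
    """

    A: AssociationMatrix
    drug_sims: tuple[SimilarityMatrix, ...]
    disease_sims: tuple[SimilarityMatrix, ...]
    truth: np.ndarray
    latent_diseases: np.ndarray
    latent_drugs: np.ndarray
    seed: int


def _cosine_similarity(f: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(f, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    sim = (f @ f.T) / np.outer(norms, norms)
    return np.clip(sim, 0.0, 1.0)


def _noisy_similarity(
    base: np.ndarray, noise: float, rng: np.random.Generator, ids
) -> SimilarityMatrix:
    g = rng.standard_normal(base.shape)
    sim = base + noise * (g + g.T) / 2.0
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, ids)


def generate_dataset(
    n: int = 80,
    m: int = 120,
    rank: int = 6,
    density: float = 0.02,
    noise: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a dataset with planted low-rank association structure.

    Non-negative latent factors ``B`` (diseases) and ``C`` (drugs) give
    the propensity ``P = B C^T`` rescaled to [0, 1]; the association
    matrix is 1 at the top ``density * n * m`` propensity cells
    (deterministic top-k thresholding, so the positive count is exact).
    Each similarity matrix is the cosine similarity of the latent factor
    rows plus independent symmetric Gaussian noise of scale ``noise``,
    clipped to [0, 1] with unit diagonal.
    """
    if not 0 < density < 0.5:
        raise ValueError("density must lie in (0, 0.5)")
    if rank >= min(n, m):
        raise ValueError("rank must be smaller than min(n, m)")
    n_pos = int(round(density * n * m))
    if n_pos < 1:
        raise ValueError("density too small: no positive cells")
    rng = np.random.default_rng(seed)
    b = rng.random((n, rank))
    c = rng.random((m, rank))
    p = b @ c.T
    p = (p - p.min()) / (p.max() - p.min())

    flat_order = np.argsort(-p.ravel(), kind="stable")
    a = np.zeros(n * m)
    a[flat_order[:n_pos]] = 1.0
    a = a.reshape(n, m)

    disease_ids = tuple(f"d{i:03d}" for i in range(n))
    drug_ids = tuple(f"r{j:03d}" for j in range(m))
    drug_base = _cosine_similarity(c)
    disease_base = _cosine_similarity(b)
    drug_sims = tuple(
        _noisy_similarity(drug_base, noise, rng, drug_ids) for _ in DRUG_SIM_NAMES
    )
    disease_sims = tuple(
        _noisy_similarity(disease_base, noise, rng, disease_ids)
        for _ in DISEASE_SIM_NAMES
    )
    return SyntheticDataset(
        A=AssociationMatrix(a, disease_ids, drug_ids),
        drug_sims=drug_sims,
        disease_sims=disease_sims,
        truth=p,
        latent_diseases=b,
        latent_drugs=c,
        seed=seed,
    )


def generate_lowrank_sparse_tensor(
    n1: int,
    n2: int,
    n3: int,
    tubal_rank: int,
    sparse_frac: float,
    magnitude: float,
    box: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted low-tubal-rank tensor plus sparse corruption.

    Returns ``(M, L0, E0)``: ``L0`` is the t-product of two factor
    tensors with i.i.d. entries (non-negative uniform factors, ``L0``
    rescaled into [0, 1], when ``box``; standard normal otherwise);
    ``E0`` is ``+-magnitude`` at uniformly random cells with probability
    ``sparse_frac``; ``M = clip(L0 + E0, 0, 1)`` when ``box`` else
    ``L0 + E0``.  Every Fourier slice of ``L0`` has matrix rank at most
    ``tubal_rank``.
    """
    if tubal_rank >= min(n1, n2):
        raise ValueError("tubal_rank must be smaller than min(n1, n2)")
    if not 0 <= sparse_frac <= 0.3:
        raise ValueError("sparse_frac must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    if box:
        f1 = rng.random((n1, tubal_rank, n3))
        f2 = rng.random((tubal_rank, n2, n3))
        l0 = t_product(f1, f2)
        l0 = l0 / l0.max()  # pure scaling preserves the tubal rank
    else:
        f1 = rng.standard_normal((n1, tubal_rank, n3))
        f2 = rng.standard_normal((tubal_rank, n2, n3))
        l0 = t_product(f1, f2)
    support = rng.random((n1, n2, n3)) < sparse_frac
    signs = rng.choice([-1.0, 1.0], size=(n1, n2, n3))
    e0 = np.where(support, signs * magnitude, 0.0)
    m = np.clip(l0 + e0, 0.0, 1.0) if box else l0 + e0
    return m, l0, e0
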
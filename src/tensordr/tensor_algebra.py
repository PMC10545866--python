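"""t-product tensor algebra for third-order tensors.

A third-order tensor ``X`` of shape ``(n1, n2, n3)`` is viewed as an
``n1 x n2`` matrix of *tubes* (fibres along the third mode).  The
t-product multiplies tensors by circular convolution along tubes, which
becomes an ordinary matrix product per frontal slice after a DFT along
the third mode.  The t-SVD factorisation ``X = U * S * V^T`` and the
tensor norms built on the Fourier-slice singular values are the
foundation of the low-rank/sparse solver in :mod:`tensordr.solver`.

Conventions
-----------
Frontal slices are indexed ``x[:, :, k]`` with ``k = 0 .. n3-1``
(0-based; slice ``k`` here is slice ``k+1`` in the usual 1-based tensor
literature).  After transforming a real tensor, slice ``k`` and slice
``n3 - k`` (``k >= 1``) are elementwise complex conjugates; routines that
manipulate the transform only touch slices ``0 .. n3//2`` and mirror the
rest, so the inverse transform is exactly real by construction.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np

__all__ = [
    "fft_frontal",
    "ifft_frontal",
    "t_product",
    "t_transpose",
    "t_identity",
    "tsvd",
    "TSVDFactors",
    "weighted_schatten_p_norm",
    "tensor_nuclear_norm",
    "map_fourier_slices",
]

#: imaginary residue (relative to the real part) tolerated when casting an
#: inverse transform back to a real tensor
_IMAG_TOL = 1e-10


def _as_tensor3(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"{name} must be a third-order tensor, got ndim={x.ndim}")
    if x.shape[0] < 1 or x.shape[1] < 1 or x.shape[2] < 1:
        raise ValueError(f"{name} has a zero-length mode: shape={x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")
    return x


def fft_frontal(x: np.ndarray) -> np.ndarray:
    """Discrete Fourier transform along the third mode.

    Returns the complex array of Fourier-domain frontal slices; slice
    ``k`` is the ``k``-th plane of the length-``n3`` DFT taken tube by
    tube.  For real input the slices are conjugate-symmetric:
    ``F[:, :, n3-k] == conj(F[:, :, k])`` for ``k >= 1``.
    """
    x = _as_tensor3(x)
    return np.fft.fft(x, axis=2)


def ifft_frontal(f: np.ndarray, imag_tol: float = _IMAG_TOL) -> np.ndarray:
    """Inverse DFT along the third mode, returning a real tensor.

    The slices must be (numerically) conjugate-symmetric so that the
    inverse transform is real; an imaginary residue above ``imag_tol``
    relative to the tensor magnitude raises ``ValueError``.
    """
    f = np.asarray(f, dtype=complex)
    if f.ndim != 3:
        raise ValueError("Fourier slices must form a third-order array")
    x = np.fft.ifft(f, axis=2)
    scale = max(1.0, float(np.max(np.abs(x.real), initial=0.0)))
    residue = float(np.max(np.abs(x.imag), initial=0.0))
    if residue > imag_tol * scale:
        raise ValueError(
            f"inverse transform is not real: imaginary residue {residue:.3e} "
            f"exceeds tolerance {imag_tol:.1e} (conjugate symmetry violated)"
        )
    return np.ascontiguousarray(x.real)


def map_fourier_slices(
    x: np.ndarray, fn: Callable[[np.ndarray, int], np.ndarray]
) -> np.ndarray:
    """Apply ``fn`` to the leading Fourier slices of ``x`` and mirror.

    ``fn(slice, k)`` is evaluated for ``k = 0 .. n3//2`` only; the
    remaining slices are filled with the complex conjugates of their
    mirror images, so the inverse transform of the result is exactly
    real whenever ``fn`` maps conjugate inputs to conjugate outputs
    (true for any spectral function of the slice).
    """
    x = _as_tensor3(x)
    n3 = x.shape[2]
    xf = np.fft.fft(x, axis=2)
    first = fn(xf[:, :, 0], 0)
    out = np.empty(first.shape + (n3,), dtype=complex)
    out[:, :, 0] = first
    for k in range(1, n3 // 2 + 1):
        out[:, :, k] = fn(xf[:, :, k], k)
    for k in range(n3 // 2 + 1, n3):
        out[:, :, k] = np.conj(out[:, :, n3 - k])
    return out


def t_transpose(a: np.ndarray) -> np.ndarray:
    """Tensor transpose: transpose each frontal slice and reverse slices 2..n3."""
    a = _as_tensor3(a, "a")
    at = a.transpose(1, 0, 2)
    return np.concatenate([at[:, :, :1], at[:, :, 1:][:, :, ::-1]], axis=2)


def t_identity(n: int, n3: int) -> np.ndarray:
    """Identity tensor: first frontal slice is I_n, the rest are zero."""
    e = np.zeros((n, n, n3))
    e[:, :, 0] = np.eye(n)
    return e


def t_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """t-product of two tensors (slicewise product in the Fourier domain).

    ``a`` has shape ``(n1, n2, n3)`` and ``b`` shape ``(n2, n4, n3)``;
    the result has shape ``(n1, n4, n3)`` and equals the block-circulant
    unfolding matrix product folded back.
    """
    a = _as_tensor3(a, "a")
    b = _as_tensor3(b, "b")
    if a.shape[1] != b.shape[0]:
        raise ValueError(f"inner dimensions differ: {a.shape[1]} vs {b.shape[0]}")
    if a.shape[2] != b.shape[2]:
        raise ValueError(f"tensor depths differ: {a.shape[2]} vs {b.shape[2]}")
    bf = np.fft.fft(b, axis=2)
    cf = map_fourier_slices(a, lambda sl, k: sl @ bf[:, :, k])
    return ifft_frontal(cf)


class TSVDFactors(NamedTuple):
    """t-SVD factors ``U * S * V^T`` of a third-order tensor.

    ``U`` is ``(n1, l, n3)``, ``S`` is ``(l, l, n3)`` with f-diagonal
    slices (diagonal in the Fourier domain, real non-negative
    non-increasing entries), ``V`` is ``(n2, l, n3)``, ``l = min(n1, n2)``.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return t_product(self.U, t_product(self.S, t_transpose(self.V)))

    def fourier_singular_values(self) -> np.ndarray:
        """Singular values per Fourier slice, shape ``(l, n3)``, descending."""
        sf = np.fft.fft(self.S, axis=2)
        return np.einsum("iik->ik", sf).real


def tsvd(x: np.ndarray) -> TSVDFactors:
    """t-SVD via slicewise SVDs in the Fourier domain.

    Singular values within each Fourier slice are sorted non-increasing
    (LAPACK order); ties keep their original index order, and the
    factors are mirrored across conjugate slices so that ``U``, ``S``,
    ``V`` are exactly real.
    """
    x = _as_tensor3(x)
    n1, n2, n3 = x.shape
    l = min(n1, n2)
    xf = np.fft.fft(x, axis=2)
    uf = np.empty((n1, l, n3), dtype=complex)
    sf = np.zeros((l, l, n3), dtype=complex)
    vf = np.empty((n2, l, n3), dtype=complex)
    for k in range(n3 // 2 + 1):
        u, s, vh = np.linalg.svd(xf[:, :, k], full_matrices=False)
        uf[:, :, k] = u
        np.fill_diagonal(sf[:, :, k], s)
        vf[:, :, k] = vh.conj().T
        mirror = n3 - k
        if 0 < k < mirror < n3:
            uf[:, :, mirror] = np.conj(u)
            np.fill_diagonal(sf[:, :, mirror], s)
            vf[:, :, mirror] = vh.T
    return TSVDFactors(ifft_frontal(uf), ifft_frontal(sf), ifft_frontal(vf))


def weighted_schatten_p_norm(x: np.ndarray, w: np.ndarray, p: float) -> float:
    """Weighted tensor Schatten p-norm.

    ``(sum_i sum_j w_j * sigma_j(Xbar_i)^p) ** (1/p)`` over all ``n3``
    Fourier slices ``i``, where ``sigma_j`` are the slice singular
    values in descending order and ``w`` has length ``min(n1, n2)``.
    With ``p = 1`` and unit weights this is the tensor nuclear norm
    (sum of Fourier-slice nuclear norms, no ``1/n3`` factor).
    """
    x = _as_tensor3(x)
    w = np.asarray(w, dtype=float)
    l = min(x.shape[0], x.shape[1])
    if w.shape != (l,):
        raise ValueError(f"weight vector must have length {l}, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    xf = np.fft.fft(x, axis=2)
    total = 0.0
    for k in range(x.shape[2]):
        s = np.linalg.svd(xf[:, :, k], compute_uv=False)
        total += float(np.sum(w * s**p))
    return total ** (1.0 / p)


def tensor_nuclear_norm(x: np.ndarray) -> float:
    """Tensor nuclear norm: sum of nuclear norms of all Fourier slices."""
    x = _as_tensor3(x)
    l = min(x.shape[0], x.shape[1])
    return weighted_schatten_p_norm(x, np.ones(l), 1.0)
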
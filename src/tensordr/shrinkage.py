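"""Thresholding and proximal operators for the low-rank/sparse solver.

Three layers:

* scalar generalized soft-thresholding (GST), the proximal map of
  ``omega * |d|^p`` for ``p in (0, 1]``:  ``min_{d>=0} 0.5*(d-s)^2 + omega*d^p``
  has the closed threshold ``tau`` below which the solution is 0 and a
  larger stationary root above it;
* the matrix proximal operator of the weighted Schatten p-norm, which
  applies GST to descending singular values paired with ascending
  weights;
* the tensor proximal operator, which applies the matrix operator per
  Fourier-domain frontal slice.

Plus elementwise soft-thresholding (L1 prox) and box projection.
"""

from __future__ import annotations

import numpy as np

from .tensor_algebra import ifft_frontal, map_fourier_slices

__all__ = [
    "gst_threshold",
    "gst_solve",
    "gst_solve_array",
    "soft_threshold",
    "wtsnm_prox_matrix",
    "wtsnm_prox_tensor",
    "box_project",
]

_GST_MAX_ITER = 100
_GST_TOL = 1e-12


def _check_p(p: float) -> None:
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")


def gst_threshold(omega: float, p: float) -> float:
    """Shrink-to-zero threshold of the generalized soft-thresholding map.

    ``tau = (2*omega*(1-p))^(1/(2-p)) + omega*p*(2*omega*(1-p))^((p-1)/(2-p))``
    for ``p < 1``; the continuous limit ``tau = omega`` is used at
    ``p = 1`` (the formula is an indeterminate 0^0 there and the map
    degenerates to the ordinary soft threshold).
    """
    _check_p(p)
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if omega == 0:
        return 0.0
    if p == 1:
        return float(omega)
    base = (2.0 * omega * (1.0 - p)) ** (1.0 / (2.0 - p))
    return float(base + omega * p * (2.0 * omega * (1.0 - p)) ** ((p - 1.0) / (2.0 - p)))


def gst_solve(sigma: float, omega: float, p: float) -> float:
    """Minimiser of ``0.5*(d - sigma)^2 + omega*|d|^p`` over ``d``.

    Returns 0 when ``|sigma|`` is at or below :func:`gst_threshold`
    (the boundary is assigned to the zero branch); otherwise
    ``sign(sigma) * S`` where ``S > 0`` is the larger root of
    ``S - |sigma| + omega*p*S^(p-1) = 0``, found by fixed-point
    iteration started at ``|sigma|``.
    """
    return float(gst_solve_array(np.asarray([sigma], dtype=float), omega, p)[0])


def gst_solve_array(
    sigma: np.ndarray, omega: float | np.ndarray, p: float
) -> np.ndarray:
    """Vectorised :func:`gst_solve`; ``omega`` may vary per element."""
    _check_p(p)
    sigma = np.asarray(sigma, dtype=float)
    omega_arr = np.broadcast_to(np.asarray(omega, dtype=float), sigma.shape).copy()
    if np.any(omega_arr < 0):
        raise ValueError("omega must be non-negative")
    mag = np.abs(sigma)
    tau = np.array(
        [gst_threshold(o, p) for o in omega_arr.ravel()]
    ).reshape(sigma.shape)
    out = np.zeros_like(mag)
    active = mag > tau
    if not np.any(active):
        return out
    if p == 1:
        out[active] = mag[active] - omega_arr[active]
        return np.sign(sigma) * out
    s_act = mag[active]
    o_act = omega_arr[active]
    delta = s_act.copy()
    converged = False
    for _ in range(_GST_MAX_ITER):
        new = s_act - o_act * p * delta ** (p - 1.0)
        if not np.all(np.isfinite(new)) or np.any(new <= 0):
            raise ArithmeticError(
                "GST fixed-point iteration left the positive branch "
                f"(p={p}, min sigma={s_act.min():.3e})"
            )
        step = float(np.max(np.abs(new - delta)))
        delta = new
        if step < _GST_TOL:
            converged = True
            break
    if not converged:
        raise ArithmeticError(
            f"GST fixed-point iteration did not converge within {_GST_MAX_ITER} "
            f"steps (last step {step:.3e}, p={p})"
        )
    out[active] = delta
    return np.sign(sigma) * out


def soft_threshold(h: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise soft-thresholding ``sign(h) * max(|h| - tau, 0)``."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    h = np.asarray(h, dtype=float)
    return np.sign(h) * np.maximum(np.abs(h) - tau, 0.0)


def _check_weights(w: np.ndarray, l: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (l,):
        raise ValueError(f"weight vector must have length {l}, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diff(w) < 0):
        raise ValueError("weights must be sorted ascending (small singular "
                         "values receive the large weights)")
    return w


def wtsnm_prox_matrix(
    y: np.ndarray, tau: float, w: np.ndarray, p: float
) -> np.ndarray:
    """Proximal operator of ``tau * ||.||_{w,Sp}^p`` at matrix ``y``.

    ``y`` may be real or complex; its (descending) singular values are
    shrunk by GST with per-value weights ``tau * w_i``, weights sorted
    ascending, and the matrix is rebuilt with the original singular
    vectors.  Ties among singular values keep the sorted-position
    weight assignment.
    """
    y = np.asarray(y)
    l = min(y.shape)
    w = _check_weights(w, l)
    if tau < 0:
        raise ValueError("tau must be non-negative")
    u, s, vh = np.linalg.svd(y, full_matrices=False)
    gamma = gst_solve_array(s, tau * w, p)
    return (u * gamma) @ vh


def wtsnm_prox_tensor(
    a: np.ndarray, tau: float, w: np.ndarray, p: float
) -> np.ndarray:
    """Tensor proximal operator of the weighted Schatten p-norm.

    Applies :func:`wtsnm_prox_matrix` with the same ``(tau, w, p)`` to
    each Fourier-domain frontal slice (leading half processed, the rest
    conjugate-mirrored) and transforms back; the output is real.
    """
    a = np.asarray(a, dtype=float)
    l = min(a.shape[0], a.shape[1])
    w = _check_weights(w, l)
    out_f = map_fourier_slices(a, lambda sl, k: wtsnm_prox_matrix(sl, tau, w, p))
    return ifft_frontal(out_f)


def box_project(x: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Elementwise projection onto the interval ``[lo, hi]``."""
    if lo > hi:
        raise ValueError(f"lower bound {lo} exceeds upper bound {hi}")
    return np.clip(np.asarray(x, dtype=float), lo, hi)
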
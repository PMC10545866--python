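"""Box-constrained low-rank + sparse tensor decomposition.

Solves

    min_{X, E}  lambda * ||E||_1 + ||X||_{w,Sp}^p
    s.t.        M = X + E,   lo <= X <= hi

by an augmented Lagrangian (ALM) scheme: alternating elementwise
soft-thresholding for the sparse part ``E``, the weighted tensor
Schatten p-norm proximal operator for the low-rank part ``X`` followed
by projection onto the box, a multiplier update, and a geometrically
growing penalty.  With ``p = 1``, unit weights and the box disabled the
iteration is the classical tensor robust PCA ALM; at depth 1 it is
matrix robust PCA.

The weight vector grades how strongly each singular value is shrunk:
leading (signal) values get weight 1, later (noise) values get weights
2 and 4.  The split points are chosen adaptively from the spectral
energy of the input tensor's Fourier slices, once, before iterating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .shrinkage import box_project, soft_threshold, wtsnm_prox_tensor
from .tensor_algebra import fft_frontal

__all__ = [
    "SolverConfig",
    "SolverResult",
    "adaptive_weights",
    "check_convergence",
    "solve",
    "default_lambda",
]

logger = logging.getLogger(__name__)


def default_lambda(shape: tuple[int, int, int]) -> float:
    """Default sparsity regulariser ``1 / sqrt(n3 * max(n1, n2))``.

    The canonical tensor-RPCA scaling: it balances the L1 and spectral
    terms so that the sparse part captures entrywise outliers instead of
    swallowing the whole tensor (any constant much smaller than this
    makes ``E = M, X = 0`` near-optimal and the decomposition collapses).
    """
    n1, n2, n3 = shape
    return 1.0 / np.sqrt(n3 * max(n1, n2))


@dataclass(frozen=True)
class SolverConfig:
    """Hyperparameters of the ALM solver.

    Parameters
    ----------
    lam:
        Sparsity regulariser lambda; ``None`` means the size-dependent
        default ``1/sqrt(n3*max(n1, n2))``.
    p:
        Schatten exponent in (0, 1]; 0.9 by default.
    rho, mu0, mu_max:
        Penalty growth factor (> 1), initial penalty and penalty cap of
        the schedule ``mu_{k+1} = min(rho * mu_k, mu_max)``.
    tol1, tol2:
        Stopping tolerances: stop when the relative change of ``X``
        satisfies ``f_k <= tol1`` and the change of ``f`` itself
        satisfies ``|f_{k+1} - f_k| / max(1, |f_k|) <= tol2``.
    feas_tol:
        Relative primal feasibility ``||M - X - E||_F / ||M||_F``
        additionally required at the stop.  Without it the iterate-change
        rule fires on the transient zero phase (X stays 0 while the
        penalty is far below the spectral scale, so its relative change
        is trivially 0 long before the constraint ``M = X + E`` holds).
    max_iter:
        Iteration cap.
    box:
        ``(lo, hi)`` bounds for ``X``; ``None`` disables the projection
        (plain tensor robust PCA).
    weight_levels, weight_fractions:
        The three weight values and the two spectral-energy fractions of
        the adaptive weighting scheme.
    weights_override:
        Explicit weight vector (ascending, length ``min(n1, n2)``);
        bypasses the adaptive scheme.
    """

    lam: float | None = None
    p: float = 0.9
    rho: float = 1.1
    mu0: float = 1e-4
    mu_max: float = 1e10
    tol1: float = 1e-3
    tol2: float = 1e-4
    feas_tol: float = 1e-6
    max_iter: int = 500
    box: tuple[float, float] | None = (0.0, 1.0)
    weight_levels: tuple[float, float, float] = (1.0, 2.0, 4.0)
    weight_fractions: tuple[float, float] = (0.1, 0.2)
    weights_override: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if not 0 < self.mu0 < self.mu_max:
            raise ValueError("need 0 < mu0 < mu_max")
        if self.tol1 <= 0 or self.tol2 <= 0 or self.feas_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.box is not None and self.box[0] > self.box[1]:
            raise ValueError("box lower bound exceeds upper bound")
        if np.any(np.diff(self.weight_levels) < 0):
            raise ValueError("weight_levels must be non-decreasing")

    def with_(self, **kwargs) -> "SolverConfig":
        return replace(self, **kwargs)


@dataclass
class SolverResult:
    """Output of :func:`solve`.

    ``X`` is the recovered low-rank tensor (inside the box), ``E`` the
    sparse residual, and ``history`` records per-iteration diagnostics
    ``(f_k, feasibility ||M - X - E||_F, mu_k)``.
    """

    X: np.ndarray
    E: np.ndarray
    iterations: int
    converged: bool
    weights: np.ndarray
    lam: float
    history: list[tuple[float, float, float]] = field(repr=False, default_factory=list)

    @property
    def final_feasibility(self) -> float:
        return self.history[-1][1] if self.history else float("nan")


def adaptive_weights(
    m: np.ndarray,
    fractions: tuple[float, float] = (0.1, 0.2),
    levels: tuple[float, float, float] = (1.0, 2.0, 4.0),
) -> np.ndarray:
    """Three-level weight vector from the spectral energy of ``m``.

    For each Fourier-domain frontal slice ``j``, ``u_j`` (``v_j``) is
    the smallest number of leading singular values capturing at least
    ``fractions[0]`` (``fractions[1]``) of the slice's singular-value
    sum.  ``U`` and ``V`` are the slice averages rounded to the nearest
    integer and clamped to ``1 <= U <= V <= min(n1, n2)``; positions
    ``1..U`` get ``levels[0]``, ``U+1..V`` get ``levels[1]`` and the
    remainder ``levels[2]``.  An all-zero slice contributes
    ``u_j = v_j = 1``.
    """
    f1, f2 = fractions
    if not (0 < f1 < f2 < 1):
        raise ValueError("fractions must be strictly increasing within (0, 1)")
    if np.any(np.diff(levels) < 0):
        raise ValueError("levels must be non-decreasing")
    mf = fft_frontal(m)
    l = min(m.shape[0], m.shape[1])
    us, vs = [], []
    for j in range(m.shape[2]):
        s = np.linalg.svd(mf[:, :, j], compute_uv=False)
        total = s.sum()
        if total == 0:
            us.append(1)
            vs.append(1)
            continue
        ratio = np.cumsum(s) / total
        us.append(int(np.searchsorted(ratio, f1 - 1e-12) + 1))
        vs.append(int(np.searchsorted(ratio, f2 - 1e-12) + 1))
    # round-half-up keeps the index deterministic across platforms
    u_cap = int(np.floor(np.mean(us) + 0.5))
    v_cap = int(np.floor(np.mean(vs) + 0.5))
    u_cap = min(max(u_cap, 1), l)
    v_cap = min(max(v_cap, u_cap), l)
    w = np.empty(l)
    w[:u_cap] = levels[0]
    w[u_cap:v_cap] = levels[1]
    w[v_cap:] = levels[2]
    return w


def check_convergence(
    x_prev: np.ndarray,
    x_next: np.ndarray,
    f_prev: float,
    tol1: float,
    tol2: float,
) -> tuple[bool, float]:
    """Joint stopping rule on the relative change of the iterate.

    ``f_next = ||x_next - x_prev||_F / ||x_prev||_F`` (denominator 1
    when ``x_prev`` is zero); stop iff ``f_next <= tol1`` and
    ``|f_next - f_prev| / max(1, |f_prev|) <= tol2``.
    """
    den = float(np.linalg.norm(x_prev))
    if den == 0.0:
        den = 1.0
    f_next = float(np.linalg.norm(x_next - x_prev)) / den
    stop = f_next <= tol1 and abs(f_next - f_prev) / max(1.0, abs(f_prev)) <= tol2
    return stop, f_next


def solve(m: np.ndarray, config: SolverConfig | None = None) -> SolverResult:
    """Run the ALM iteration on tensor ``m``.

    Starting from ``X = E = L = 0``, each sweep updates in turn::

        E <- soft_threshold(M + L/mu - X, lam/mu)
        X <- box_project(prox_{w,Sp}(M + L/mu - E, 1/mu))
        L <- L + mu * (M - X - E)
        mu <- min(rho * mu, mu_max)

    and stops on the joint tolerance rule or at ``max_iter``.  The
    solver contains no randomness: identical inputs give bitwise
    identical results.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 3:
        raise ValueError("m must be a third-order tensor")
    if not np.all(np.isfinite(m)):
        raise ValueError("m contains non-finite entries")
    if config is None:
        config = SolverConfig()
    lam = config.lam if config.lam is not None else default_lambda(m.shape)
    if config.weights_override is not None:
        w = np.asarray(config.weights_override, dtype=float)
    else:
        w = adaptive_weights(m, config.weight_fractions, config.weight_levels)

    x = np.zeros_like(m)
    e = np.zeros_like(m)
    lagr = np.zeros_like(m)
    mu = config.mu0
    norm_m = float(np.linalg.norm(m))
    f_prev = 0.0
    history: list[tuple[float, float, float]] = []
    converged = False
    iterations = 0

    for k in range(config.max_iter):
        e = soft_threshold(m + lagr / mu - x, lam / mu)
        x_star = wtsnm_prox_tensor(m + lagr / mu - e, 1.0 / mu, w, config.p)
        if config.box is not None:
            x_next = box_project(x_star, *config.box)
        else:
            x_next = x_star
        lagr = lagr + mu * (m - x_next - e)
        stop, f_next = check_convergence(x, x_next, f_prev, config.tol1, config.tol2)
        x = x_next
        mu = min(config.rho * mu, config.mu_max)
        feas = float(np.linalg.norm(m - x - e))
        history.append((f_next, feas, mu))
        iterations = k + 1
        if not np.isfinite(f_next):
            raise ArithmeticError(
                f"solver diverged at iteration {iterations} (f={f_next}); "
                f"history={history[-5:]}"
            )
        logger.debug(
            "iter=%d f=%.3e feas=%.3e mu=%.3e", iterations, f_next, feas, mu
        )
        f_prev = f_next
        if stop and feas <= config.feas_tol * max(norm_m, 1e-300):
            converged = True
            break

    return SolverResult(
        X=x,
        E=e,
        iterations=iterations,
        converged=converged,
        weights=w,
        lam=lam,
        history=history,
    )
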
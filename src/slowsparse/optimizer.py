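"""Gradient projection on the orthogonal group.

A Rosen-style projected gradient descent: take a plain gradient step on the
filter matrix, project the result back onto the orthogonal group with
symmetric (Löwdin) orthogonalization -- the Frobenius-closest orthonormal
matrix -- and backtrack the step length until the objective improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "random_orthonormal",
    "symmetric_orthogonalize",
    "optimize",
]


@dataclass
class OptimizerConfig:
    """Settings for the projected gradient descent.

    Parameters
    ----------
    mu0 : float
        Initial step length of the line search.
    backtrack_factor : float
        Multiplicative reduction of the step length while the candidate does
        not improve the objective; must lie in (0, 1).
    max_backtracks : int
        Line-search attempts per iteration before declaring convergence.
    tol : float
        Relative objective-change threshold for termination.
    max_iter : int
        Iteration cap.
    adaptive_step : bool
        If true (default) the step length carries over between iterations and
        doubles after a step accepted without backtracking; otherwise every
        iteration restarts the search at ``mu0``.
    """

    mu0: float = 1.0
    backtrack_factor: float = 0.5
    max_backtracks: int = 30
    tol: float = 1e-8
    max_iter: int = 2000
    adaptive_step: bool = True

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if not 0.0 < self.backtrack_factor < 1.0:
            raise ValueError("backtrack_factor must lie strictly in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1 or self.max_backtracks < 1:
            raise ValueError("max_iter and max_backtracks must be >= 1")


@dataclass
class OptimizationTrace:
    """Record of one optimization run (accepted iterations only)."""

    objective_per_iteration: list[float] = field(default_factory=list)
    accepted_step_lengths: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    message: str = ""


def random_orthonormal(d: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw a Haar-distributed orthonormal ``d x d`` matrix.

    ``d`` must be even so that the rows can be grouped into two-dimensional
    subspaces.
    """
    if d < 2:
        raise ValueError("dimension must be at least 2")
    if d % 2:
        raise ValueError(f"dimension must be even to form 2-D subspaces, got {d}")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((d, d))
    q, r = np.linalg.qr(a)
    # Sign fix makes the QR-based draw exactly Haar on O(d).
    q *= np.sign(np.diag(r))
    return q


def symmetric_orthogonalize(m: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Project ``m`` onto the orthogonal group: ``m (m^T m)^{-1/2}``.

    Computed through the symmetric eigendecomposition of ``m^T m``.  Raises
    for (numerically) singular input, naming the offending singular value.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    gram = m.T @ m
    evals, evecs = np.linalg.eigh(gram)
    smallest_sv = float(np.sqrt(max(evals[0], 0.0)))
    largest_sv = float(np.sqrt(max(evals[-1], 0.0)))
    if smallest_sv <= floor * max(largest_sv, 1.0):
        raise np.linalg.LinAlgError(
            f"matrix is numerically singular: smallest singular value {smallest_sv:.3e}"
        )
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    return m @ inv_sqrt


def optimize(
    value: Callable[[np.ndarray], float],
    value_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    w0: np.ndarray,
    config: OptimizerConfig | None = None,
) -> tuple[np.ndarray, OptimizationTrace]:
    """Minimize ``value`` over orthonormal matrices starting from ``w0``.

    Each iteration forms the candidate
    ``symmetric_orthogonalize(W - mu * grad)`` and shrinks ``mu`` by
    ``backtrack_factor`` until the candidate strictly improves the objective.
    If no improving step is found within ``max_backtracks`` the current point
    is returned as converged (monotone descent is never violated).
    """
    config = config or OptimizerConfig()
    w = np.array(w0, dtype=float)
    trace = OptimizationTrace()

    f, grad = value_and_grad(w)
    if not np.isfinite(f) or not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite objective or gradient at iteration 0")
    trace.objective_per_iteration.append(float(f))

    mu = config.mu0
    for iteration in range(1, config.max_iter + 1):
        if not config.adaptive_step:
            mu = config.mu0
        accepted = False
        backtracked = False
        for _ in range(config.max_backtracks):
            cand = symmetric_orthogonalize(w - mu * grad)
            f_cand = value(cand)
            if not np.isfinite(f_cand):
                raise FloatingPointError(
                    f"non-finite objective during line search at iteration {iteration}"
                )
            if f_cand < f:
                accepted = True
                break
            mu *= config.backtrack_factor
            backtracked = True
        if not accepted:
            trace.converged = True
            trace.message = "no improving step within max_backtracks"
            break

        improvement = f - f_cand
        w = cand
        f = f_cand
        trace.objective_per_iteration.append(float(f))
        trace.accepted_step_lengths.append(float(mu))
        trace.n_iterations = iteration
        if config.adaptive_step and not backtracked:
            mu *= 2.0

        if improvement <= config.tol * max(1.0, abs(f)):
            trace.converged = True
            trace.message = "objective change below tolerance"
            break

        f_check, grad = value_and_grad(w)
        if not np.isfinite(f_check) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at iteration {iteration}")
    else:
        trace.message = "maximum number of iterations reached"

    return w, trace
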
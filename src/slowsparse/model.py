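"""Subspace-energy models and the slowness / sparsity objectives.

The representation is an orthonormal filter matrix ``W`` acting on whitened
inputs ``x``.  Consecutive row pairs of ``W`` span two-dimensional subspaces
and the model output is the squared norm of the projection of ``x`` onto each
subspace,

    y_i(t) = sum_{k in subspace i} (w_k^T x(t))^2,

the classical energy model of a complex cell.  If the filters are discrete
Fourier quadrature pairs (same frequency, 90 degrees apart) the outputs are
exactly the power spectrum of the input.

Three objectives are defined over a bank of such units, all minimized under
the constraint that ``W`` stays orthonormal:

* slowness (SSA): the mean squared temporal difference of the subspace
  energies over adjacent frame pairs,
  ``Psi_slow = (1/I) sum_i mean_t (y_i(t+1) - y_i(t))^2``;
* sparsity (ISA): the negative log-likelihood of a spherical exponential
  distribution on each subspace, with constants dropped,
  ``Psi_sparse = (1/(I T)) sum_{t,i} sqrt(y_i(t))``;
* their one-parameter mixture
  ``Psi = (1 - gamma) Psi_slow + gamma Psi_sparse``  (gamma in [0, 1]),
  which interpolates between SSA (gamma = 0) and ISA (gamma = 1).

Both objectives are averaged over subspaces and time so the mixture combines
quantities on comparable per-unit scales.  No ``1/K`` factor is applied to the
energies; on whitened data ``E[y_i] = K``.  Constant factors rescale the
objectives without moving their optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .optimizer import OptimizerConfig, optimize, random_orthonormal

__all__ = [
    "ObjectiveSpec",
    "ObjectiveValue",
    "subspace_energies",
    "ssa_objective",
    "ssa_gradient",
    "isa_objective",
    "isa_gradient",
    "mixed_objective",
    "SubspaceAnalysis",
    "SlowSubspaceAnalysis",
    "IndependentSubspaceAnalysis",
]

#: epsilon inside sqrt(y) for the sparsity gradient; guards y = 0 at a scale
#: far below whitened-data energies.
SQRT_EPS = 1e-12


@dataclass
class ObjectiveSpec:
    """Objective selection: the slowness/sparsity trade-off weight.

    ``gamma = 0`` is pure slowness (SSA), ``gamma = 1`` pure sparsity (ISA).
    ``alpha`` and ``log_z`` are the scale and normalization constants of the
    spherical exponential density; they do not move the optimum and are
    dropped from the objective (kept here only to make that choice explicit).
    """

    gamma: float = 0.0
    alpha: float = 1.0
    log_z: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")


@dataclass
class ObjectiveValue:
    """Value of the (mixed) objective with its decomposition."""

    total: float
    slow_part: float
    sparse_part: float
    per_subspace_slowness: np.ndarray | None = None


def _check_bank(w: np.ndarray, subspace_dim: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("filter matrix must be square (complete representation)")
    if w.shape[0] % subspace_dim:
        raise ValueError(
            f"dimension {w.shape[0]} is not divisible by subspace_dim {subspace_dim}"
        )
    return w


def subspace_energies(w: np.ndarray, x: np.ndarray, subspace_dim: int = 2) -> np.ndarray:
    """Energy outputs ``y_i(t)`` for every sample.

    Parameters
    ----------
    w : (D, D) orthonormal filter matrix, rows are filters; consecutive
        ``subspace_dim`` rows form one subspace.
    x : (T, D) whitened input samples.

    Returns
    -------
    (T, I) array of non-negative energies, ``I = D / subspace_dim``.  For an
    orthonormal complete ``w`` the energies of each sample sum to its squared
    norm.
    """
    w = _check_bank(w, subspace_dim)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != w.shape[0]:
        raise ValueError(f"input width {x.shape[1]} != filter dimension {w.shape[0]}")
    r = x @ w.T
    return _energies_from_responses(r, subspace_dim)


def _energies_from_responses(r: np.ndarray, subspace_dim: int) -> np.ndarray:
    t, d = r.shape
    return (r * r).reshape(t, d // subspace_dim, subspace_dim).sum(axis=2)


def _expand(y: np.ndarray, subspace_dim: int) -> np.ndarray:
    """Repeat each subspace column once per filter of that subspace."""
    return np.repeat(y, subspace_dim, axis=1)


def _check_pairs(x_t: np.ndarray, x_t1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    x_t1 = np.atleast_2d(np.asarray(x_t1, dtype=float))
    if x_t.shape != x_t1.shape:
        raise ValueError("x_t and x_t1 must have the same shape")
    if x_t.shape[0] == 0:
        raise ValueError("empty pair set")
    return x_t, x_t1


def ssa_objective(
    w: np.ndarray, x_t: np.ndarray, x_t1: np.ndarray, subspace_dim: int = 2
) -> ObjectiveValue:
    """Temporal-smoothness objective: mean squared energy difference.

    ``s_i = mean_t (y_i(t+1) - y_i(t))^2`` per subspace (the inverse
    slowness; 0 means perfect invariance), ``Psi_slow = mean_i s_i``.
    """
    x_t, x_t1 = _check_pairs(x_t, x_t1)
    dy = subspace_energies(w, x_t1, subspace_dim) - subspace_energies(w, x_t, subspace_dim)
    s = np.mean(dy * dy, axis=0)
    psi = float(np.mean(s))
    return ObjectiveValue(total=psi, slow_part=psi, sparse_part=0.0, per_subspace_slowness=s)


def ssa_gradient(
    w: np.ndarray, x_t: np.ndarray, x_t1: np.ndarray, subspace_dim: int = 2
) -> np.ndarray:
    """Exact gradient of :func:`ssa_objective` with respect to ``W``."""
    x_t, x_t1 = _check_pairs(x_t, x_t1)
    w = _check_bank(w, subspace_dim)
    r0 = x_t @ w.T
    r1 = x_t1 @ w.T
    y0 = _energies_from_responses(r0, subspace_dim)
    y1 = _energies_from_responses(r1, subspace_dim)
    dy = _expand(y1 - y0, subspace_dim)
    t, d = x_t.shape
    n_sub = d // subspace_dim
    return (4.0 / (n_sub * t)) * ((dy * r1).T @ x_t1 - (dy * r0).T @ x_t)


def isa_objective(w: np.ndarray, x: np.ndarray, subspace_dim: int = 2) -> ObjectiveValue:
    """Sparsity objective: mean subspace norm (spherical exponential NLL).

    The scaling and normalization constants of the density are omitted; the
    objective is minimized, and is lower for heavy-tailed (sparse) energy
    profiles at fixed mean energy.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("empty sample set")
    y = subspace_energies(w, x, subspace_dim)
    psi = float(np.mean(np.sqrt(y)))
    return ObjectiveValue(total=psi, slow_part=0.0, sparse_part=psi)


def isa_gradient(w: np.ndarray, x: np.ndarray, subspace_dim: int = 2) -> np.ndarray:
    """Gradient of :func:`isa_objective`; ``sqrt`` guarded by a tiny epsilon."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("empty sample set")
    w = _check_bank(w, subspace_dim)
    r = x @ w.T
    y = _energies_from_responses(r, subspace_dim)
    t, d = x.shape
    n_sub = d // subspace_dim
    a = r / _expand(np.sqrt(y + SQRT_EPS), subspace_dim)
    return (1.0 / (n_sub * t)) * (a.T @ x)


def mixed_objective(
    w: np.ndarray,
    x_t: np.ndarray,
    x_t1: np.ndarray,
    spec: ObjectiveSpec,
    subspace_dim: int = 2,
    with_gradient: bool = False,
) -> ObjectiveValue | tuple[ObjectiveValue, np.ndarray]:
    """Weighted mixture ``(1 - gamma) Psi_slow + gamma Psi_sparse``.

    The sparsity part is evaluated on the first frames ``x_t`` (for data
    produced by a walk these are the full frame stream).  At the endpoints the
    unused part is skipped, so ``gamma = 0`` reproduces the SSA objective and
    ``gamma = 1`` the ISA objective bit-exactly.
    """
    gamma = spec.gamma
    slow_part, sparse_part = 0.0, 0.0
    s = None
    grad = None
    if gamma < 1.0:
        ov = ssa_objective(w, x_t, x_t1, subspace_dim)
        slow_part, s = ov.slow_part, ov.per_subspace_slowness
        if with_gradient:
            grad = (1.0 - gamma) * ssa_gradient(w, x_t, x_t1, subspace_dim)
    if gamma > 0.0:
        sparse_part = isa_objective(w, x_t, subspace_dim).sparse_part
        if with_gradient:
            g_sparse = gamma * isa_gradient(w, x_t, subspace_dim)
            grad = g_sparse if grad is None else grad + g_sparse
    total = (1.0 - gamma) * slow_part + gamma * sparse_part
    value = ObjectiveValue(
        total=total, slow_part=slow_part, sparse_part=sparse_part, per_subspace_slowness=s
    )
    if with_gradient:
        return value, grad
    return value


class SubspaceAnalysis(TransformerMixin, BaseEstimator):
    """Energy-model subspace learning under a slowness/sparsity mixture.

    Fits a complete orthonormal filter bank on whitened frame pairs by
    projected gradient descent on the orthogonal group.  ``gamma`` selects
    the objective: 0 is slow subspace analysis (SSA), 1 is independent
    subspace analysis (ISA), intermediate values their weighted mixture
    (ISSA).

    Parameters
    ----------
    gamma : float in [0, 1]
        Trade-off weight between slowness and sparsity.
    subspace_dim : int
        Filters per subspace (the energy-model pair size), default 2.
    mu0, backtrack_factor, max_backtracks, tol, max_iter, adaptive_step
        Line-search and termination settings, see
        :class:`~slowsparse.optimizer.OptimizerConfig`.
    init : None or (D, D) array
        Starting filter bank; a seeded random orthonormal matrix if None.
    random_state : int or None
        Seed for the random initialization.

    Attributes
    ----------
    components_ : (D, D) array
        Learned orthonormal filter bank, rows are filters; consecutive
        ``subspace_dim`` rows form one subspace.
    n_subspaces_ : int
    objective_ : float
        Final objective value on the training pairs.
    objective_value_ : ObjectiveValue
        Final objective with its slow/sparse decomposition.
    slowness_ : (I,) array or None
        Per-subspace inverse slowness on the training pairs (None for pure
        ISA fits without pair data).
    trace_ : OptimizationTrace
    """

    def __init__(
        self,
        gamma: float = 0.0,
        subspace_dim: int = 2,
        mu0: float = 1.0,
        backtrack_factor: float = 0.5,
        max_backtracks: int = 30,
        tol: float = 1e-8,
        max_iter: int = 2000,
        adaptive_step: bool = True,
        init: np.ndarray | None = None,
        random_state: int | None = None,
    ) -> None:
        self.gamma = gamma
        self.subspace_dim = subspace_dim
        self.mu0 = mu0
        self.backtrack_factor = backtrack_factor
        self.max_backtracks = max_backtracks
        self.tol = tol
        self.max_iter = max_iter
        self.adaptive_step = adaptive_step
        self.init = init
        self.random_state = random_state

    def _optimizer_config(self) -> OptimizerConfig:
        return OptimizerConfig(
            mu0=self.mu0,
            backtrack_factor=self.backtrack_factor,
            max_backtracks=self.max_backtracks,
            tol=self.tol,
            max_iter=self.max_iter,
            adaptive_step=self.adaptive_step,
        )

    def fit(self, X, y=None, X_next=None):
        """Learn the filter bank from whitened frames.

        Parameters
        ----------
        X : (T, D) array
            Whitened frames ``x(t)``.
        X_next : (T, D) array, required unless ``gamma == 1``
            The temporally adjacent frames ``x(t+1)``.
        """
        spec = ObjectiveSpec(gamma=self.gamma)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x dimensions)")
        d = X.shape[1]
        if d % self.subspace_dim:
            raise ValueError(
                f"data dimension {d} not divisible by subspace_dim {self.subspace_dim}"
            )
        if spec.gamma < 1.0:
            if X_next is None:
                raise ValueError("X_next (adjacent frames) is required unless gamma == 1")
            X, X_next = _check_pairs(X, X_next)

        if self.init is not None:
            w0 = np.array(self.init, dtype=float)
            if w0.shape != (d, d):
                raise ValueError(f"init must have shape ({d}, {d})")
        else:
            w0 = random_orthonormal(d, self.random_state)

        if spec.gamma == 1.0:

            def value(w):
                return isa_objective(w, X, self.subspace_dim).total

            def value_and_grad(w):
                return (
                    isa_objective(w, X, self.subspace_dim).total,
                    isa_gradient(w, X, self.subspace_dim),
                )

        else:

            def value(w):
                return mixed_objective(w, X, X_next, spec, self.subspace_dim).total

            def value_and_grad(w):
                ov, g = mixed_objective(
                    w, X, X_next, spec, self.subspace_dim, with_gradient=True
                )
                return ov.total, g

        w, trace = optimize(value, value_and_grad, w0, self._optimizer_config())

        self.components_ = w
        self.n_features_in_ = d
        self.n_subspaces_ = d // self.subspace_dim
        self.trace_ = trace
        self.initial_components_ = w0
        if spec.gamma == 1.0:
            ov = isa_objective(w, X, self.subspace_dim)
            if X_next is not None:
                ov_s = ssa_objective(w, X, X_next, self.subspace_dim)
                self.slowness_ = ov_s.per_subspace_slowness
            else:
                self.slowness_ = None
        else:
            ov = mixed_objective(w, X, X_next, spec, self.subspace_dim)
            self.slowness_ = ov.per_subspace_slowness
        self.objective_value_ = ov
        self.objective_ = ov.total
        return self

    def transform(self, X) -> np.ndarray:
        """Subspace energies of ``X`` under the learned bank."""
        check_is_fitted(self, "components_")
        return subspace_energies(self.components_, X, self.subspace_dim)


class SlowSubspaceAnalysis(SubspaceAnalysis):
    """Pure slowness learning (SSA): :class:`SubspaceAnalysis` at gamma = 0."""

    def __init__(
        self,
        subspace_dim: int = 2,
        mu0: float = 1.0,
        backtrack_factor: float = 0.5,
        max_backtracks: int = 30,
        tol: float = 1e-8,
        max_iter: int = 2000,
        adaptive_step: bool = True,
        init: np.ndarray | None = None,
        random_state: int | None = None,
    ) -> None:
        super().__init__(
            gamma=0.0,
            subspace_dim=subspace_dim,
            mu0=mu0,
            backtrack_factor=backtrack_factor,
            max_backtracks=max_backtracks,
            tol=tol,
            max_iter=max_iter,
            adaptive_step=adaptive_step,
            init=init,
            random_state=random_state,
        )


class IndependentSubspaceAnalysis(SubspaceAnalysis):
    """Pure sparsity learning (ISA): :class:`SubspaceAnalysis` at gamma = 1."""

    def __init__(
        self,
        subspace_dim: int = 2,
        mu0: float = 1.0,
        backtrack_factor: float = 0.5,
        max_backtracks: int = 30,
        tol: float = 1e-8,
        max_iter: int = 2000,
        adaptive_step: bool = True,
        init: np.ndarray | None = None,
        random_state: int | None = None,
    ) -> None:
        super().__init__(
            gamma=1.0,
            subspace_dim=subspace_dim,
            mu0=mu0,
            backtrack_factor=backtrack_factor,
            max_backtracks=max_backtracks,
            tol=tol,
            max_iter=max_iter,
            adaptive_step=adaptive_step,
            init=init,
            random_state=random_state,
        )
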
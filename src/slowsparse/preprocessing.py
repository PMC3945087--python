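"""DC projection and symmetric (ZCA) whitening of image patch vectors.

Patches are vectorized column-major.  The constant (DC) direction carries the
patch mean and is projected out; the remaining AC coordinates -- expressed in
a fixed, deterministic orthonormal basis of the complement of the all-ones
vector -- are decorrelated with the symmetric whitener ``C^{-1/2}``.  No
low-pass filtering or dimensionality reduction is applied.  Learned filters
live in the whitened coordinates and are mapped back to pixel space for
inspection; the back-projection preserves filter responses exactly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "vectorize_patch",
    "devectorize_patch",
    "ac_basis",
    "PatchWhitener",
    "fit_preprocessor",
    "apply_preprocessor",
    "filters_to_pixel_space",
]


def vectorize_patch(patch: np.ndarray) -> np.ndarray:
    """Stack the columns of a 2-D patch into a vector (column-major)."""
    patch = np.asarray(patch)
    if patch.ndim != 2:
        raise ValueError("expected a 2-D patch")
    return patch.ravel(order="F")


def devectorize_patch(v: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`vectorize_patch`."""
    return np.asarray(v).reshape(shape, order="F")


def ac_basis(d: int) -> np.ndarray:
    """Deterministic orthonormal basis of the complement of the ones vector.

    Columns 2..d of the Householder reflection that maps the first unit
    vector onto ``ones/sqrt(d)``; shape ``(d, d - 1)``.
    """
    if d < 2:
        raise ValueError("need at least 2 pixels")
    u = np.full(d, 1.0 / np.sqrt(d))
    v = u - np.eye(d)[:, 0]
    v /= np.linalg.norm(v)
    h = np.eye(d) - 2.0 * np.outer(v, v)
    return h[:, 1:]


def _circulant_covariance_from_spectrum(power: np.ndarray) -> np.ndarray:
    """Pixel covariance of a torus-stationary process with DFT power ``power``.

    ``power[f] = E|X_f|^2`` on the ``side x side`` torus; the covariance
    between pixels depends only on their (cyclic) offset and equals the
    inverse DFT of the spectrum.
    """
    side = power.shape[0]
    c = np.fft.ifft2(power).real / (side * side)
    idx = np.arange(side)
    # column-major vectorization: pixel p = (row, col) -> col * side + row
    rows = np.tile(idx, side)
    cols = np.repeat(idx, side)
    dr = (rows[:, None] - rows[None, :]) % side
    dc = (cols[:, None] - cols[None, :]) % side
    return c[dr, dc]


class PatchWhitener(TransformerMixin, BaseEstimator):
    """DC projection followed by symmetric whitening of patch vectors.

    Parameters
    ----------
    regularization : float
        Fraction of the mean AC eigenvalue added to the covariance diagonal
        before the inverse square root; guards nearly degenerate directions
        (the disc data set has some).
    stationary : bool
        If true, estimate the covariance under the assumption that the
        patches are stationary on the square-patch torus: the covariance is
        constrained to be circulant, estimated from the mean DFT power
        spectrum of the training patches.  This is the natural estimator for
        the cyclic-shift data whose generator is torus-stationary by
        construction, and it makes Fourier quadrature planes exactly
        isotropic after whitening.

    Attributes
    ----------
    ac_basis_ : (D, D-1) array, orthonormal, orthogonal to the ones vector.
    whitener_ : (D-1, D-1) symmetric positive definite matrix ``C^{-1/2}``.
    dewhitener_ : its inverse ``C^{1/2}``.
    mean_ : (D,) per-dimension training mean (stored for reference; the
        transform subtracts each patch's own mean and is strictly linear).
    eigenvalues_ : AC covariance eigenvalues (ascending, regularized).
    """

    def __init__(self, regularization: float = 1e-10, stationary: bool = False) -> None:
        self.regularization = regularization
        self.stationary = stationary

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (patches x pixels)")
        n, d = X.shape
        if n < 10 * d:
            raise ValueError(
                f"need at least 10 x {d} = {10 * d} training patches, got {n}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("training patches contain non-finite values")

        basis = ac_basis(d)
        xc = X - X.mean(axis=1, keepdims=True)
        a = xc @ basis

        if self.stationary:
            side = int(round(np.sqrt(d)))
            if side * side != d:
                raise ValueError("stationary covariance estimation needs square patches")
            # column-major vectors: reshape(order='F') restores (row, col)
            frames = xc.reshape(n, side, side, order="F")
            power = np.mean(np.abs(np.fft.fft2(frames, axes=(1, 2))) ** 2, axis=0)
            c_pixel = _circulant_covariance_from_spectrum(power)
            cov = basis.T @ c_pixel @ basis
        else:
            a_mean = a.mean(axis=0)
            ac = a - a_mean
            cov = (ac.T @ ac) / (n - 1)

        evals, evecs = np.linalg.eigh(cov)
        rank_tol = max(evals[-1], 0.0) * 1e-12
        deficient = int(np.sum(evals <= rank_tol))
        if deficient:
            raise ValueError(
                f"AC covariance is rank-deficient: {deficient} eigenvalue(s) at or "
                f"below {rank_tol:.3e}"
            )
        evals = evals + self.regularization * float(np.mean(evals))
        inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
        sqrt_c = (evecs * np.sqrt(evals)) @ evecs.T

        self.n_features_in_ = d
        self.n_components_ = d - 1
        self.ac_basis_ = basis
        self.whitener_ = inv_sqrt
        self.dewhitener_ = sqrt_c
        self.mean_ = X.mean(axis=0)
        self.eigenvalues_ = evals
        return self

    def transform(self, X) -> np.ndarray:
        """Whitened AC coordinates; linear, applied row-wise.

        ``z = C^{-1/2} B^T (x - mean(x))`` with ``B`` the AC basis and the
        per-patch mean subtraction (itself a linear projection).
        """
        check_is_fitted(self, "whitener_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} pixels, got {X.shape[1]}"
            )
        xc = X - X.mean(axis=1, keepdims=True)
        z = xc @ self.ac_basis_ @ self.whitener_
        return z[0] if single else z

    def inverse_transform(self, Z) -> np.ndarray:
        """Back-project whitened coordinates to (zero-mean) pixel space."""
        check_is_fitted(self, "whitener_")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z @ self.dewhitener_ @ self.ac_basis_.T

    def filters_to_pixel_space(self, w: np.ndarray) -> np.ndarray:
        """Pixel-space filters equivalent to whitened-space filters ``w``.

        Rows of ``w`` are filters over whitened coordinates; the returned
        rows ``v`` satisfy ``v^T x = w^T transform(x)`` for every patch ``x``
        and have zero mean (the DC direction was projected out).
        """
        check_is_fitted(self, "whitener_")
        w = np.atleast_2d(np.asarray(w, dtype=float))
        if w.shape[1] != self.n_components_:
            raise ValueError(
                f"expected filters of dimension {self.n_components_}, got {w.shape[1]}"
            )
        return w @ self.whitener_ @ self.ac_basis_.T


def fit_preprocessor(x_all: np.ndarray, **kwargs) -> PatchWhitener:
    """Fit a :class:`PatchWhitener` on training patch vectors."""
    return PatchWhitener(**kwargs).fit(x_all)


def apply_preprocessor(p: PatchWhitener, x: np.ndarray) -> np.ndarray:
    """Apply a fitted whitener to a patch vector or matrix."""
    return p.transform(x)


def filters_to_pixel_space(p: PatchWhitener, w: np.ndarray) -> np.ndarray:
    """Back-project whitened-space filters to pixel space."""
    return p.filters_to_pixel_space(w)
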
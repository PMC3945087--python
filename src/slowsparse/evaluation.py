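"""Analyses of learned filter banks.

Per-subspace inverse slowness and its ordering, amplitude spectra, quadrature
phase statistics, overlap with the Fourier quadrature basis, spatial
localization, and the slowness-sparsity trade-off curve.  All scores that
compare subspaces are invariant to rotations of the two filters within a
subspace and to subspace permutation -- the gauge freedoms of the energy
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ObjectiveSpec,
    SubspaceAnalysis,
    isa_objective,
    ssa_objective,
)
from .optimizer import random_orthonormal

__all__ = [
    "SlownessReport",
    "TradeoffCurve",
    "PhaseDifference",
    "fourier_quadrature_bank",
    "rank_subspaces",
    "amplitude_spectrum",
    "pair_phase_difference",
    "fourier_match_score",
    "subspace_overlap_score",
    "localization_index",
    "tradeoff_curve",
    "build_report",
]


@dataclass
class SlownessReport:
    """Per-subspace evaluation of a learned filter bank."""

    s_by_subspace: np.ndarray  # inverse slowness, sorted ascending
    subspace_order: np.ndarray  # permutation: position -> original subspace index
    phase_differences: np.ndarray | None = None  # radians, in [0, pi], sorted order
    phase_reliable: np.ndarray | None = None
    fourier_match: float | None = None
    localization_index: np.ndarray | None = None  # per filter, sorted order


@dataclass
class TradeoffCurve:
    """Performance against both objectives along the gamma grid."""

    gammas: np.ndarray
    perf_slow: np.ndarray  # percent of the maximal slowness gain
    perf_sparse: np.ndarray  # percent of the maximal sparsity gain
    psi_slow: np.ndarray
    psi_sparse: np.ndarray
    psi_slow_random: float = np.nan  # anchors: the shared random start
    psi_sparse_random: float = np.nan
    break_even_gamma: float | None = None
    w_per_gamma: list[np.ndarray] = field(default_factory=list)
    failed: np.ndarray | None = None


@dataclass
class PhaseDifference:
    """Principal-value phase offset of a filter pair at its shared peak."""

    value: float  # radians in [0, pi]
    reliable: bool


def fourier_quadrature_bank(side: int) -> tuple[np.ndarray, np.ndarray]:
    """Real Fourier quadrature pairs on the ``side x side`` torus.

    Returns ``(filters, freqs)``: ``filters`` has ``side**2 - 1`` rows for odd
    ``side`` (all non-DC frequencies, one representative per conjugate pair),
    column-major pixel vectors, orthonormal; consecutive rows are the cosine
    and sine of one frequency and span one quadrature subspace.  ``freqs``
    holds the integer frequency vector of each subspace.
    """
    reps = []
    seen = set()
    for a in range(side):
        for b in range(side):
            if (a, b) == (0, 0):
                continue
            conj = ((-a) % side, (-b) % side)
            if conj in seen:
                continue
            seen.add((a, b))
            reps.append((a, b))
    rows = []
    freqs = []
    grid_r, grid_c = np.mgrid[0:side, 0:side]
    for a, b in reps:
        phase = 2.0 * np.pi * (a * grid_r + b * grid_c) / side
        cos_f = np.cos(phase)
        sin_f = np.sin(phase)
        sn = np.linalg.norm(sin_f)
        if sn < 1e-9:
            # self-conjugate frequency (even side only): no quadrature partner
            continue
        rows.append(cos_f.ravel(order="F") / np.linalg.norm(cos_f))
        rows.append(sin_f.ravel(order="F") / sn)
        freqs.append((a, b))
    return np.array(rows), np.array(freqs)


def rank_subspaces(
    w: np.ndarray, x_t: np.ndarray, x_t1: np.ndarray, subspace_dim: int = 2
) -> SlownessReport:
    """Sort subspaces by ascending inverse slowness (ties keep original order)."""
    ov = ssa_objective(w, x_t, x_t1, subspace_dim)
    s = ov.per_subspace_slowness
    order = np.argsort(s, kind="stable")
    return SlownessReport(s_by_subspace=s[order], subspace_order=order)


def amplitude_spectrum(filt: np.ndarray, side: int) -> np.ndarray:
    """2-D DFT magnitude of a pixel-space filter, quadrant-shifted (DC central)."""
    filt = np.asarray(filt, dtype=float)
    if filt.size != side * side:
        raise ValueError(f"filter length {filt.size} is not {side}**2")
    frame = filt.reshape(side, side, order="F")
    return np.fft.fftshift(np.abs(np.fft.fft2(frame)))


def pair_phase_difference(
    v1: np.ndarray, v2: np.ndarray, side: int, min_overlap: float = 0.5
) -> PhaseDifference:
    """Phase offset of two filters at their shared dominant frequency.

    The dominant bin is the peak of the product of the two magnitude
    spectra; the result is the absolute principal-value difference of the
    DFT phases there, in ``[0, pi]``.  If either filter's magnitude at the
    shared bin falls below ``min_overlap`` times its own spectral peak the
    estimate is flagged unreliable (the pair does not share a dominant
    frequency) instead of raising.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if not (np.any(v1) and np.any(v2)):
        raise ValueError("filters must be nonzero")
    f1 = np.fft.fft2(v1.reshape(side, side, order="F"))
    f2 = np.fft.fft2(v2.reshape(side, side, order="F"))
    m1, m2 = np.abs(f1), np.abs(f2)
    prod = m1 * m2
    prod[0, 0] = 0.0  # ignore DC
    peak = np.unravel_index(np.argmax(prod), prod.shape)
    reliable = bool(
        m1[peak] >= min_overlap * m1.max() and m2[peak] >= min_overlap * m2.max()
    )
    dphi = np.angle(f1[peak]) - np.angle(f2[peak])
    dphi = abs((dphi + np.pi) % (2.0 * np.pi) - np.pi)
    return PhaseDifference(value=float(dphi), reliable=reliable)


def _orthonormal_pairs(w: np.ndarray, subspace_dim: int = 2) -> list[np.ndarray]:
    """Orthonormal bases (columns) of the row-pair subspaces of ``w``."""
    w = np.atleast_2d(np.asarray(w, dtype=float))
    out = []
    for i in range(0, w.shape[0], subspace_dim):
        q, _ = np.linalg.qr(w[i : i + subspace_dim].T)
        out.append(q)
    return out


def _mean_overlap_matrix(bank_a: list[np.ndarray], bank_b: list[np.ndarray]) -> np.ndarray:
    """Mean squared principal-angle cosines between all subspace pairs."""
    k = bank_a[0].shape[1]
    a = np.stack(bank_a)  # (I, D, k)
    b = np.stack(bank_b)
    cross = np.einsum("idk,jdl->ijkl", a, b)
    return np.sum(cross * cross, axis=(2, 3)) / k


def fourier_match_score(w_pixel: np.ndarray, side: int, subspace_dim: int = 2) -> float:
    """Overlap of a bank's subspaces with the Fourier quadrature subspaces.

    ``w_pixel`` holds pixel-space filters (rows); consecutive pairs form
    subspaces.  For each learned subspace the squared principal-angle
    cosines against every Fourier quadrature plane are averaged and the best
    match taken; the score is the mean over learned subspaces, in [0, 1],
    invariant to within-subspace rotations and subspace permutation.  The
    exact Fourier quadrature bank scores 1.
    """
    fb, _ = fourier_quadrature_bank(side)
    learned = _orthonormal_pairs(w_pixel, subspace_dim)
    fourier = _orthonormal_pairs(fb, subspace_dim)
    overlap = _mean_overlap_matrix(learned, fourier)
    return float(np.mean(np.max(overlap, axis=1)))


def subspace_overlap_score(
    w_pixel_a: np.ndarray, w_pixel_b: np.ndarray, subspace_dim: int = 2
) -> float:
    """Mean best-match subspace overlap between two filter banks (in [0, 1])."""
    a = _orthonormal_pairs(w_pixel_a, subspace_dim)
    b = _orthonormal_pairs(w_pixel_b, subspace_dim)
    overlap = _mean_overlap_matrix(a, b)
    return float(np.mean(np.max(overlap, axis=1)))


def localization_index(filt: np.ndarray, side: int | None = None) -> float:
    """One minus the normalized spatial entropy of the filter's energy map.

    1 for a single-pixel filter, near 0 for a constant-magnitude global
    wave; monotone in how concentrated the filter energy is.
    """
    filt = np.asarray(filt, dtype=float)
    energy = filt * filt
    total = energy.sum()
    if total <= 0:
        raise ValueError("filter must be nonzero")
    p = energy / total
    nz = p[p > 0]
    entropy = -np.sum(nz * np.log(nz))
    return float(1.0 - entropy / np.log(p.size))


def principal_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Canonical angles (radians, ascending) between the column spans of a, b."""
    qa, _ = np.linalg.qr(np.asarray(a, dtype=float))
    qb, _ = np.linalg.qr(np.asarray(b, dtype=float))
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(sv, -1.0, 1.0))[::-1]


def tradeoff_curve(
    x_t: np.ndarray,
    x_t1: np.ndarray,
    gammas: np.ndarray | None = None,
    subspace_dim: int = 2,
    seed: int = 0,
    keep_banks: bool = False,
    warm_start: bool = True,
    **fit_params,
) -> TradeoffCurve:
    """Slowness/sparsity performance along a gamma grid.

    Performance is the achieved gain over a seeded random orthonormal
    initialization, as a percentage of the gain of the pure objective's own
    optimum: ``perf_slow(g) = 100 (Psi_s(W_rand) - Psi_s(W_g)) /
    (Psi_s(W_rand) - Psi_s(W_0)))`` and analogously ``perf_sparse`` against
    the gamma = 1 bank, so both endpoints sit at exactly 100%.  The
    break-even gamma where the two percentage curves cross is located by
    linear interpolation.

    With ``warm_start`` (the default) the grid is swept upward with each
    gamma starting from the previous optimum, then downward from the
    gamma = 1 solution, and for every gamma the bank with the lower mixture
    objective is kept.  Independent cold starts land in different local
    basins of the orthogonal-group landscape, which buries the frontier's
    monotonicity under basin-to-basin scatter; bidirectional continuation
    propagates the best basin found along the grid.  ``warm_start=False``
    optimizes every gamma from the shared random start.
    """
    if gammas is None:
        gammas = np.round(np.arange(0.0, 1.01, 0.1), 10)
    gammas = np.asarray(gammas, dtype=float)
    if gammas[0] != 0.0 or gammas[-1] != 1.0:
        raise ValueError("the gamma grid must include the endpoints 0 and 1")

    d = x_t.shape[1]
    w0 = random_orthonormal(d, seed)
    n_g = len(gammas)
    failed = np.zeros(n_g, dtype=bool)

    def fit_one(g, w_init):
        est = SubspaceAnalysis(
            gamma=float(g), subspace_dim=subspace_dim, init=w_init, **fit_params
        )
        est.fit(x_t, X_next=x_t1)
        return est.components_, est.objective_

    banks = [None] * n_g
    totals = np.full(n_g, np.inf)
    sweeps = [range(n_g)] + ([range(n_g - 1, -1, -1)] if warm_start else [])
    for sweep in sweeps:
        w_init = w0 if not warm_start else None
        for j in sweep:
            start = banks[j] if w_init is None and banks[j] is not None else w_init
            if start is None:
                start = w0
            try:
                w, total = fit_one(gammas[j], start)
            except FloatingPointError:
                failed[j] = True
                continue
            if total < totals[j]:
                banks[j] = w
                totals[j] = total
            if warm_start:
                w_init = banks[j]

    psi_slow = np.full(n_g, np.nan)
    psi_sparse = np.full(n_g, np.nan)
    for j, w in enumerate(banks):
        if w is None:
            failed[j] = True
            banks[j] = w0.copy()
            continue
        psi_slow[j] = ssa_objective(w, x_t, x_t1, subspace_dim).total
        psi_sparse[j] = isa_objective(w, x_t, subspace_dim).total

    slow_rand = ssa_objective(w0, x_t, x_t1, subspace_dim).total
    sparse_rand = isa_objective(w0, x_t, subspace_dim).total
    perf_slow = 100.0 * (slow_rand - psi_slow) / (slow_rand - psi_slow[0])
    perf_sparse = 100.0 * (sparse_rand - psi_sparse) / (sparse_rand - psi_sparse[-1])

    break_even = _crossing(gammas, perf_slow, perf_sparse)
    return TradeoffCurve(
        gammas=gammas,
        perf_slow=perf_slow,
        perf_sparse=perf_sparse,
        psi_slow=psi_slow,
        psi_sparse=psi_sparse,
        psi_slow_random=slow_rand,
        psi_sparse_random=sparse_rand,
        break_even_gamma=break_even,
        w_per_gamma=banks if keep_banks else [],
        failed=failed,
    )


def _crossing(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> float | None:
    """First sign change of a - b, located by linear interpolation."""
    diff = a - b
    ok = np.isfinite(diff)
    x, diff = x[ok], diff[ok]
    for j in range(len(diff) - 1):
        if diff[j] == 0.0:
            return float(x[j])
        if diff[j] * diff[j + 1] < 0:
            t = diff[j] / (diff[j] - diff[j + 1])
            return float(x[j] + t * (x[j + 1] - x[j]))
    if len(diff) and diff[-1] == 0.0:
        return float(x[-1])
    return None


def build_report(
    w: np.ndarray,
    x_t: np.ndarray,
    x_t1: np.ndarray,
    pixel_filters: np.ndarray | None = None,
    side: int | None = None,
    subspace_dim: int = 2,
) -> SlownessReport:
    """Full evaluation of a bank: slowness order plus pixel-space statistics.

    ``pixel_filters`` (rows aligned with ``w``) and ``side`` enable the
    phase, Fourier-match and localization analyses.
    """
    report = rank_subspaces(w, x_t, x_t1, subspace_dim)
    if pixel_filters is not None and side is not None:
        order = report.subspace_order
        phases = np.empty(len(order))
        reliable = np.empty(len(order), dtype=bool)
        loc = np.empty(len(order) * subspace_dim)
        for pos, i in enumerate(order):
            rows = pixel_filters[subspace_dim * i : subspace_dim * (i + 1)]
            pd = pair_phase_difference(rows[0], rows[1], side)
            phases[pos] = pd.value
            reliable[pos] = pd.reliable
            for k in range(subspace_dim):
                loc[pos * subspace_dim + k] = localization_index(rows[k], side)
        report.phase_differences = phases
        report.phase_reliable = reliable
        report.localization_index = loc
        report.fourier_match = fourier_match_score(pixel_filters, side, subspace_dim)
    return report
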
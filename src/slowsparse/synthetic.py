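"""Seeded synthetic stimulus sequences for subspace learning.

Natural-image inputs are emulated with large 1/f ("pink") noise images, the
canonical second-order surrogate for natural scenes.  Time-varying input is
produced by random-walk transformation processes over those images: open-
boundary subpixel translations, exact cyclic (torus) translations of
circulant-covariance pink-noise patches, patch-centered rotations (square
window or disc), patch-centered anisotropic scalings, and a movie surrogate
composing small increments of all three.  Every generator is deterministic
per seed and stores adjacent frame pairs ``(x(t), x(t+1))`` -- the only
signal the temporal objectives consume -- together with the logged walk
increments.

Interpolation is bilinear for the open-boundary generators.  The cyclic
generator shifts in the frequency domain (pure phase multiplication), so
torus translation is exact for any real-valued shift and the power spectrum
of every frame is invariant along the walk; Fourier quadrature pairs are
then an exactly invariant energy representation, which serves as analytic
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "KINDS",
    "SourceImage",
    "TransformProcess",
    "PatchPairSet",
    "DiscMask",
    "disc_mask",
    "make_pink_noise_image",
    "make_circulant_pink_patches",
    "translation_pairs",
    "cyclic_shift_pairs",
    "rotation_pairs",
    "scaling_pairs",
    "movie_surrogate_pairs",
]

KINDS = (
    "translation_open",
    "translation_cyclic",
    "rotation_square",
    "rotation_disc",
    "scaling",
    "movie_surrogate",
)

DEG = np.pi / 180.0


@dataclass
class SourceImage:
    """A large zero-mean grayscale noise image standing in for a photograph."""

    pixels: np.ndarray
    spectral_exponent: float
    seed: int

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TransformProcess:
    """Parameters of a random-walk transformation process.

    ``max_shift`` is the per-axis translation magnitude bound in pixels (the
    per-step displacement magnitude is uniform on ``[0, max_shift]`` with an
    independent random sign per axis).  ``angle_range`` is the per-step
    rotation increment interval in radians, ``scale_factor_range`` the
    per-step multiplicative window-size factor interval per axis.
    """

    kind: str
    n_pairs: int = 50_000
    seed: int = 0
    max_shift: float = 2.0
    angle_range: tuple[float, float] = (-10.0 * DEG, 10.0 * DEG)
    scale_factor_range: tuple[float, float] = (0.95, 1.05)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown process kind {self.kind!r}; expected one of {KINDS}")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        lo, hi = self.scale_factor_range
        if lo <= 0 or hi <= 0:
            raise ValueError("scale_factor_range endpoints must be positive")
        if hi < lo:
            raise ValueError("scale_factor_range must be an interval (lo <= hi)")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class PatchPairSet:
    """Time-adjacent vectorized patch pairs plus generation metadata."""

    x_t: np.ndarray
    x_t1: np.ndarray
    process: TransformProcess
    patch_side: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.x_t.shape != self.x_t1.shape:
            raise ValueError("x_t and x_t1 must have matching shapes")
        if not (np.all(np.isfinite(self.x_t)) and np.all(np.isfinite(self.x_t1))):
            raise ValueError("pair set contains non-finite values")

    @property
    def n_pairs(self) -> int:
        return self.x_t.shape[0]

    @property
    def dim(self) -> int:
        return self.x_t.shape[1]


@dataclass
class DiscMask:
    """The 121 pixels of a ``frame_side x frame_side`` frame closest to its center."""

    frame_side: int
    selected: np.ndarray  # (n, 2) int array of (row, col)

    @property
    def n_pixels(self) -> int:
        return self.selected.shape[0]


def disc_mask(frame_side: int = 14, n_selected: int = 121) -> DiscMask:
    """Select the ``n_selected`` pixels closest to the frame center.

    Ties in distance are broken row-major.  For the default 14x14 / 121
    configuration the cut falls one pixel into a four-pixel distance class,
    so the disc is mirror-symmetric about both frame axes apart from that
    single boundary pixel.
    """
    if n_selected > frame_side * frame_side:
        raise ValueError("cannot select more pixels than the frame holds")
    center = (frame_side - 1) / 2.0
    rr, cc = np.mgrid[0:frame_side, 0:frame_side]
    d2 = (rr - center) ** 2 + (cc - center) ** 2
    flat_order = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
    chosen = flat_order[:n_selected]
    selected = np.column_stack((rr.ravel()[chosen], cc.ravel()[chosen]))
    return DiscMask(frame_side=frame_side, selected=selected)


# ---------------------------------------------------------------------------
# pink noise synthesis


def _pink_amplitudes(height: int, width: int, exponent: float) -> np.ndarray:
    """Deterministic DFT amplitude grid proportional to 1/f**exponent, DC = 0."""
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.rfftfreq(width)[None, :]
    f = np.sqrt(fx * fx + fy * fy)
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** (-exponent), 0.0)
    return amp


def _hermitian_random_phases(
    rng: np.random.Generator, height: int, width: int, n: int | None = None
) -> np.ndarray:
    """Unit-modulus random phases on the rfft2 grid with Hermitian symmetry.

    Entries whose conjugate partner lies inside the half grid (the first
    column, and the Nyquist column for even width) are symmetrized; the four
    possible self-conjugate bins get a random real sign.
    """
    wr = width // 2 + 1
    shape = (height, wr) if n is None else (n, height, wr)
    z = np.exp(2j * np.pi * rng.uniform(0.0, 1.0, size=shape))
    sym_cols = [0] + ([width // 2] if width % 2 == 0 else [])
    half = (height - 1) // 2
    rows = np.arange(1, half + 1)
    for c in sym_cols:
        z[..., height - rows, c] = np.conj(z[..., rows, c])
        z[..., 0, c] = np.sign(z[..., 0, c].real) + 0.0
        if height % 2 == 0:
            z[..., height // 2, c] = np.sign(z[..., height // 2, c].real) + 0.0
    return z


def make_pink_noise_image(
    height: int, width: int, spectral_exponent: float = 1.0, seed: int = 0
) -> SourceImage:
    """Synthesize a 1/f**exponent amplitude-spectrum noise image.

    DFT amplitudes are assigned deterministically (DC amplitude zero), phases
    are uniform with Hermitian symmetry; the image is normalized to unit
    pixel variance and has zero mean by construction.  ``exponent = 0`` gives
    white noise; the default 1 (power spectrum 1/f^2) is the standard
    natural-image surrogate.
    """
    if height <= 0 or width <= 0:
        raise ValueError("image dimensions must be positive")
    if height < 16 or width < 16:
        raise ValueError("image must be at least 16 x 16")
    if not 0.0 <= spectral_exponent <= 3.0:
        raise ValueError("spectral_exponent must lie in [0, 3]")
    rng = np.random.default_rng(seed)
    amp = _pink_amplitudes(height, width, spectral_exponent)
    spectrum = amp * _hermitian_random_phases(rng, height, width)
    img = np.fft.irfft2(spectrum, s=(height, width))
    img /= img.std()
    return SourceImage(pixels=img, spectral_exponent=spectral_exponent, seed=seed)


def make_circulant_pink_patches(n: int, side: int = 11, seed: int = 0) -> np.ndarray:
    """Stationary Gaussian pink-noise patches on the ``side x side`` torus.

    Each patch is an independent draw of a zero-mean Gaussian process that is
    stationary on the torus: independent DFT coefficients with standard
    deviation proportional to 1/f on torus frequencies and zero DC
    (equivalently, white noise filtered with a 1/f amplitude kernel).  The
    ensemble covariance is therefore block-circulant -- left-border pixels
    correlate with right-border pixels as if they were direct neighbors --
    and every patch has exactly zero mean.  Normalized to unit population
    pixel variance.  Returns ``(n, side**2)`` column-major patch vectors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if side < 4:
        raise ValueError("side must be >= 4")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.sqrt(fx * fx + fy * fy)
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, 1.0 / f, 0.0)
    # unit population pixel variance: Var(x_p) = sum_f amp_f^2 / N
    amp *= np.sqrt(side * side / np.sum(amp**2))
    white = rng.standard_normal((n, side, side))
    patches = np.fft.ifft2(np.fft.fft2(white) * amp).real
    return patches.transpose(0, 2, 1).reshape(n, side * side)


# ---------------------------------------------------------------------------
# transformation walks


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the boundaries."""
    span = hi - lo
    if span <= 0:
        return np.full_like(np.asarray(v, dtype=float), lo)
    t = np.mod(np.asarray(v, dtype=float) - lo, 2.0 * span)
    return lo + np.where(t <= span, t, 2.0 * span - t)


def _signed_uniform_steps(
    rng: np.random.Generator, n: int, max_shift: float
) -> np.ndarray:
    """Per-axis displacement: magnitude uniform on [0, max_shift], random sign."""
    mag = rng.uniform(0.0, max_shift, size=(n, 2))
    sign = rng.choice([-1.0, 1.0], size=(n, 2))
    return mag * sign


def _bilinear_frames(pixels: np.ndarray, coords_r: np.ndarray, coords_c: np.ndarray) -> np.ndarray:
    """Sample frames by bilinear interpolation; coords shape (n, h, w)."""
    flat = map_coordinates(
        pixels, [coords_r.ravel(), coords_c.ravel()], order=1, mode="nearest"
    )
    return flat.reshape(coords_r.shape)


def _vectorize_frames(frames: np.ndarray) -> np.ndarray:
    """Column-major vectorization of a stack of square frames."""
    n, h, w = frames.shape
    return frames.transpose(0, 2, 1).reshape(n, h * w)


def translation_pairs(
    image: SourceImage,
    process: TransformProcess,
    patch_side: int = 11,
    steps: np.ndarray | None = None,
    start: tuple[float, float] | None = None,
) -> PatchPairSet:
    """Open-boundary translation walk of a window over the image.

    A two-dimensional random walk of a ``patch_side`` window; per-axis step
    magnitudes are uniform on ``[0, max_shift]`` with random sign, allowing
    subpixel shifts, and the walk reflects at the image borders.  Subpixel
    window contents come from bilinear interpolation.  ``steps`` and
    ``start`` override the random walk (used to cross-check against direct
    crops).
    """
    if process.kind != "translation_open":
        raise ValueError(f"expected kind 'translation_open', got {process.kind!r}")
    h, w = image.height, image.width
    if patch_side > h or patch_side > w:
        raise ValueError("patch larger than source image")
    rng = np.random.default_rng(process.seed)
    n = process.n_pairs
    if steps is None:
        steps = _signed_uniform_steps(rng, n, process.max_shift)
    else:
        steps = np.asarray(steps, dtype=float)
        if steps.shape != (n, 2):
            raise ValueError(f"steps must have shape ({n}, 2)")
    hi_r, hi_c = float(h - patch_side), float(w - patch_side)
    if start is None:
        start = (rng.uniform(0.0, hi_r), rng.uniform(0.0, hi_c))
    positions = np.empty((n + 1, 2))
    positions[0] = start
    for k in range(n):
        positions[k + 1, 0] = _reflect(positions[k, 0] + steps[k, 0], 0.0, hi_r)
        positions[k + 1, 1] = _reflect(positions[k, 1] + steps[k, 1], 0.0, hi_c)

    offs = np.arange(patch_side, dtype=float)
    shape = (n + 1, patch_side, patch_side)
    coords_r = np.broadcast_to(positions[:, 0][:, None, None] + offs[None, :, None], shape)
    coords_c = np.broadcast_to(positions[:, 1][:, None, None] + offs[None, None, :], shape)
    frames = _vectorize_frames(_bilinear_frames(image.pixels, coords_r, coords_c))
    return PatchPairSet(
        x_t=frames[:-1],
        x_t1=frames[1:],
        process=process,
        patch_side=patch_side,
        metadata={"steps": steps, "positions": positions},
    )


def cyclic_shift_pairs(
    patches: np.ndarray,
    process: TransformProcess,
    shifts: np.ndarray | None = None,
) -> PatchPairSet:
    """Exact spectral cyclic shifts of square patches.

    ``x_t1`` is ``x_t`` translated on the torus by a real-valued per-axis
    shift (magnitude uniform on ``[0, max_shift]``, random sign), implemented
    as a pure phase multiplication in the frequency domain, so the DFT
    magnitudes -- and hence Fourier subspace energies -- of each frame are
    preserved exactly.
    """
    if process.kind != "translation_cyclic":
        raise ValueError(f"expected kind 'translation_cyclic', got {process.kind!r}")
    patches = np.asarray(patches, dtype=float)
    n, d = patches.shape
    side = int(round(np.sqrt(d)))
    if side * side != d:
        raise ValueError("patches must be square (side**2 pixels)")
    if n != process.n_pairs:
        raise ValueError(f"process.n_pairs = {process.n_pairs} but got {n} patches")
    rng = np.random.default_rng(process.seed)
    if shifts is None:
        shifts = _signed_uniform_steps(rng, n, process.max_shift)
    else:
        shifts = np.asarray(shifts, dtype=float)
        if shifts.shape != (n, 2):
            raise ValueError(f"shifts must have shape ({n}, 2)")

    frames = patches.reshape(n, side, side, order="F")
    spec = np.fft.fft2(frames)
    f = np.fft.fftfreq(side)
    phase_r = np.exp(-2j * np.pi * f[None, :, None] * shifts[:, 0][:, None, None])
    phase_c = np.exp(-2j * np.pi * f[None, None, :] * shifts[:, 1][:, None, None])
    shifted = np.fft.ifft2(spec * phase_r * phase_c).real
    x_t1 = shifted.transpose(0, 2, 1).reshape(n, d)
    return PatchPairSet(
        x_t=patches,
        x_t1=x_t1,
        process=process,
        patch_side=side,
        metadata={"shifts": shifts},
    )


def _segment_lengths(n_pairs: int, segment_len: int) -> list[int]:
    out = []
    remaining = n_pairs
    while remaining > 0:
        out.append(min(segment_len, remaining))
        remaining -= out[-1]
    return out


def rotation_pairs(
    image: SourceImage,
    process: TransformProcess,
    mask: DiscMask | None = None,
    patch_side: int = 11,
    increments: Iterable[float] | None = None,
    segment_len: int = 50,
) -> PatchPairSet:
    """Patch-centered rotation walks over the image.

    The sampling window rotates about its center pixel by cumulative angle
    increments drawn uniformly from ``angle_range``; frames are bilinear
    resamplings of the source image.  The walk is split into segments, each
    around an independent random center, so the pair set covers the image.
    With ``kind = 'rotation_disc'`` only the 121 disc pixels of a 14x14
    frame are emitted.
    """
    if process.kind not in ("rotation_square", "rotation_disc"):
        raise ValueError(f"expected a rotation kind, got {process.kind!r}")
    if process.kind == "rotation_square" and mask is not None:
        raise ValueError("a disc mask cannot be combined with kind 'rotation_square'")
    if process.kind == "rotation_disc" and mask is None:
        mask = disc_mask()

    if mask is not None:
        frame_side = mask.frame_side
        sel_r, sel_c = mask.selected[:, 0], mask.selected[:, 1]
    else:
        frame_side = patch_side
    center_off = (frame_side - 1) / 2.0
    offs = np.arange(frame_side, dtype=float) - center_off
    oi = np.broadcast_to(offs[:, None], (frame_side, frame_side))
    oj = np.broadcast_to(offs[None, :], (frame_side, frame_side))

    margin = int(np.ceil(center_off * np.sqrt(2.0))) + 2
    h, w = image.height, image.width
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("source image too small for the rotated sampling window")

    rng = np.random.default_rng(process.seed)
    n = process.n_pairs
    if increments is not None:
        increments = np.asarray(list(increments), dtype=float)
        if increments.shape != (n,):
            raise ValueError(f"increments must have shape ({n},)")
    else:
        lo, hi = process.angle_range
        increments = rng.uniform(lo, hi, size=n)

    frames = []
    centers = []
    angles = np.empty(n + len(_segment_lengths(n, segment_len)))
    k = 0
    pos = 0
    for seg in _segment_lengths(n, segment_len):
        cr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        seg_angles = theta + np.concatenate(([0.0], np.cumsum(increments[k : k + seg])))
        for a in seg_angles:
            ca, sa = np.cos(a), np.sin(a)
            rr = cr + ca * oi - sa * oj
            ccs = cc + sa * oi + ca * oj
            frames.append((rr, ccs))
            centers.append((cr, cc))
        angles[pos : pos + seg + 1] = seg_angles
        pos += seg + 1
        k += seg

    coords_r = np.stack([f[0] for f in frames])
    coords_c = np.stack([f[1] for f in frames])
    sampled = _bilinear_frames(image.pixels, coords_r, coords_c)
    if mask is not None:
        vectors = sampled[:, sel_r, sel_c]
    else:
        vectors = _vectorize_frames(sampled)

    x_t_idx, x_t1_idx = _pair_indices(_segment_lengths(n, segment_len))
    return PatchPairSet(
        x_t=vectors[x_t_idx],
        x_t1=vectors[x_t1_idx],
        process=process,
        patch_side=frame_side if mask is None else frame_side,
        metadata={
            "increments": increments,
            "angles": angles,
            "centers": np.asarray(centers),
            "mask": None if mask is None else mask.selected,
        },
    )


def _pair_indices(segment_lengths: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices of (x_t, x_t1) pairs for segment-wise chained frames."""
    i0, i1 = [], []
    base = 0
    for seg in segment_lengths:
        idx = base + np.arange(seg)
        i0.append(idx)
        i1.append(idx + 1)
        base += seg + 1
    return np.concatenate(i0), np.concatenate(i1)


def scaling_pairs(
    image: SourceImage,
    process: TransformProcess,
    patch_side: int = 11,
    factors: np.ndarray | None = None,
    segment_len: int = 50,
) -> PatchPairSet:
    """Patch-centered anisotropic scaling walks.

    The sampling window side performs a multiplicative random walk per axis
    (factors uniform on ``scale_factor_range``, drawn independently for x
    and y), clipped to ``[patch_side, 2 * patch_side]``; each window is
    resampled to ``patch_side x patch_side`` by bilinear interpolation.
    """
    if process.kind != "scaling":
        raise ValueError(f"expected kind 'scaling', got {process.kind!r}")
    lo, hi = process.scale_factor_range
    if hi - lo < 0 or (lo == hi and lo != 1.0 and factors is None):
        raise ValueError("degenerate scale_factor_range")
    rng = np.random.default_rng(process.seed)
    n = process.n_pairs
    if factors is not None:
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (n, 2):
            raise ValueError(f"factors must have shape ({n}, 2)")
        if np.any(factors <= 0):
            raise ValueError("scale factors must be positive")
    else:
        factors = rng.uniform(lo, hi, size=(n, 2))

    s_min, s_max = float(patch_side), float(2 * patch_side)
    margin = int(np.ceil(s_max / 2.0)) + 2
    h, w = image.height, image.width
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("source image too small for the scaled sampling window")

    half = (patch_side - 1) / 2.0
    unit = (np.arange(patch_side, dtype=float) - half) / half  # in [-1, 1]

    seg_lengths = _segment_lengths(n, segment_len)
    n_frames = n + len(seg_lengths)
    coords_r = np.empty((n_frames, patch_side, patch_side))
    coords_c = np.empty((n_frames, patch_side, patch_side))
    sizes = np.empty((n_frames, 2))
    k = 0
    pos = 0
    for seg in seg_lengths:
        cr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        sy, sx = rng.uniform(s_min, s_max, size=2)
        for j in range(seg + 1):
            if j > 0:
                sy = float(np.clip(sy * factors[k + j - 1, 1], s_min, s_max))
                sx = float(np.clip(sx * factors[k + j - 1, 0], s_min, s_max))
            rr = cr + unit[:, None] * (sy - 1.0) / 2.0
            ccs = cc + unit[None, :] * (sx - 1.0) / 2.0
            coords_r[pos + j] = np.broadcast_to(rr, (patch_side, patch_side))
            coords_c[pos + j] = np.broadcast_to(ccs, (patch_side, patch_side))
            sizes[pos + j] = (sy, sx)
        pos += seg + 1
        k += seg

    frames = _vectorize_frames(_bilinear_frames(image.pixels, coords_r, coords_c))
    i0, i1 = _pair_indices(seg_lengths)
    return PatchPairSet(
        x_t=frames[i0],
        x_t1=frames[i1],
        process=process,
        patch_side=patch_side,
        metadata={"factors": factors, "window_sizes": sizes},
    )


def movie_surrogate_pairs(
    image: SourceImage,
    process: TransformProcess,
    patch_side: int = 11,
    segment_len: int = 50,
) -> PatchPairSet:
    """Movie-like sequences composing translation, rotation and scaling.

    Each segment walks a window over a pink-noise scene with small per-step
    translation (bounded by ``max_shift``), rotation (``angle_range``) and
    per-axis scaling (``scale_factor_range``) increments, all logged.  A
    stand-in for natural video whose dominant local transform is translation
    with weaker rotation/zoom components.
    """
    if process.kind != "movie_surrogate":
        raise ValueError(f"expected kind 'movie_surrogate', got {process.kind!r}")
    rng = np.random.default_rng(process.seed)
    n = process.n_pairs

    steps = _signed_uniform_steps(rng, n, process.max_shift)
    lo_a, hi_a = process.angle_range
    dthetas = rng.uniform(lo_a, hi_a, size=n)
    lo_s, hi_s = process.scale_factor_range
    sfactors = rng.uniform(lo_s, hi_s, size=(n, 2))

    half = (patch_side - 1) / 2.0
    unit = (np.arange(patch_side, dtype=float) - half) / half
    s_min, s_max = float(patch_side), float(1.5 * patch_side)
    margin = int(np.ceil(s_max / 2.0 * np.sqrt(2.0))) + 2
    h, w = image.height, image.width
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("source image too small for the movie sampling window")

    seg_lengths = _segment_lengths(n, segment_len)
    n_frames = n + len(seg_lengths)
    coords_r = np.empty((n_frames, patch_side, patch_side))
    coords_c = np.empty((n_frames, patch_side, patch_side))
    k = 0
    pos = 0
    for seg in seg_lengths:
        cr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        sy, sx = rng.uniform(s_min, s_max, size=2)
        for j in range(seg + 1):
            if j > 0:
                cr = float(_reflect(cr + steps[k + j - 1, 0], margin, h - 1 - margin))
                cc = float(_reflect(cc + steps[k + j - 1, 1], margin, w - 1 - margin))
                theta += dthetas[k + j - 1]
                sy = float(np.clip(sy * sfactors[k + j - 1, 1], s_min, s_max))
                sx = float(np.clip(sx * sfactors[k + j - 1, 0], s_min, s_max))
            oi = unit[:, None] * (sy - 1.0) / 2.0
            oj = unit[None, :] * (sx - 1.0) / 2.0
            ca, sa = np.cos(theta), np.sin(theta)
            coords_r[pos + j] = cr + ca * oi - sa * oj
            coords_c[pos + j] = cc + sa * oi + ca * oj
        pos += seg + 1
        k += seg

    frames = _vectorize_frames(_bilinear_frames(image.pixels, coords_r, coords_c))
    i0, i1 = _pair_indices(seg_lengths)
    return PatchPairSet(
        x_t=frames[i0],
        x_t1=frames[i1],
        process=process,
        patch_side=patch_side,
        metadata={"steps": steps, "angle_increments": dthetas, "scale_factors": sfactors},
    )
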
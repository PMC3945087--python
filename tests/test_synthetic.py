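"""Stimulus generator contracts: spectra, exactness oracles, determinism."""

import numpy as np
import pytest

import slowsparse as sp
from slowsparse.synthetic import disc_mask


def radial_log_slope(image: np.ndarray) -> float:
    """Log-log slope of the radially averaged amplitude spectrum."""
    h, w = image.shape
    amp = np.abs(np.fft.fft2(image))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.sqrt(fx * fx + fy * fy).ravel()
    a = amp.ravel()
    # mid-frequency band, away from DC and Nyquist
    sel = (f > 0.03) & (f < 0.3)
    bins = np.linspace(np.log(0.03), np.log(0.3), 24)
    idx = np.digitize(np.log(f[sel]), bins)
    xs, ys = [], []
    for b in range(1, len(bins)):
        m = idx == b
        if m.sum() > 10:
            xs.append(np.log(f[sel][m]).mean())
            ys.append(np.log(a[sel][m].mean()))
    return float(np.polyfit(xs, ys, 1)[0])


class TestPinkNoiseImage:
    def test_pink_spectrum_slope(self):
        img = sp.make_pink_noise_image(256, 256, 1.0, seed=3)
        assert abs(radial_log_slope(img.pixels) + 1.0) < 0.15

    def test_white_noise_flat_spectrum(self):
        img = sp.make_pink_noise_image(256, 256, 0.0, seed=3)
        assert abs(radial_log_slope(img.pixels)) < 0.1

    def test_zero_mean_unit_variance(self):
        img = sp.make_pink_noise_image(64, 64, 1.0, seed=0)
        assert abs(img.pixels.mean()) < 1e-9 * img.pixels.std()
        assert np.isclose(img.pixels.std(), 1.0)

    def test_deterministic(self):
        a = sp.make_pink_noise_image(64, 64, 1.0, seed=9)
        b = sp.make_pink_noise_image(64, 64, 1.0, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("h,w", [(0, 64), (64, -3), (8, 64)])
    def test_bad_dimensions(self, h, w):
        with pytest.raises(ValueError):
            sp.make_pink_noise_image(h, w, 1.0, seed=0)


class TestCirculantPatches:
    def test_per_patch_mean_zero(self):
        p = sp.make_circulant_pink_patches(200, 11, seed=1)
        assert np.abs(p.mean(axis=1)).max() < 1e-12

    def test_wraparound_correlation(self):
        # left border correlates with right border like direct neighbors
        p = sp.make_circulant_pink_patches(60_000, 11, seed=2)
        frames = p.reshape(-1, 11, 11, order="F")
        col0, col1, col10 = frames[:, :, 0], frames[:, :, 1], frames[:, :, 10]
        corr_neighbor = np.corrcoef(col0.ravel(), col1.ravel())[0, 1]
        corr_wrap = np.corrcoef(col0.ravel(), col10.ravel())[0, 1]
        assert abs(corr_neighbor - corr_wrap) < 0.02

    def test_block_circulant_covariance(self):
        # covariance entries related by a torus shift agree within sampling error
        side, n = 7, 60_000
        p = sp.make_circulant_pink_patches(n, side, seed=3)
        cov = (p.T @ p) / n
        d = side * side
        rows = np.arange(d) % side
        cols = np.arange(d) // side
        groups: dict[tuple[int, int], list[float]] = {}
        for i in range(d):
            for j in range(d):
                key = ((rows[i] - rows[j]) % side, (cols[i] - cols[j]) % side)
                groups.setdefault(key, []).append(cov[i, j])
        se = 3.0 / np.sqrt(n)
        spread = max(np.ptp(v) for v in groups.values())
        assert spread < 3 * se

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            sp.make_circulant_pink_patches(0, 11)


class TestTranslationPairs:
    def test_zero_shift_identity(self, small_image):
        proc = sp.TransformProcess(
            kind="translation_open", n_pairs=50, seed=1, max_shift=0.0
        )
        pairs = sp.translation_pairs(small_image, proc, 9)
        np.testing.assert_allclose(pairs.x_t, pairs.x_t1)

    def test_integer_shift_matches_direct_crop(self, small_image):
        proc = sp.TransformProcess(
            kind="translation_open", n_pairs=1, seed=1, max_shift=2.0
        )
        pairs = sp.translation_pairs(
            small_image, proc, 9, steps=np.array([[1.0, 0.0]]), start=(20.0, 30.0)
        )
        crop0 = small_image.pixels[20:29, 30:39]
        crop1 = small_image.pixels[21:30, 30:39]
        np.testing.assert_array_equal(pairs.x_t[0], crop0.ravel(order="F"))
        np.testing.assert_array_equal(pairs.x_t1[0], crop1.ravel(order="F"))

    def test_step_magnitudes_bounded(self, small_image):
        proc = sp.TransformProcess(
            kind="translation_open", n_pairs=500, seed=2, max_shift=2.0
        )
        pairs = sp.translation_pairs(small_image, proc, 11)
        assert np.abs(pairs.metadata["steps"]).max() <= 2.0

    def test_patch_larger_than_image(self, small_image):
        proc = sp.TransformProcess(kind="translation_open", n_pairs=5, seed=0)
        with pytest.raises(ValueError):
            sp.translation_pairs(small_image, proc, 1000)


class TestCyclicShiftPairs:
    def test_zero_shift_identity(self):
        p = sp.make_circulant_pink_patches(20, 9, seed=4)
        proc = sp.TransformProcess(kind="translation_cyclic", n_pairs=20, seed=0)
        pairs = sp.cyclic_shift_pairs(p, proc, shifts=np.zeros((20, 2)))
        np.testing.assert_allclose(pairs.x_t1, pairs.x_t, atol=1e-12)

    def test_full_wrap_identity(self):
        p = sp.make_circulant_pink_patches(20, 9, seed=4)
        proc = sp.TransformProcess(kind="translation_cyclic", n_pairs=20, seed=0)
        pairs = sp.cyclic_shift_pairs(p, proc, shifts=np.full((20, 2), 9.0))
        np.testing.assert_allclose(pairs.x_t1, pairs.x_t, atol=1e-10)

    def test_subpixel_shift_preserves_spectrum(self):
        p = sp.make_circulant_pink_patches(50, 11, seed=5)
        proc = sp.TransformProcess(
            kind="translation_cyclic", n_pairs=50, seed=6, max_shift=2.0
        )
        pairs = sp.cyclic_shift_pairs(p, proc)
        f0 = np.abs(np.fft.fft2(pairs.x_t.reshape(-1, 11, 11, order="F")))
        f1 = np.abs(np.fft.fft2(pairs.x_t1.reshape(-1, 11, 11, order="F")))
        assert np.max(np.abs(f0 - f1)) < 1e-10 * np.max(f0)

    def test_non_square_rejected(self):
        proc = sp.TransformProcess(kind="translation_cyclic", n_pairs=3, seed=0)
        with pytest.raises(ValueError):
            sp.cyclic_shift_pairs(np.zeros((3, 10)), proc)


class TestRotationPairs:
    def test_zero_increment_identity(self, small_image):
        proc = sp.TransformProcess(
            kind="rotation_square", n_pairs=40, seed=1, angle_range=(0.0, 0.0)
        )
        pairs = sp.rotation_pairs(small_image, proc, patch_side=11)
        np.testing.assert_allclose(pairs.x_t1, pairs.x_t, atol=1e-12)

    def test_full_turn_identity(self, small_image):
        proc = sp.TransformProcess(kind="rotation_square", n_pairs=1, seed=2)
        pairs = sp.rotation_pairs(
            small_image, proc, patch_side=11, increments=[2.0 * np.pi]
        )
        np.testing.assert_allclose(pairs.x_t1, pairs.x_t, atol=1e-10)

    def test_disc_emits_121_values(self, small_image):
        proc = sp.TransformProcess(kind="rotation_disc", n_pairs=30, seed=3)
        pairs = sp.rotation_pairs(small_image, proc)
        assert pairs.x_t.shape[1] == 121

    def test_mask_with_square_kind_rejected(self, small_image):
        proc = sp.TransformProcess(kind="rotation_square", n_pairs=5, seed=0)
        with pytest.raises(ValueError):
            sp.rotation_pairs(small_image, proc, mask=disc_mask())


class TestDiscMask:
    def test_exactly_121_pixels(self):
        assert disc_mask().n_pixels == 121

    def test_symmetric_up_to_boundary_tie(self):
        # the 121st pixel splits a 4-pixel distance class; the rest of the
        # selection is mirror-symmetric about both frame axes
        m = disc_mask()
        grid = np.zeros((14, 14), dtype=bool)
        grid[m.selected[:, 0], m.selected[:, 1]] = True
        center = 6.5
        d2 = (m.selected[:, 0] - center) ** 2 + (m.selected[:, 1] - center) ** 2
        boundary = np.isclose(d2, d2.max())
        assert boundary.sum() == 1
        inner = np.zeros((14, 14), dtype=bool)
        keep = m.selected[~boundary]
        inner[keep[:, 0], keep[:, 1]] = True
        assert np.array_equal(inner, inner[::-1, :])
        assert np.array_equal(inner, inner[:, ::-1])


class TestScalingPairs:
    def test_unit_factors_identity(self, small_image):
        proc = sp.TransformProcess(
            kind="scaling", n_pairs=40, seed=1, scale_factor_range=(1.0, 1.0)
        )
        pairs = sp.scaling_pairs(
            small_image, proc, 11, factors=np.ones((40, 2))
        )
        np.testing.assert_allclose(pairs.x_t1, pairs.x_t, atol=1e-12)

    def test_bilinear_preserves_affine_ramp(self):
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        ramp = sp.SourceImage(
            pixels=0.3 * yy - 0.7 * xx + 2.0, spectral_exponent=0.0, seed=0
        )
        proc = sp.TransformProcess(kind="scaling", n_pairs=30, seed=2)
        pairs = sp.scaling_pairs(ramp, proc, 11)
        for frame in pairs.x_t1.reshape(-1, 11, 11, order="F"):
            row_d = np.diff(frame, axis=0)
            col_d = np.diff(frame, axis=1)
            assert np.allclose(row_d, row_d[0, 0], atol=1e-9)
            assert np.allclose(col_d, col_d[0, 0], atol=1e-9)

    def test_independent_axis_factors_logged(self, small_image):
        proc = sp.TransformProcess(kind="scaling", n_pairs=200, seed=3)
        pairs = sp.scaling_pairs(small_image, proc, 11)
        factors = pairs.metadata["factors"]
        assert factors.shape == (200, 2)
        assert not np.allclose(factors[:, 0], factors[:, 1])


class TestMovieSurrogate:
    def test_zero_increments_identity(self, small_image):
        proc = sp.TransformProcess(
            kind="movie_surrogate",
            n_pairs=30,
            seed=1,
            max_shift=0.0,
            angle_range=(0.0, 0.0),
            scale_factor_range=(1.0, 1.0),
        )
        pairs = sp.movie_surrogate_pairs(small_image, proc, 11)
        np.testing.assert_allclose(pairs.x_t1, pairs.x_t, atol=1e-12)


def _generate(kind, image, n=30, seed=13):
    proc = sp.TransformProcess(kind=kind, n_pairs=n, seed=seed, max_shift=1.5)
    if kind == "translation_open":
        return sp.translation_pairs(image, proc, 9)
    if kind == "translation_cyclic":
        patches = sp.make_circulant_pink_patches(n, 9, seed=seed)
        return sp.cyclic_shift_pairs(patches, proc)
    if kind == "rotation_square":
        return sp.rotation_pairs(image, proc, patch_side=9)
    if kind == "rotation_disc":
        return sp.rotation_pairs(image, proc)
    if kind == "scaling":
        return sp.scaling_pairs(image, proc, 9)
    return sp.movie_surrogate_pairs(image, proc, 9)


@pytest.mark.parametrize("kind", sp.KINDS)
def test_generators_deterministic_and_finite(kind, small_image):
    a = _generate(kind, small_image)
    b = _generate(kind, small_image)
    np.testing.assert_array_equal(a.x_t, b.x_t)
    np.testing.assert_array_equal(a.x_t1, b.x_t1)
    assert np.all(np.isfinite(a.x_t)) and np.all(np.isfinite(a.x_t1))


def test_process_validation():
    with pytest.raises(ValueError):
        sp.TransformProcess(kind="translation_open", n_pairs=0)
    with pytest.raises(ValueError):
        sp.TransformProcess(kind="translation_open", max_shift=-1.0)
    with pytest.raises(ValueError):
        sp.TransformProcess(kind="scaling", scale_factor_range=(-0.5, 1.0))
    with pytest.raises(ValueError):
        sp.TransformProcess(kind="nonsense")
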
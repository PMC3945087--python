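"""Objective and gradient contracts of the subspace-energy model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import slowsparse as sp
from slowsparse.evaluation import fourier_quadrature_bank
from slowsparse.model import ObjectiveSpec, mixed_objective
from slowsparse.preprocessing import ac_basis


def finite_difference_gradient(fun, w, eps=1e-6):
    g = np.zeros_like(w)
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            wp, wm = w.copy(), w.copy()
            wp[i, j] += eps
            wm[i, j] -= eps
            g[i, j] = (fun(wp) - fun(wm)) / (2 * eps)
    return g


class TestSubspaceEnergies:
    def test_zero_input(self):
        w = sp.random_orthonormal(6, 0)
        y = sp.subspace_energies(w, np.zeros((4, 6)))
        np.testing.assert_array_equal(y, np.zeros((4, 3)))

    def test_energy_conservation(self, rng):
        w = sp.random_orthonormal(12, 1)
        x = rng.standard_normal((50, 12))
        y = sp.subspace_energies(w, x)
        np.testing.assert_allclose(y.sum(axis=1), (x**2).sum(axis=1), atol=1e-10)
        assert np.all(y >= 0)

    def test_fourier_quadrature_bank_outputs_power_spectrum(self, rng):
        # with DFT quadrature pair filters the energies are the power
        # spectrum of the input (up to the filters' unit normalization)
        side = 7
        fb, freqs = fourier_quadrature_bank(side)
        b = ac_basis(side * side)
        w = fb @ b  # square, orthonormal, acting on AC coordinates
        patch = rng.standard_normal((side, side))
        patch -= patch.mean()
        z = patch.ravel(order="F") @ b
        y = sp.subspace_energies(w, z[None, :])[0]
        power = np.abs(np.fft.fft2(patch)) ** 2
        expected = np.array([power[a, b_] for a, b_ in freqs]) * 2.0 / (side * side)
        np.testing.assert_allclose(y, expected, rtol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            sp.subspace_energies(sp.random_orthonormal(6, 0), np.zeros((4, 8)))


class TestSsaObjective:
    def test_constant_sequence_is_zero(self, rng):
        w = sp.random_orthonormal(8, 2)
        x = rng.standard_normal((30, 8))
        assert sp.ssa_objective(w, x, x).total == 0.0

    def test_hand_computed_single_pair(self):
        # one subspace, energies 1 -> 4, squared difference 9
        ov = sp.ssa_objective(np.eye(2), [[1.0, 0.0]], [[0.0, 2.0]])
        assert ov.total == 9.0
        np.testing.assert_array_equal(ov.per_subspace_slowness, [9.0])

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            sp.ssa_objective(np.eye(2), np.empty((0, 2)), np.empty((0, 2)))

    def test_decomposition_consistency(self, rng):
        w = sp.random_orthonormal(10, 3)
        x0, x1 = rng.standard_normal((2, 40, 10))
        ov = sp.ssa_objective(w, x0, x1)
        assert np.isclose(ov.total, ov.per_subspace_slowness.mean())
        assert ov.total >= 0


class TestIsaObjective:
    def test_zero_input(self):
        assert sp.isa_objective(np.eye(4), np.zeros((5, 4))).total == 0.0

    def test_hand_computed(self):
        # energies 1 and 4 -> mean sqrt = (1 + 2) / 2
        ov = sp.isa_objective(np.eye(2), [[1.0, 0.0], [0.0, 2.0]])
        assert ov.total == 1.5

    def test_heavy_tail_is_sparser(self, rng):
        # equal mean energy, heavier tail -> smaller mean subspace norm
        w = np.eye(2)
        light = np.column_stack([np.ones(1000), np.zeros(1000)])
        heavy_r = rng.pareto(3.0, 1000) + 0.1
        heavy_r *= np.sqrt(1000 / np.sum(heavy_r**2))
        heavy = np.column_stack([heavy_r, np.zeros(1000)])
        assert np.isclose((light**2).sum(), (heavy**2).sum())
        assert sp.isa_objective(w, heavy).total < sp.isa_objective(w, light).total


class TestGradients:
    @pytest.mark.parametrize("draw", range(5))
    def test_ssa_gradient_matches_finite_differences(self, draw, rng):
        d = int(rng.integers(2, 5)) * 2
        w = sp.random_orthonormal(d, draw)
        x0, x1 = rng.standard_normal((2, 25, d))
        g = sp.ssa_gradient(w, x0, x1)
        g_fd = finite_difference_gradient(lambda m: sp.ssa_objective(m, x0, x1).total, w)
        assert np.abs(g - g_fd).max() < 1e-5 * max(np.abs(g_fd).max(), 1.0)

    @pytest.mark.parametrize("draw", range(5))
    def test_isa_gradient_matches_finite_differences(self, draw, rng):
        d = int(rng.integers(2, 5)) * 2
        w = sp.random_orthonormal(d, 100 + draw)
        x = rng.standard_normal((25, d)) + 0.5  # keep energies away from 0
        g = sp.isa_gradient(w, x)
        g_fd = finite_difference_gradient(lambda m: sp.isa_objective(m, x).total, w)
        assert np.abs(g - g_fd).max() < 1e-5 * max(np.abs(g_fd).max(), 1.0)

    def test_ssa_gradient_zero_on_constant_sequence(self, rng):
        w = sp.random_orthonormal(6, 0)
        x = rng.standard_normal((20, 6))
        np.testing.assert_allclose(sp.ssa_gradient(w, x, x), 0.0, atol=1e-12)

    def test_isa_zero_samples_guarded(self):
        g = sp.isa_gradient(np.eye(4), np.zeros((10, 4)))
        assert np.all(np.isfinite(g))
        np.testing.assert_allclose(g, 0.0)

    def test_isa_gradient_homogeneity(self, rng):
        # sqrt(y) is degree-1 homogeneous in x: scaling data scales gradient
        w = sp.random_orthonormal(6, 1)
        x = rng.standard_normal((30, 6)) + 0.3
        np.testing.assert_allclose(
            sp.isa_gradient(w, 2.0 * x), 2.0 * sp.isa_gradient(w, x), rtol=1e-9
        )


def whitened_fourier_bank(pw, side):
    """Fourier quadrature bank expressed in whitened coordinates.

    Rows are normalized so the bank is orthonormal; with stationary
    whitening the normalization is uniform within each quadrature pair, so
    subspace energies remain exactly shift-invariant.
    """
    fb, _ = fourier_quadrature_bank(side)
    w = (fb @ pw.ac_basis_) @ pw.dewhitener_
    return w / np.linalg.norm(w, axis=1, keepdims=True)


@pytest.fixture(scope="module")
def cyclic_small():
    side, n = 5, 1500
    patches = sp.make_circulant_pink_patches(n, side, seed=17)
    proc = sp.TransformProcess(
        kind="translation_cyclic", n_pairs=n, seed=18, max_shift=2.0
    )
    pairs = sp.cyclic_shift_pairs(patches, proc)
    pw = sp.PatchWhitener(stationary=True).fit(pairs.x_t)
    return side, pw, pw.transform(pairs.x_t), pw.transform(pairs.x_t1)


class TestFourierOptimum:
    def test_fourier_bank_reaches_zero_objective(self, cyclic_small):
        side, pw, z0, z1 = cyclic_small
        w = whitened_fourier_bank(pw, side)
        d = side * side - 1
        np.testing.assert_allclose(w @ w.T, np.eye(d), atol=1e-8)
        scale = np.mean(np.sum(z0**2, axis=1) ** 2)
        assert sp.ssa_objective(w, z0, z1).total <= 1e-10 * scale

    def test_tangent_gradient_vanishes_at_optimum(self, cyclic_small):
        side, pw, z0, z1 = cyclic_small
        w = whitened_fourier_bank(pw, side)
        g = sp.ssa_gradient(w, z0, z1)
        skew = 0.5 * (w @ g.T - g @ w.T)  # tangent component in Lie coordinates
        assert np.linalg.norm(skew) < 1e-6


class TestMixedObjective:
    def test_gamma_zero_is_ssa_bitexact(self, rng):
        w = sp.random_orthonormal(8, 0)
        x0, x1 = rng.standard_normal((2, 30, 8))
        mixed = mixed_objective(w, x0, x1, ObjectiveSpec(gamma=0.0))
        assert mixed.total == sp.ssa_objective(w, x0, x1).total

    def test_gamma_one_is_isa_bitexact(self, rng):
        w = sp.random_orthonormal(8, 0)
        x0, x1 = rng.standard_normal((2, 30, 8))
        mixed = mixed_objective(w, x0, x1, ObjectiveSpec(gamma=1.0))
        assert mixed.total == sp.isa_objective(w, x0).total

    def test_half_mixture_combination(self, rng):
        w = sp.random_orthonormal(8, 1)
        x0, x1 = rng.standard_normal((2, 30, 8))
        mixed = mixed_objective(w, x0, x1, ObjectiveSpec(gamma=0.5))
        expected = 0.5 * sp.ssa_objective(w, x0, x1).total + 0.5 * sp.isa_objective(w, x0).total
        assert abs(mixed.total - expected) < 1e-14

    def test_gamma_out_of_range(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(gamma=1.5)

    def test_mixed_gradient_matches_finite_differences(self, rng):
        w = sp.random_orthonormal(6, 2)
        x0 = rng.standard_normal((25, 6)) + 0.4
        x1 = rng.standard_normal((25, 6)) + 0.4
        spec = ObjectiveSpec(gamma=0.3)
        _, g = mixed_objective(w, x0, x1, spec, with_gradient=True)
        g_fd = finite_difference_gradient(
            lambda m: mixed_objective(m, x0, x1, spec).total, w
        )
        assert np.abs(g - g_fd).max() < 1e-5 * np.abs(g_fd).max()


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), angle=st.floats(0.0, 2 * np.pi))
def test_within_subspace_rotation_gauge_invariance(seed, angle):
    """Rotating the two filters of one subspace leaves all outputs unchanged."""
    rng = np.random.default_rng(seed)
    w = sp.random_orthonormal(6, seed)
    x0 = rng.standard_normal((20, 6))
    x1 = rng.standard_normal((20, 6))
    rot = np.eye(6)
    c, s = np.cos(angle), np.sin(angle)
    rot[2:4, 2:4] = [[c, -s], [s, c]]
    w_rot = rot @ w
    np.testing.assert_allclose(
        sp.subspace_energies(w_rot, x0), sp.subspace_energies(w, x0), atol=1e-10
    )
    assert abs(sp.ssa_objective(w_rot, x0, x1).total - sp.ssa_objective(w, x0, x1).total) < 1e-10
    assert abs(sp.isa_objective(w_rot, x0).total - sp.isa_objective(w, x0).total) < 1e-10


class TestEstimator:
    def test_fit_requires_pairs_unless_pure_isa(self, rng):
        x = rng.standard_normal((50, 6))
        with pytest.raises(ValueError, match="X_next"):
            sp.SubspaceAnalysis(gamma=0.5).fit(x)
        est = sp.IndependentSubspaceAnalysis(max_iter=5).fit(x)
        assert est.components_.shape == (6, 6)

    def test_fit_attributes_and_transform(self, small_whitened):
        _, z0, z1 = small_whitened
        est = sp.SlowSubspaceAnalysis(random_state=0, max_iter=30)
        est.fit(z0, X_next=z1)
        d = z0.shape[1]
        assert est.components_.shape == (d, d)
        np.testing.assert_allclose(
            est.components_ @ est.components_.T, np.eye(d), atol=1e-8
        )
        y = est.transform(z0[:7])
        assert y.shape == (7, d // 2)
        assert est.objective_ < est.trace_.objective_per_iteration[0]

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = sp.SubspaceAnalysis(gamma=0.25, max_iter=10)
        est2 = clone(est)
        assert est2.gamma == 0.25 and est2.max_iter == 10
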
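"""Shared fixtures.

The expensive trained banks (full 120-dimensional runs) are session-scoped
and shared between the evaluation-level tests so each is trained once.
"""

from __future__ import annotations

import numpy as np
import pytest

import slowsparse as sp
from slowsparse import experiments


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140306)


@pytest.fixture(scope="session")
def small_image():
    return sp.make_pink_noise_image(128, 128, 1.0, seed=5)


@pytest.fixture(scope="session")
def small_translation_pairs(small_image):
    process = sp.TransformProcess(
        kind="translation_open", n_pairs=2000, seed=7, max_shift=2.0
    )
    return sp.translation_pairs(small_image, process, patch_side=7)


@pytest.fixture(scope="session")
def small_whitened(small_translation_pairs):
    pw = sp.PatchWhitener().fit(small_translation_pairs.x_t)
    return (
        pw,
        pw.transform(small_translation_pairs.x_t),
        pw.transform(small_translation_pairs.x_t1),
    )


# ---------------------------------------------------------------------------
# full-scale trained banks shared by the acceptance suite


@pytest.fixture(scope="session")
def cyclic_recovery():
    """SSA on 20k circulant pink-noise pairs with exact cyclic shifts (D=120)."""
    return experiments.cyclic_fourier_recovery(seed=11)


@pytest.fixture(scope="session")
def translation_whitened():
    """Whitened translation pairs plus a held-out set in the same coordinates."""
    whitener, z_t, z_t1, pairs = experiments.translation_data(seed=21, n_pairs=20_000)
    image = sp.make_pink_noise_image(512, 512, 1.0, seed=31)
    process = sp.TransformProcess(
        kind="translation_open", n_pairs=5_000, seed=32, max_shift=2.0
    )
    held = sp.translation_pairs(image, process, 11)
    return {
        "whitener": whitener,
        "z_t": z_t,
        "z_t1": z_t1,
        "held_z_t": whitener.transform(held.x_t),
        "held_z_t1": whitener.transform(held.x_t1),
    }


@pytest.fixture(scope="session")
def ssa_translation_bank(translation_whitened):
    est = sp.SlowSubspaceAnalysis(
        random_state=41, max_iter=600, tol=1e-10, max_backtracks=40
    )
    est.fit(translation_whitened["z_t"], X_next=translation_whitened["z_t1"])
    return est


@pytest.fixture(scope="session")
def isa_translation_bank(translation_whitened):
    est = sp.IndependentSubspaceAnalysis(
        random_state=41, max_iter=600, tol=1e-10, max_backtracks=40
    )
    est.fit(translation_whitened["z_t"], X_next=translation_whitened["z_t1"])
    return est
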
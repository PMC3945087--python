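"""Model complex cells from quadratic slow feature analysis, probed with
spike-triggered covariance.

Instead of prescribing two-dimensional invariant subspaces, slow feature
analysis (SFA) on the full quadratic feature space of a low-dimensional
stimulus representation learns quadratic forms whose outputs change as
slowly as possible; the rank structure of those forms is then free.  Each
learned form is turned into a pair of Poisson model neurons by a median
split of its responses to white noise (excitatory rates from responses above
the median, inhibitory rates from the magnitude of responses below), and the
spike-triggered covariance (STC) of the resulting spike trains is
eigen-analyzed.  Significance of each eigenvalue rank is assessed against
spike-count shuffles at a mean +/- z * SD band (z = 4.4 by default, a
Bonferroni-style confidence band for Gaussian-distributed eigenvalues).

The contrast of interest: a planted rank-2 energy-model neuron shows exactly
two significant excitatory eigenvalues, whereas an SFA-derived quadratic
form driven by translating inputs spreads significance over most stimulus
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "QuadraticNeuron",
    "StcResult",
    "quadratic_expansion",
    "QuadraticSFA",
    "sfa_quadratic",
    "neuron_rates",
    "poisson_counts",
    "stc_matrix",
    "significance_count",
    "nested_significance_count",
    "neuron_significance",
]


@dataclass
class QuadraticNeuron:
    """A quadratic-form response unit ``r(z) = z^T Q z + linear^T z + const``."""

    Q: np.ndarray
    linear: np.ndarray
    const: float = 0.0
    rate_scale: float | None = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if not np.allclose(self.Q, self.Q.T, atol=1e-12):
            raise ValueError("Q must be symmetric")
        self.linear = np.asarray(self.linear, dtype=float)

    def response(self, stimuli: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(stimuli, dtype=float))
        quad = np.einsum("ni,ij,nj->n", s, self.Q, s)
        return quad + s @ self.linear + self.const


@dataclass
class StcResult:
    """STC eigen-spectrum with its shuffle-based significance band."""

    eigenvalues: np.ndarray  # ascending
    shuffle_mean: np.ndarray
    shuffle_sd: np.ndarray
    n_sig_excitatory: int  # eigenvalues above the band
    n_sig_inhibitory: int  # eigenvalues below the band
    z_threshold: float


def quadratic_expansion(z: np.ndarray) -> np.ndarray:
    """All degree-2 monomials ``z_a z_b`` (a <= b) followed by the linear terms.

    For ``n`` coordinates the feature vector has length ``n(n+1)/2 + n``;
    for n = 2 the ordering is ``(z1^2, z1 z2, z2^2, z1, z2)``.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    z = np.atleast_2d(z)
    n = z.shape[1]
    if n < 2:
        raise ValueError("need at least 2 stimulus coordinates")
    iu, ju = np.triu_indices(n)
    order = np.lexsort((ju, iu))  # row-major over (a, b), a <= b
    quad = z[:, iu[order]] * z[:, ju[order]]
    feats = np.concatenate([quad, z], axis=1)
    return feats[0] if single else feats


class QuadraticSFA(TransformerMixin, BaseEstimator):
    """Slow feature analysis on the quadratic expansion of the stimulus.

    Features are expanded, centered on the training mean and whitened; the
    slow components are the bottom eigenvectors of the temporal-difference
    covariance in the whitened feature space (unit variance, mutually
    uncorrelated on the training data by construction).  Each component maps
    back to a :class:`QuadraticNeuron` over the raw stimulus coordinates.

    Attributes
    ----------
    neurons_ : list[QuadraticNeuron]
        Slowest-first quadratic forms.
    delta_values_ : (n_components,) ascending temporal-difference variances.
    """

    def __init__(self, n_components: int = 16, regularization: float = 1e-10) -> None:
        self.n_components = n_components
        self.regularization = regularization

    def fit(self, X, y=None, X_next=None):
        if X_next is None:
            raise ValueError("X_next (adjacent frames) is required")
        z0 = np.asarray(X, dtype=float)
        z1 = np.asarray(X_next, dtype=float)
        if z0.shape != z1.shape:
            raise ValueError("X and X_next must have the same shape")
        f0 = quadratic_expansion(z0)
        f1 = quadratic_expansion(z1)
        n, m = f0.shape
        if n < 2 * m:
            raise ValueError(
                f"need well over {m} pairs for a {m}-dimensional feature space, got {n}"
            )
        mean = f0.mean(axis=0)
        f0c = f0 - mean
        f1c = f1 - mean

        cov = (f0c.T @ f0c) / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        rank_tol = max(evals[-1], 0.0) * 1e-10
        deficient = int(np.sum(evals <= rank_tol))
        if deficient:
            raise ValueError(
                f"feature covariance is rank-deficient: {deficient} eigenvalue(s) at "
                f"or below {rank_tol:.3e}"
            )
        evals = evals + self.regularization * float(np.mean(evals))
        # PCA whitening map: g = (f - mean) @ white.T
        white = (evecs / np.sqrt(evals)).T

        g0 = f0c @ white.T
        g1 = f1c @ white.T
        diff = g1 - g0
        dcov = (diff.T @ diff) / n
        dvals, dvecs = np.linalg.eigh(dcov)

        k = min(self.n_components, m)
        comps = dvecs[:, :k]  # slowest first
        coef = white.T @ comps  # feature-space coefficient vectors, (m, k)

        d = z0.shape[1]
        iu, ju = np.triu_indices(d)
        order = np.lexsort((ju, iu))
        iu, ju = iu[order], ju[order]
        neurons = []
        for j in range(k):
            c = coef[:, j]
            q = np.zeros((d, d))
            cq = c[: len(iu)]
            np.add.at(q, (iu, ju), cq / 2.0)
            np.add.at(q, (ju, iu), cq / 2.0)
            q[np.diag_indices(d)] = cq[iu == ju]
            neurons.append(
                QuadraticNeuron(
                    Q=q, linear=c[len(iu) :], const=float(-c @ mean)
                )
            )
        self.n_features_in_ = d
        self.mean_ = mean
        self.whitener_ = white
        self.components_ = comps
        self.neurons_ = neurons
        self.delta_values_ = dvals[:k]
        return self

    def transform(self, X) -> np.ndarray:
        """Slow-component responses for raw stimulus coordinates ``X``."""
        check_is_fitted(self, "neurons_")
        f = quadratic_expansion(np.asarray(X, dtype=float)) - self.mean_
        return (f @ self.whitener_.T) @ self.components_


def sfa_quadratic(
    x_t: np.ndarray, x_t1: np.ndarray, n_components: int = 16, **kwargs
) -> list[QuadraticNeuron]:
    """Fit :class:`QuadraticSFA` on stimulus pairs; return the slow neurons."""
    return QuadraticSFA(n_components=n_components, **kwargs).fit(x_t, X_next=x_t1).neurons_


def neuron_rates(
    neuron: QuadraticNeuron,
    stimuli: np.ndarray,
    rate_scale: float | None = None,
    target_mean_rate: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Median-split firing rates of a quadratic neuron.

    Responses are centered at their median; excitatory rates are the
    positive part, inhibitory rates the magnitude of the negative part, each
    multiplied by ``rate_scale`` (calibrated, when not given, so the mean of
    excitatory plus inhibitory rate is ``target_mean_rate`` spikes/frame).
    At most one of the two rates is positive in any frame.
    """
    r = neuron.response(stimuli)
    med = float(np.median(r))
    centered = r - med
    if rate_scale is None:
        rate_scale = neuron.rate_scale
    if rate_scale is None:
        mean_abs = float(np.mean(np.abs(centered)))
        rate_scale = target_mean_rate / mean_abs if mean_abs > 0 else 0.0
    exc = np.maximum(centered, 0.0) * rate_scale
    inh = np.maximum(-centered, 0.0) * rate_scale
    return exc, inh


def poisson_counts(rates: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Independent Poisson spike counts per frame, seeded."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(rates)


def stc_matrix(stimuli: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Spike-triggered covariance relative to a white stimulus prior.

    The spike-weighted covariance of the stimuli about the spike-triggered
    mean, minus the identity (the prior covariance of whitened stimuli).
    """
    s = np.asarray(stimuli, dtype=float)
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("no spikes: total count is zero")
    sta = (c @ s) / total
    sc = s - sta
    cov = (sc.T * c) @ sc / total
    cov = 0.5 * (cov + cov.T)  # exact symmetry despite summation rounding
    return cov - np.eye(s.shape[1])


def significance_count(
    stimuli: np.ndarray,
    counts: np.ndarray,
    n_shuffles: int = 100,
    z: float = 4.4,
    seed: int | np.random.Generator = 0,
) -> StcResult:
    """Shuffle test for significant STC eigenvalues.

    Spike counts are randomly permuted ``n_shuffles`` times; the per-rank
    mean and SD of the shuffled eigen-spectra define a ``mean +/- z * SD``
    band.  Observed eigenvalues above the band count as significant
    excitatory directions, below as significant inhibitory ones.
    """
    if n_shuffles < 20:
        raise ValueError("need at least 20 shuffles")
    rng = np.random.default_rng(seed)
    obs = np.sort(np.linalg.eigvalsh(stc_matrix(stimuli, counts)))
    spectra = np.empty((n_shuffles, obs.size))
    for j in range(n_shuffles):
        perm = rng.permutation(len(counts))
        spectra[j] = np.sort(np.linalg.eigvalsh(stc_matrix(stimuli, counts[perm])))
    mean = spectra.mean(axis=0)
    sd = spectra.std(axis=0, ddof=1)
    upper = mean + z * sd
    lower = mean - z * sd
    return StcResult(
        eigenvalues=obs,
        shuffle_mean=mean,
        shuffle_sd=sd,
        n_sig_excitatory=int(np.sum(obs > upper)),
        n_sig_inhibitory=int(np.sum(obs < lower)),
        z_threshold=z,
    )


def nested_significance_count(
    stimuli: np.ndarray,
    counts: np.ndarray,
    n_shuffles: int = 100,
    z: float = 4.4,
    seed: int | np.random.Generator = 0,
    max_rounds: int | None = None,
) -> StcResult:
    """Sequential (nested) shuffle test for significant STC eigenvalues.

    The flat per-rank band suffers a rank-alignment artifact: once a strong
    signal eigenvalue occupies the top rank, the remaining noise eigenvalues
    are compared against shuffle ranks shifted by one, and the largest noise
    eigenvalue can spuriously clear the band.  The sequential procedure used
    in physiological STC analyses avoids this: test only the extreme
    eigenvalues against their shuffle band; if the largest (smallest) is
    significantly excitatory (inhibitory), project its eigenvector out of
    the stimulus ensemble and repeat on the reduced space until no extreme
    eigenvalue is significant.
    """
    rng = np.random.default_rng(seed)
    s = np.asarray(stimuli, dtype=float)
    d = s.shape[1]
    max_rounds = d if max_rounds is None else max_rounds
    n_exc = 0
    n_inh = 0
    first: StcResult | None = None
    for _ in range(max_rounds):
        if s.shape[1] == 0:
            break
        res = significance_count(s, counts, n_shuffles, z, rng)
        if first is None:
            first = res
        m = stc_matrix(s, counts)
        evals, evecs = np.linalg.eigh(m)
        top_sig = evals[-1] > res.shuffle_mean[-1] + z * res.shuffle_sd[-1]
        bot_sig = evals[0] < res.shuffle_mean[0] - z * res.shuffle_sd[0]
        if not top_sig and not bot_sig:
            break
        # remove the more extreme excursion first
        top_z = (evals[-1] - res.shuffle_mean[-1]) / max(res.shuffle_sd[-1], 1e-30)
        bot_z = (res.shuffle_mean[0] - evals[0]) / max(res.shuffle_sd[0], 1e-30)
        if top_sig and (top_z >= bot_z or not bot_sig):
            direction = evecs[:, -1]
            n_exc += 1
        else:
            direction = evecs[:, 0]
            n_inh += 1
        basis = np.linalg.svd(
            np.eye(s.shape[1]) - np.outer(direction, direction)
        )[0][:, : s.shape[1] - 1]
        s = s @ basis
    assert first is not None
    return StcResult(
        eigenvalues=first.eigenvalues,
        shuffle_mean=first.shuffle_mean,
        shuffle_sd=first.shuffle_sd,
        n_sig_excitatory=n_exc,
        n_sig_inhibitory=n_inh,
        z_threshold=z,
    )


def neuron_significance(
    neuron: QuadraticNeuron,
    stimuli: np.ndarray,
    n_shuffles: int = 100,
    z: float = 4.4,
    seed: int = 0,
    nested: bool = True,
) -> tuple[StcResult, StcResult]:
    """Full STC significance analysis of one model neuron.

    White-noise stimuli drive the neuron; the excitatory and inhibitory
    median-split spike trains are analyzed separately (sequential test by
    default).  Returns the :class:`StcResult` of each train (excitatory
    first).
    """
    rng = np.random.default_rng(seed)
    exc, inh = neuron_rates(neuron, stimuli)
    test = nested_significance_count if nested else significance_count
    res = []
    for rates in (exc, inh):
        counts = poisson_counts(rates, rng)
        res.append(test(stimuli, counts, n_shuffles, z, rng))
    return res[0], res[1]
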
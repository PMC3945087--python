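# Methods

## Model

The representation is a complete orthonormal filter matrix `W ∈ R^{D×D}`
over whitened patch coordinates, grouped into `I = D/K` subspaces of
dimension `K = 2` (consecutive rows).  The output of subspace `i` at time
`t` is the energy `y_i(t) = Σ_{k∈i} (w_k^T x(t))²` — the energy model of a
complex cell.  When the rows are discrete-Fourier quadrature pairs (cosine
and sine of one frequency), the outputs are the power spectrum of the
input; cyclic translation rotates each quadrature plane and leaves the
energies exactly unchanged, which is the analytic anchor of the package.

No `1/K` normalization is applied to the energies, so `E[y_i] = K` on
whitened data; constant factors rescale the objectives without moving
their optima.

### Objectives

All objectives are minimized subject to `W W^T = I` and are averaged over
both subspaces and time so the mixture combines per-unit quantities on the
same scale (the relative weighting inside the mixture is exactly the raw
sum of the two averages; no further transformation is applied):

* slowness: `Ψ_slow = (1/I) Σ_i s_i` with the inverse slowness
  `s_i = mean_t (y_i(t+1) − y_i(t))²`.  The discrete-time difference
  quotient with unit time step is used; temporal-difference means vanish
  and variance terms are constant under the orthonormality constraint, so
  `s_i` is the raw mean squared energy difference.
* sparsity: `Ψ_sparse = (1/(I·T)) Σ_{t,i} √(y_i(t))`, the negative
  log-likelihood of a spherical exponential density on each subspace with
  its scale and normalization constants dropped.
* mixture: `Ψ = (1−γ) Ψ_slow + γ Ψ_sparse`.  At the endpoints the unused
  part is skipped, so γ=0 and γ=1 reproduce the pure objectives bit-exactly.
  In the mixture the sparsity term is evaluated on the first frames of the
  pairs (for walk-generated data these are the full frame stream).

Gradients are analytic (`∂s_i/∂w_j` via the chain rule through the
responses; the sparsity gradient guards `√y` with `ε = 1e−12`, far below
whitened-data energies) and are verified against central finite differences
at relative error `< 1e−5` in the test suite.

### Optimizer

A Rosen-style projected gradient descent: candidate
`W' = orth(W − μ ∇Ψ)` with symmetric (Löwdin) orthogonalization
`M ↦ M (M^T M)^{−1/2}` — the Frobenius-closest orthonormal matrix,
computed by symmetric eigendecomposition with an eigenvalue floor of
1e−12 — and a backtracking line search that halves `μ` until the
objective strictly improves.  Defaults: `μ0 = 1`, backtrack factor 0.5,
at most 30 backtracks, relative-change tolerance 1e−8, 2000 iterations,
full-batch gradients.  The step length carries over between iterations
and doubles after a step accepted without backtracking ("adaptive"
mode, the default); `adaptive_step=False` restarts every line search at
`μ0`.  If no improving step exists the optimizer halts and flags
convergence; accepted objective values are strictly decreasing by
construction.

### Frustrated pairings and targeted restarts

On cyclic-shift data the global optimum (the Fourier quadrature bank) is
known, yet plain gradient projection from a random orthonormal start
reliably terminates in local minima with a characteristic structure: a
small closed set of subspaces each straddling two frequency planes
half-and-half (including odd cycles, e.g. three subspaces sharing three
planes), where no individual rotation lowers the objective.  These traps
are robust — random tangent perturbations up to amplitude 0.3 fall back
into the same basin — and they carry a clean signature: the trapped
subspaces' inverse slowness sits orders of magnitude above the rest.

`experiments.fit_ssa_with_restarts` therefore alternates full-bank descent
with targeted restarts: subspaces whose `s_i` exceeds 5% of the maximum
(when the maximum exceeds the median thirtyfold) are re-mixed by a seeded
random orthonormal rotation of just their rows — which keeps the bank
orthonormal and leaves all other subspaces untouched — and the small
subproblem over those rows' responses is re-optimized before full descent
resumes.  If descent stalls without the two-scale signature, the dominant
contributors to the objective are re-dealt instead.  All randomness is
derived from one seed; each inner optimization retains the monotone
line-search contract.  In practice one or two restart rounds reduce the
objective to ~1e−16 of its initial value with Fourier-match score 1.0.

The sparsity objective shows the same trap class on data drawn from the
spherical-exponential subspace model: descent from a random start reaches
a bank whose subspaces each hold one (rotated) direction from each of two
source planes, a first-order critical configuration robust to tangent
perturbations, with no per-subspace signature to detect it by.
`experiments.fit_isa_with_pairing_polish` therefore follows full descent
with Jacobi-style pairwise sweeps: for every pair of subspaces the
objective restricted to rotations of their four rows (evaluated on the
precomputed block responses, leaving all other subspaces untouched) is
probed by short optimizations from seeded random block rotations — the
block landscape itself retains a sizable straddle basin, so confirmation
sweeps escalate the number of probes — and re-optimized thoroughly when a
probe finds a materially better pairing.  Sweeps alternate with full-bank
descent until two consecutive sweeps find nothing.  Across tested seeds
this recovers every planted subspace to within ~4 degrees of principal
angle.

## Preprocessing

Patches are vectorized column-major.  The DC component (each patch's own
mean, equivalently the projection onto the constant vector) is removed and
the remaining coordinates are expressed in a fixed deterministic
orthonormal AC basis (the Householder complement of the normalized ones
vector), then decorrelated with the symmetric ("ZCA") whitener `C^{−1/2}`
from the eigendecomposition of the AC covariance, with `1e−10 ×` the mean
eigenvalue added to the diagonal to guard near-degenerate directions (the
disc data set has some).  No low-pass filtering or dimension reduction is
applied.  The transform is strictly linear; learned filters are mapped
back to pixel space by `v = B C^{−1/2} w`, which preserves responses
exactly and yields zero-mean pixel filters.

For the cyclic-shift experiment the covariance is estimated under the
generator's known torus stationarity (`PatchWhitener(stationary=True)`):
the mean DFT power spectrum of the training patches defines a circulant
covariance whose whitener is diagonal in the Fourier basis.  This is still
symmetric whitening, with a structured covariance estimator.  The choice
matters: with the raw sample covariance, finite-sample anisotropy within
each frequency plane (`O(1/√n)`) makes *exact* invariance infeasible under
the orthonormality constraint and floors the objective near 1e−3 of its
initial value at n = 20,000, whereas the stationary estimate leaves the
Fourier bank exactly feasible and the objective reaches numerical zero.

## Synthetic data

The generators emulate the study inputs with Gaussian surrogates:

* `make_pink_noise_image`: deterministic DFT amplitudes `∝ 1/f^α`
  (default α = 1, i.e. power `∝ 1/f²`, the canonical natural-image
  surrogate), uniform Hermitian-symmetric phases, zero DC, unit variance.
* `make_circulant_pink_patches`: independent complex-Gaussian DFT
  coefficients with scale `∝ 1/f` on torus frequencies (white noise
  filtered on the torus), zero DC.  The ensemble covariance is exactly
  block-circulant; each patch has exactly zero mean.  Gaussian
  coefficients — rather than fixed-modulus spectra with random phases —
  matter for the optimization landscape: with every patch carrying an
  identical amplitude spectrum, the data manifold degenerates to a torus
  and random-start SSA systematically lands in spurious minima far from
  the Fourier bank; with Gaussian coefficients recovery is clean.
* transformation walks: per-axis translation steps with magnitude uniform
  on `[0, max_shift]` (default 2 px) and independent random sign,
  reflecting at image borders; rotation-angle increments uniform on
  ±10°; per-axis multiplicative scale factors uniform on `[0.95, 1.05]`
  with window side clipped to `[side, 2·side]`.  The rotation, scaling
  and movie walks are split into segments of 50 frames around independent
  random centers so the pair set covers the image.  Interpolation is
  bilinear for all open-boundary generators; cyclic shifts are exact
  spectral phase multiplications.  Pair sets store adjacent frames
  `(x(t), x(t+1))` — the only statistics the objectives consume — plus all
  logged increments; everything is bit-reproducible per seed.
* the disc window: the 121 pixels of a 14×14 frame closest to its center,
  ties broken row-major.  The 121st pixel falls one deep into a four-pixel
  distance class, so the mask is mirror-symmetric apart from that single
  boundary pixel (an exactly symmetric 121-pixel disc does not exist at
  this geometry).

Default pair count is 50,000 per data set — large enough for stable
fourth-order statistics at 120 dimensions, small enough for a desk run;
the evaluation pipelines in `experiments` use 20,000 and the trade-off
analysis runs at 7×7 patches with a few thousand pairs, sizes chosen so
each pipeline completes in minutes on one CPU.

What the surrogates do *not* contain: the heavy-tailed, phase-aligned
structure of natural images (edges, occlusions).  Gaussian pink noise has
no higher-order statistics, so the sparsity objective is nearly flat over
orthonormal banks in expectation, and ISA banks trained here stay close to
their initialization rather than developing the strongly localized Gabor
structure seen on natural input.  Conclusions that survive this surrogate
— Fourier recovery under cyclic shifts, quadrature-pair structure and
slowness gains under translation, the *relative* localization difference
between SSA and ISA banks, the trade-off geometry — are second-order
effects; absolute filter shapes on natural movies are out of reach by
construction.

## Evaluation

* `rank_subspaces`: subspaces sorted by ascending `s_i`, ties kept stable.
* `pair_phase_difference`: DFT phase offset of the two filters at the peak
  of the product of their magnitude spectra, principal value in `[0, π]`;
  flagged (not raised) when the filters do not share a dominant frequency
  (either filter's magnitude at the shared peak below half its own
  maximum).
* `fourier_match_score` / `subspace_overlap_score`: mean over subspaces of
  the best mean squared principal-angle cosine against the reference bank
  — invariant to within-subspace rotation and subspace permutation.
* `localization_index`: one minus the normalized spatial entropy of the
  filter's pixel energy map (1 = single pixel, →0 = global).
* `tradeoff_curve`: performance at each γ is the achieved objective gain
  over a shared seeded random initialization, as a percentage of the gain
  of the pure objective's own optimum, so both endpoints are 100% by
  construction (the random start is the only reference shared by all γ).
  The grid is optimized by bidirectional warm-start continuation: swept
  upward with each γ starting from the previous optimum, then downward
  from the γ = 1 solution, keeping the better optimum per γ.  Independent
  cold starts were tried first and land in different local basins, which
  buries the frontier's monotonicity under 10-20-percentage-point scatter
  (the sparsity gain on Gaussian surrogates is small, so its percentage
  scale amplifies any scatter); continuation propagates the best basin
  along the grid and the resulting curves are exactly monotone.  The
  break-even γ is located by linear interpolation of the crossing of the
  two percentage curves; default grid {0, 0.1, …, 1}.

## STC supplement

Quadratic slow feature analysis expands a low-dimensional stimulus
projection (the 8 lowest-frequency Fourier quadrature pairs of the patch,
16 coordinates, standardized) into all monomials of degree ≤ 2 (152
features), centers and whitens the features, and takes the bottom
eigenvectors of the temporal-difference covariance; each component maps
back to an exact quadratic form over the stimulus coordinates.

Each form becomes two Poisson model neurons by centering its white-noise
responses at their median: excitatory rates from the positive part,
inhibitory from the magnitude of the negative part, scaled so the mean
total rate is 0.5 spikes/frame (a rate convention chosen once; it is
reported in output metadata).  Spike-triggered covariance is the
spike-weighted stimulus covariance about the spike-triggered mean minus
the identity prior.

Significance of eigenvalues is assessed against spike-count shuffles
(random permutations) at `mean ± 4.4 SD` per rank — 4.4 being the
Bonferroni-style two-sided Gaussian quantile for ~100 comparisons.  Two
procedures are provided.  The flat test compares every observed rank with
its shuffled rank band; it suffers a rank-alignment artifact (with strong
signal eigenvalues occupying the top ranks, the largest noise eigenvalue
is compared against a shuffle rank short of the edge and can spuriously
clear the band).  The sequential (nested) test — the procedure standard in
physiological STC analyses — tests only the extreme eigenvalues, projects
a significant direction out of the stimulus ensemble, and repeats on the
reduced space; it is exact on planted ground truth (a rank-2 energy-model
neuron yields exactly two significant excitatory eigenvalues across seeds)
and is what the pipelines report.  Scale defaults: 16 stimulus dimensions,
20,000 frames, 100 shuffles.

## Numerical choices and degenerate inputs

* Symmetric orthogonalization and whitening raise informative errors on
  singular input (naming the offending singular value / the count of
  deficient eigenvalues) rather than regularizing silently; only the
  whitening adds its small documented ridge.
* `optimize` aborts with the iteration index on non-finite objective or
  gradient values.
* Constant frame sequences make every orthonormal bank optimal for
  slowness; the optimizer then halts at the start without accepting a
  step.
* Within-subspace rotations are a gauge freedom of every reported
  quantity; tests verify drift `≤ 1e−10` under random gauges.

## Known limitations

* Sparsity on Gaussian surrogates is weakly identified (see above); ISA
  results here probe the *contrast* with slowness, not Gabor formation.
* The restart heuristic is tailored to objectives with a near-zero
  attainable optimum (cyclic data); on open-boundary data it simply never
  triggers its frustration branch.
* The nested STC test assumes white stimuli (identity prior), as generated.
* `transform` of `QuadraticSFA` and the neurons share the training-set
  feature mean; responses on new stimuli are exact quadratic forms, but
  the median split is recomputed per stimulus ensemble by design.
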
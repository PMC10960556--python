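# Methods

## Model

Sensor data at a single time point follow the linear Gaussian forward model
`b ~ N(A x, σ² I)`: `A ∈ R^{M×N}` maps `N` cortical sources, constrained to
unit dipoles along the local surface normal, to `M` scalp sensors with
i.i.d. sensor noise. The prior on the source map `x` is a Laplace
distribution on its graph Fourier coefficients `Uᵀ x`, where `U` holds the
eigenvectors (connectome harmonics) of the symmetric normalized Laplacian
`L = I − D^{-1/2} W D^{-1/2}` of the structural connectome graph. The MAP
estimate is the convex program

    x̂ = argmin_x ‖b − A x‖₂² + λ ‖Uᵀ x‖₁ ,        λ = 2σ²/β,

with β the Laplace scale. The penalty is an *analysis* sparsity prior: it
favours maps synthesized from few harmonics, i.e. few simultaneously active
distributed brain networks, rather than few active vertices.

## Connectome graph

Two edge sets are combined: long-range connectivity with streamline-count
weights, and short-range cortical neighbourhood edges, a Gaussian kernel
`exp(−d²/2ς²)` of Euclidean distance restricted to mesh edges. Neither the
kernel, its bandwidth, nor the combination rule is canonical, so all three
are explicit parameters: bandwidth ς defaults to the mean mesh edge length
(mm), each edge set is rescaled to unit mean edge weight, and they are summed
with a mix ratio (default 1). Raw streamline counts are used without a log
transform. Graphs must be connected (mesh edges guarantee this in practice);
isolated vertices are rejected rather than patched because `D^{-1/2}` is
undefined for them. Eigenvector signs follow a fixed convention (largest-
magnitude entry positive, ties to the lowest vertex index) so spectra are
reproducible across linear-algebra backends; within numerically degenerate
eigenvalue blocks only subspace-level properties are guaranteed. The full
dense eigendecomposition is used — the method needs the complete basis — with
a configurable size cap (default 4000 vertices).

## Solver

Accelerated proximal gradient descent (FISTA-type):

    a   = (k − 1)/(k + 2)
    y   = (1 + a) x_k − a x_{k−1}
    z   = y − τ · 2 Aᵀ(A y − b)
    x_{k+1} = prox(z),   prox(z) = z + U (S_{τλ}(Uᵀz) − Uᵀz)

with step `τ = 1/ρ`, `ρ = 2 σ_max(A)²` the Lipschitz constant of the gradient
of the least-squares term, and `S` the soft-thresholding operator. The
threshold is `τ·λ`, the exact proximal map of the scaled penalty.
Initialization is `x₀ = 0` (deterministic and scale-free); iteration stops
when the relative change `‖x_k − x_{k−1}‖/‖x_{k−1}‖` falls below `tol`
(default 1e-4, the protocol value), skipping the test while `x_{k−1} = 0`; a
`max_iter` cap (default 10⁴) flags, rather than raises on, non-convergence.
Multiple time points are solved independently per column.

Implementation note: because `U` is a full orthogonal matrix, the iteration
is run on the spectral coefficients `c = Uᵀx` with the rotated lead field
`B = AU`, where the prox is plain elementwise soft thresholding. The iterate
sequence is exactly the orthogonal transform of the vertex-domain sequence —
identical objective values, relative-change statistics and stopping decisions,
and `σ_max(B) = σ_max(A)` — while avoiding two `N×N` products per iteration.
The vertex-domain prox formula is exposed separately and the equivalence is
tested against independent convex oracles.

### Normalization bookkeeping

Before solving, each lead-field column is divided by its L2 norm (depth
normalization — least-squares inverses otherwise favour superficial sources
with large gain norms) and the recording is divided by its per-time-point L2
norm (so the useful λ range is scale-free). The physical-scale estimate is
recovered exactly as `x̂_i = x̂_i^{norm} · ‖b‖₂ / ‖A_i‖₂`. Normalization is
applied per source column even where a row-wise phrasing is conventional,
because the final rescaling indexes sources and depth bias is a source-side
phenomenon; sensor-row whitening is a different operation and is not
implemented. This bookkeeping makes the full pipeline exactly equivariant
under scaling of `b` (bit-exact for power-of-two factors).

## Baselines

Minimum norm, dSPM and sLORETA share the Tikhonov kernel
`K = Aᵀ(A Aᵀ + λ C)^{-1}` with diagonal noise covariance `C = σ² I`, with σ
matched to the simulation noise. dSPM divides each source estimate by its
noise standard deviation `sqrt(diag(K C Kᵀ))`; sLORETA by the square root of
the resolution diagonal `diag(K A)`, which localizes a single noiseless
dipole exactly (verified exhaustively). These are the standard literature
closed forms, implemented directly so that method comparisons exercise the
experimental design rather than any package's defaults; no depth weighting is
applied to baselines by default (a flag shares the spectral method's
normalization). λ for every method is selected on the same grid — 20
log-spaced values from 1e-5 to 0.3 — by maximizing r² against the reference
map. eLORETA is a registration hook only; its iterative weighting scheme is
out of scope.

## Synthetic data

The generator emulates the study's simulation design end to end:

- **Cortex**: `n` near-uniform points on a sphere (golden-angle lattice,
  tangential jitter), triangulated by convex hull — a closed 2-sphere mesh
  at any vertex count with outward radial normals. Radius 80 mm.
- **Connectome**: mesh edges as short-range support plus `2n` long-range
  edges sampled with probability ∝ distance², integer weights from a
  geometric distribution with mean 20 (streamline-count-like).
- **Lead field**: infinite-homogeneous-medium dipole potentials
  (conductivity 0.33 S/m) for normal-oriented unit dipoles, sensors on a
  concentric 100 mm sphere, common-average referenced. A single-shell
  analytic head is used deliberately: any fixed linear `A` exercises the
  inverse machinery identically, and layered-head modelling is a separate
  problem.
- **Truth maps**: `k` active harmonics (default 5) drawn with probability
  ∝ 1/(1+rank)², geometrically decaying amplitudes (ratio 0.8) with random
  signs. The squared-rank low-frequency bias reflects that evoked activity
  maps are dominated by smooth harmonics, and keeps planted sources within
  the sensor-visible part of the spectrum: scalp sensors are nearly blind to
  high-graph-frequency harmonics (measured gain norms ~0.3 vs ~3 for smooth
  ones), and with a heavier-tailed bias no estimator could recover the
  planted map even noiselessly. By default the map is then standardized
  (sample std) and shifted to be nonnegative, matching how statistical
  activation maps are prepared for forward simulation; the raw signed map
  (exactly k-sparse spectrum) is available via `nonnegative=False`. A
  mismatched-basis variant plants truth in the harmonics of an independently
  re-sampled connectome to probe robustness honestly.
- **Noise**: i.i.d. Gaussian at a stated SNR; the noise variance is
  mean-square signal power / 10^(SNR/10), with the reference power averaged
  over all sensors and time points. Default 3 dB, the protocol value.

Default sizes are 800 vertices / 64 sensors, a desk-scale stand-in for
~8000-node, 128-electrode high-resolution EEG; full eigendecomposition plus
grid-selected solves complete in seconds per scenario on one CPU. What
passing tests show is that the estimator recovers planted, spectrally
compressible activity through a calibrated linear forward model better than
minimum-norm baselines; what they cannot show is performance under realistic
cortical folding (where opposing sulcal walls cancel), layered-head lead
fields, correlated sensor noise, or connectome estimation error beyond the
mismatched-basis probe.

## Evaluation protocol

- **r²**: squared Pearson correlation between planted and reconstructed maps,
  vertex-wise at a single analysis time point (a time-averaged variant
  exists but is not the default).
- **Spectral fidelity**: two-sample Kolmogorov–Smirnov distance between the
  distributions of absolute graph Fourier coefficients of reconstruction and
  truth (signed-coefficient option available). Note the KS statistic is
  informative only when the truth spectrum has no large atom at zero: for an
  exactly k-sparse signed truth both dense estimates saturate near (N−k)/N,
  which is why the shaped nonnegative truth is the default comparison
  condition.
- **λ selection**: argmax of the score over the 20-point log grid
  [1e-5, 0.3]; ties break to the smallest λ; per-λ solver failures are
  recorded, not fatal.
- **λ sensitivity**: worst-case percentage score drop over
  [0.95 λ*, 1.05 λ*] (endpoints always evaluated), aggregated as 5th/50th/
  95th percentiles across random seeds, which stand in for subjects — a
  protocol analogue, not a reproduction of any subject-level table.
- **SNR / ROI traces**: per-time mean-square source power relative to a
  pre-stimulus window; mean absolute amplitude over a vertex set.

## Numerical choices and edge cases

- Eigenvalue range checks use 1e-8 tolerances; GFT round trips 1e-10.
- `prox` validates `UᵀU = I` to 1e-6 and rejects non-orthonormal bases.
- Zero recordings, zero lead-field columns, constant maps, empty ROIs and
  out-of-range indices raise with the offending index named.
- `SNR = inf` is the documented noiseless flag (noise σ = 0).
- The λ = 0 limit reproduces the pseudoinverse minimum-norm solution (the
  iteration starts at 0 and stays in the row space of `A`).

## Problem sizes used in the shipped studies

The test suite runs the comparative study at the default 800/64 scale over
20 seeds and the acceptance script over 10 seeds with 5-point sensitivity
intervals; the solver-vs-oracle checks use small random instances (M ≤ 12,
N ≤ 40) against 10⁵-iteration unaccelerated proximal descent. These sizes
were chosen so a full rerun completes in minutes on a single CPU while
keeping every qualitative comparison at the default study scale.
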
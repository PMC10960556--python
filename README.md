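# cset — connectome-spectrum electromagnetic tomography

EEG/MEG source imaging estimates cortical current amplitudes `x ∈ R^N` from
scalp measurements `b ∈ R^M` through a linear forward model `b ≈ A x`
(`A` the lead field). With far more sources than sensors the problem is
ill-posed; every estimator is defined by its prior. This package implements a
source estimator whose prior is that brain activity is **sparse in the
harmonic basis of the structural connectome**: writing `L = I − D^{-1/2} W
D^{-1/2} = U Λ Uᵀ` for the normalized Laplacian of the connectome graph
(`W` = streamline-count + cortical-neighbourhood edge weights), the estimate
is the MAP solution under Gaussian sensor noise and a Laplace prior on the
graph Fourier coefficients `Uᵀx`:

```
x̂ = argmin_x ‖b − A x‖₂² + λ ‖Uᵀ x‖₁
```

solved by accelerated proximal gradient descent (momentum `a_k = (k−1)/(k+2)`,
step `τ = 1/ρ` with `ρ = 2 σ_max(A)²`), where the proximal map of the spectral
L1 penalty is soft thresholding in the harmonic basis. Depth bias is handled
by unit-normalizing each lead-field column before solving and rescaling the
solution afterwards; the recording is unit-normalized per time point so the
useful range of `λ` does not depend on measurement scale.

The package is aimed at methods researchers in electrophysiological source
imaging and graph signal processing. It also ships the classical linear
baselines (minimum norm, dSPM, sLORETA) in their standard closed forms, a
fully synthetic simulation suite (cortex mesh, connectome, dipole lead field,
planted activity maps, calibrated sensor noise), and the evaluation protocol:
r² against the planted map, Kolmogorov–Smirnov distance between spectral
weight distributions, λ selection on a 20-point log grid from 1e-5 to 0.3,
and ±5 % λ-sensitivity analysis.

## Worked example

```python
from cset import (make_scenario, ConnectomeSpectrumTomography, MinimumNorm,
                  ks_distance, spectral_weight_distribution)

sc = make_scenario(seed=0)          # 800 sources, 64 sensors, 5 harmonics, 3 dB
model = ConnectomeSpectrumTomography.from_scenario(sc)
res = model.fit_grid(truth=sc.truth)   # lambda chosen on the 20-point log grid
print(res.summary(truth=sc.truth))

mne = MinimumNorm.from_scenario(sc).fit_grid(truth=sc.truth)
truth_w = spectral_weight_distribution(sc.basis, sc.truth)
print("r2  (minimum norm):", round(mne.score(sc.truth), 4))
print("KS  cset vs truth :", round(ks_distance(
    spectral_weight_distribution(sc.basis, res.params), truth_w), 4))
print("KS  mne  vs truth :", round(ks_distance(
    spectral_weight_distribution(sc.basis, mne.params), truth_w), 4))
```

prints

```
Source reconstruction results
==================================
method:        cset
sensors (M):   64
sources (N):   800
lambda:        0.3
iterations:    92
converged:     True
objective:     0.417501
r2 vs truth:   0.5837

r2  (minimum norm): 0.4315
KS  cset vs truth : 0.34
KS  mne  vs truth : 0.4675
```

The spectral-sparsity estimator recovers the planted activity map more
accurately than minimum norm (r² 0.58 vs 0.43) and its reconstruction's
spectral weight distribution is closer to the truth's (KS 0.34 vs 0.47):
minimum norm spreads energy over many harmonics and underestimates the
sparsity of the activity in the connectome spectrum.

A command-line interface mirrors the library
(`cset fixtures | graph | simulate | solve | evaluate | run`); see
`cset --help`.

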
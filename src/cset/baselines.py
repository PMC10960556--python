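"""Classical linear inverse solvers: minimum norm (MNE), dSPM, sLORETA.

All three share the Tikhonov-regularized minimum-norm kernel

    K = A^T (A A^T + lam * C)^{-1},        x_hat = K b,

with C the (diagonal) sensor noise covariance.  dSPM divides each source
estimate by the noise-induced standard deviation of its estimator,
sqrt(diag(K C K^T)); sLORETA divides by the square root of the diagonal of
the resolution matrix, sqrt(diag(K A)), which gives exact (zero-error)
localization of a single noiseless dipole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .forward import LeadField, NoiseModel, SensorRecording
from .solver import ReconstructionResult


@dataclass
class LinearInverseOperator:
    """Cached sensors-to-sources kernel for a linear inverse method."""

    K: np.ndarray
    method_tag: str
    lam: float
    noise: NoiseModel

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if not np.all(np.isfinite(self.K)):
            raise ValueError("kernel contains non-finite entries")
        if self.method_tag not in {"mne", "dspm", "sloreta"}:
            raise ValueError(f"unknown method tag {self.method_tag!r}")

    def apply(self, b: np.ndarray) -> np.ndarray:
        return self.K @ b


def assemble_noise_covariance(noise_sigma: float, n_sensors: int) -> NoiseModel:
    """Diagonal noise covariance sigma^2 * I matching the simulation noise."""
    if noise_sigma <= 0:
        raise ValueError("noise sigma must be positive")
    return NoiseModel(sigma=float(noise_sigma), n_sensors=int(n_sensors))


def _mne_kernel(A: np.ndarray, C: np.ndarray, lam: float) -> np.ndarray:
    G = A @ A.T + lam * C
    try:
        # solve G^T y = A  ->  K = A^T G^{-1}; G symmetric
        K = scipy.linalg.solve(G, A, assume_a="sym").T
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular sensor covariance system; increase lam"
        ) from None
    if not np.all(np.isfinite(K)):
        raise np.linalg.LinAlgError("singular sensor covariance system; increase lam")
    return K


def _as_matrix(rec: SensorRecording | np.ndarray) -> tuple[np.ndarray, bool]:
    if isinstance(rec, SensorRecording):
        return rec.as_matrix(), rec.b.ndim == 1
    b = np.asarray(rec, dtype=float)
    return (b[:, None], True) if b.ndim == 1 else (b, False)


def _result(X: np.ndarray, vector_in: bool, tag: str, lam: float) -> ReconstructionResult:
    x = X[:, 0] if vector_in else X
    return ReconstructionResult(x_hat=x, x_hat_normalized=x, lam=lam, method_tag=tag)


def mne_operator(lf: LeadField, noise: NoiseModel, lam: float) -> LinearInverseOperator:
    """Minimum-norm (Tikhonov) inverse operator K = A^T (A A^T + lam C)^{-1}."""
    K = _mne_kernel(lf.A, noise.covariance, lam)
    return LinearInverseOperator(K=K, method_tag="mne", lam=lam, noise=noise)


def mne_solve(
    lf: LeadField, rec: SensorRecording | np.ndarray, noise: NoiseModel, lam: float
) -> ReconstructionResult:
    """Minimum norm estimate x_hat = A^T (A A^T + lam C)^{-1} b."""
    op = mne_operator(lf, noise, lam)
    B, vec = _as_matrix(rec)
    return _result(op.apply(B), vec, "mne", lam)


def dspm_solve(
    lf: LeadField, rec: SensorRecording | np.ndarray, noise: NoiseModel, lam: float
) -> ReconstructionResult:
    """Noise-normalized minimum norm (dSPM): MNE divided per source by the
    noise-induced standard deviation sqrt(diag(K C K^T))."""
    op = mne_operator(lf, noise, lam)
    denom = np.sqrt(np.einsum("nm,mk,nk->n", op.K, noise.covariance, op.K))
    if np.any(denom == 0):
        raise ValueError("zero noise-variance diagonal; dSPM undefined")
    B, vec = _as_matrix(rec)
    return _result(op.apply(B) / denom[:, None], vec, "dspm", lam)


def sloreta_solve(
    lf: LeadField, rec: SensorRecording | np.ndarray, noise: NoiseModel, lam: float
) -> ReconstructionResult:
    """Resolution-standardized minimum norm (sLORETA): MNE divided per source
    by sqrt(diag(K A)).  Localizes a single noiseless dipole exactly."""
    op = mne_operator(lf, noise, lam)
    diag_res = np.einsum("nm,mn->n", op.K, lf.A)
    if np.any(diag_res <= 0):
        raise ValueError("nonpositive resolution diagonal; sLORETA undefined")
    B, vec = _as_matrix(rec)
    return _result(op.apply(B) / np.sqrt(diag_res)[:, None], vec, "sloreta", lam)


# Registry so additional linear solvers (e.g. an external eLORETA) can be
# plugged in without touching the evaluation code.
BASELINE_SOLVERS = {
    "mne": mne_solve,
    "dspm": dspm_solve,
    "sloreta": sloreta_solve,
}


def register_baseline(tag: str, solve_fn) -> None:
    """Register an external linear inverse solver under a new method tag."""
    if tag in BASELINE_SOLVERS:
        raise ValueError(f"method tag {tag!r} already registered")
    BASELINE_SOLVERS[tag] = solve_fn
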
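"""Sparse-in-spectrum source reconstruction by accelerated proximal gradient descent.

The estimator minimizes

    ||b - A x||_2^2 + lam * ||U^T x||_1,

the MAP estimate under Gaussian sensor noise and a Laplace prior on the graph
Fourier coefficients of the source map.  The non-smooth term is handled with
the proximal operator of the spectral L1 penalty, which for a full orthonormal
U is soft thresholding in the harmonic basis.  Acceleration uses the momentum
schedule a_k = (k - 1) / (k + 2) with step tau = 1 / rho, where
rho = 2 * sigma_max(A)^2 is the gradient Lipschitz constant of the
least-squares term.

Internally the iteration runs on the spectral coefficients c = U^T x with the
rotated lead field B = A U: because U is orthogonal this is exactly the same
iterate sequence (same objective values, same relative-change statistic,
sigma_max(B) = sigma_max(A)) while avoiding two N x N products per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField, SensorRecording, depth_normalize, normalize_recording
from .graph import SpectralBasis


@dataclass
class SolverConfig:
    """APGD solver settings.

    lam : regularization weight (>= 0) on the spectral L1 term.
    tol : relative-change stopping threshold ||x_k - x_{k-1}|| / ||x_{k-1}||.
    max_iter : iteration cap; hitting it flags the run as not converged.
    x0 : optional initial source map (defaults to zeros).
    """

    lam: float = 0.01
    tol: float = 1e-4
    max_iter: int = 10_000
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ReconstructionResult:
    """Output of an inverse solve.

    ``x_hat`` is the physical-scale estimate (after undoing the depth and
    recording normalizations); ``x_hat_normalized`` is the solution of the
    normalized problem.  Per-time-point convergence metadata are arrays of
    length T.
    """

    x_hat: np.ndarray
    x_hat_normalized: np.ndarray | None = None
    objective_traces: list[np.ndarray] | None = None
    n_iter: np.ndarray | None = None
    converged: np.ndarray | None = None
    relative_change: np.ndarray | None = None
    lam: float | None = None
    method_tag: str = "cset"

    @property
    def objective_trace(self) -> np.ndarray | None:
        """Objective trace of the first (or only) time point."""
        return None if self.objective_traces is None else self.objective_traces[0]


def objective(
    A: np.ndarray, b: np.ndarray, U: np.ndarray, lam: float, x: np.ndarray
) -> float:
    """Penalized least-squares objective ||b - A x||^2 + lam ||U^T x||_1."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if A.shape[1] != x.shape[0] or A.shape[0] != b.shape[0]:
        raise ValueError("dimension mismatch between A, b and x")
    r = b - A @ x
    return float(r @ r + lam * np.abs(U.T @ x).sum())


def soft_threshold(z: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage S_tau(z) = sign(z) * max(|z| - tau, 0)."""
    if tau < 0:
        raise ValueError("threshold must be nonnegative")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - tau, 0.0)


def prox_spectral_l1(U: np.ndarray, z: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of x -> tau * ||U^T x||_1 for orthonormal U.

    Computed as z + U (S_tau(U^T z) - U^T z); for a full orthonormal basis
    this equals U S_tau(U^T z), the exact prox.
    """
    U = np.asarray(U, dtype=float)
    z = np.asarray(z, dtype=float)
    if tau < 0:
        raise ValueError("threshold must be nonnegative")
    G = U.T @ U
    if np.abs(G - np.eye(U.shape[1])).max() > 1e-6:
        raise ValueError("U must have orthonormal columns")
    w = U.T @ z
    return z + U @ (soft_threshold(w, tau) - w)


def lipschitz_step(A: np.ndarray) -> tuple[float, float]:
    """Gradient Lipschitz constant of ||b - A x||^2 and the matching step.

    Returns (rho, tau) with rho = 2 * sigma_max(A)^2 and tau = 1 / rho.
    """
    A = np.asarray(A, dtype=float)
    if not np.any(A):
        raise ValueError("lead field matrix is zero")
    smax = np.linalg.svd(A, compute_uv=False)[0]
    rho = 2.0 * smax**2
    return rho, 1.0 / rho


def _apgd_single(
    B: np.ndarray,
    b: np.ndarray,
    tau: float,
    lam: float,
    tol: float,
    max_iter: int,
    c0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int, bool, float]:
    """APGD on spectral coefficients for one time point.

    Returns (c, objective_trace, n_iter, converged, final relative change).
    """
    def obj(c: np.ndarray) -> float:
        r = b - B @ c
        return float(r @ r + lam * np.abs(c).sum())

    c_prev = c0.copy()
    c = c0.copy()
    trace = [obj(c)]
    thr = tau * lam
    converged = False
    rel = np.inf
    k = 0
    for k in range(1, max_iter + 1):
        a = (k - 1.0) / (k + 2.0)
        y = (1.0 + a) * c - a * c_prev
        z = y - tau * 2.0 * (B.T @ (B @ y - b))
        c_new = soft_threshold(z, thr)
        if not np.all(np.isfinite(c_new)):
            raise FloatingPointError(f"non-finite iterate at iteration {k}")
        denom = np.linalg.norm(c)
        step = np.linalg.norm(c_new - c)
        c_prev, c = c, c_new
        trace.append(obj(c))
        if denom > 0:
            rel = step / denom
            if rel <= tol:
                converged = True
                break
    return c, np.asarray(trace), k, converged, float(rel)


def _as_gain(lf: LeadField | np.ndarray) -> np.ndarray:
    return lf.A if isinstance(lf, LeadField) else np.asarray(lf, dtype=float)


def _as_data(rec: SensorRecording | np.ndarray) -> np.ndarray:
    if isinstance(rec, SensorRecording):
        return rec.as_matrix()
    b = np.asarray(rec, dtype=float)
    return b[:, None] if b.ndim == 1 else b


def _as_basis(basis: SpectralBasis | np.ndarray) -> np.ndarray:
    return basis.U if isinstance(basis, SpectralBasis) else np.asarray(basis, dtype=float)


def apgd_solve(
    lf: LeadField | np.ndarray,
    rec: SensorRecording | np.ndarray,
    basis: SpectralBasis | np.ndarray,
    cfg: SolverConfig,
) -> ReconstructionResult:
    """Minimize ||b - A x||^2 + lam ||U^T x||_1 by accelerated proximal
    gradient descent, one time point at a time.

    ``lf`` is expected to be depth-normalized and ``rec`` unit-norm per time
    point (see :func:`solve_cset` for the full pipeline); the math does not
    require it, but the regularization grid of the study protocol assumes it.
    The returned ``x_hat`` is the solution of the normalized problem —
    rescaling to physical units is a separate bookkeeping step
    (:func:`rescale_solution`).
    """
    A = _as_gain(lf)
    Bmat = _as_data(rec)
    U = _as_basis(basis)
    if A.shape[1] != U.shape[0]:
        raise ValueError("lead field and basis disagree on the number of sources")
    if Bmat.shape[0] != A.shape[0]:
        raise ValueError("recording and lead field disagree on sensor count")
    _, tau = lipschitz_step(A)
    BU = A @ U  # rotated lead field on spectral coefficients
    if cfg.x0 is None:
        c0 = np.zeros(U.shape[0])
    else:
        x0 = np.asarray(cfg.x0, dtype=float)
        if x0.shape[0] != U.shape[0]:
            raise ValueError("x0 has wrong length")
        c0 = U.T @ x0

    T = Bmat.shape[1]
    C = np.empty((U.shape[0], T))
    traces: list[np.ndarray] = []
    iters = np.empty(T, dtype=int)
    conv = np.empty(T, dtype=bool)
    rels = np.empty(T)
    for t in range(T):
        c, tr, k, ok, rel = _apgd_single(
            BU, Bmat[:, t], tau, cfg.lam, cfg.tol, cfg.max_iter, c0
        )
        C[:, t] = c
        traces.append(tr)
        iters[t] = k
        conv[t] = ok
        rels[t] = rel
    X = U @ C
    x_out = X[:, 0] if (isinstance(rec, SensorRecording) and rec.b.ndim == 1) or (
        not isinstance(rec, SensorRecording) and np.asarray(rec).ndim == 1
    ) else X
    return ReconstructionResult(
        x_hat=x_out,
        x_hat_normalized=x_out,
        objective_traces=traces,
        n_iter=iters,
        converged=conv,
        relative_change=rels,
        lam=cfg.lam,
        method_tag="cset",
    )


def rescale_solution(
    x_norm: np.ndarray, column_norms: np.ndarray, b_scale: float | np.ndarray
) -> np.ndarray:
    """Undo the depth and recording normalizations: x_i = x_norm_i * b_scale / ||A_i||."""
    x_norm = np.asarray(x_norm, dtype=float)
    column_norms = np.asarray(column_norms, dtype=float)
    if np.any(column_norms <= 0):
        raise ValueError("column norms must be positive")
    b_scale = np.asarray(b_scale, dtype=float)
    if np.any(b_scale <= 0):
        raise ValueError("b_scale must be positive")
    if x_norm.ndim == 1:
        return x_norm * float(b_scale) / column_norms
    return x_norm * b_scale[None, :] / column_norms[:, None]


def solve_cset(
    lf: LeadField,
    rec: SensorRecording,
    basis: SpectralBasis,
    cfg: SolverConfig,
) -> ReconstructionResult:
    """Full reconstruction pipeline: depth-normalize the lead field,
    unit-normalize the recording, run APGD, rescale back to physical units."""
    lf_n = depth_normalize(lf)
    rec_n, scales = normalize_recording(rec)
    res = apgd_solve(lf_n, rec_n, basis, cfg)
    b_scale = float(scales[0]) if rec.b.ndim == 1 else scales
    res.x_hat = rescale_solution(
        res.x_hat_normalized, lf_n.depth_reference_norms, b_scale
    )
    return res
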
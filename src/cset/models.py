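"""Model/Results interface over the inverse solvers.

Each model is constructed from data (a sensor recording plus a lead field,
and for the spectral method a harmonic basis); ``fit()`` returns a
:class:`SourceReconstructionResults` carrying the source estimate,
convergence diagnostics, and a ``summary()`` table.  ``fit_grid()`` selects
the regularization weight on the study's log-spaced grid against a scoring
function (r^2 against a reference map in simulations).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from . import baselines as _bl
from .evaluation import (
    DEFAULT_GRID_HI,
    DEFAULT_GRID_LO,
    DEFAULT_GRID_N,
    lambda_grid_search,
    r_squared,
)
from .forward import LeadField, NoiseModel, SensorRecording
from .graph import SpectralBasis
from .solver import ReconstructionResult, SolverConfig, solve_cset
from .synthetic import Scenario


class SourceReconstructionResults:
    """Fitted source estimate with diagnostics.

    Attributes
    ----------
    params : ndarray
        The estimated source map (N-vector or N x T), physical scale.
    """

    def __init__(self, model, raw: ReconstructionResult,
                 lam_star: float | None = None,
                 grid_table: pd.DataFrame | None = None):
        self.model = model
        self._raw = raw
        self.params = raw.x_hat
        self.lam = raw.lam if lam_star is None else lam_star
        self.grid_table = grid_table

    @property
    def x_hat(self) -> np.ndarray:
        return self.params

    @property
    def x_hat_normalized(self) -> np.ndarray | None:
        return self._raw.x_hat_normalized

    @property
    def objective_trace(self) -> np.ndarray | None:
        return self._raw.objective_trace

    @property
    def n_iter(self):
        return self._raw.n_iter

    @property
    def converged(self):
        return self._raw.converged

    def score(self, truth: np.ndarray) -> float:
        """r^2 of the estimate against a reference source map."""
        return r_squared(truth, self.params)

    def summary(self, truth: np.ndarray | None = None) -> str:
        lines = [
            "Source reconstruction results",
            "=" * 34,
            f"method:        {self._raw.method_tag}",
            f"sensors (M):   {self.model.leadfield.n_sensors}",
            f"sources (N):   {self.model.leadfield.n_sources}",
            f"lambda:        {self.lam:.6g}" if self.lam is not None else "lambda:        n/a",
        ]
        if self._raw.n_iter is not None:
            lines.append(f"iterations:    {int(np.max(self._raw.n_iter))}")
            lines.append(f"converged:     {bool(np.all(self._raw.converged))}")
        if self._raw.objective_trace is not None:
            lines.append(f"objective:     {self._raw.objective_trace[-1]:.6g}")
        if truth is not None:
            lines.append(f"r2 vs truth:   {self.score(truth):.4f}")
        return "\n".join(lines)


class _InverseModel:
    """Shared constructor/grid machinery for all inverse models."""

    method_tag: str = ""

    def __init__(self, recording: SensorRecording, leadfield: LeadField):
        if recording.n_sensors != leadfield.n_sensors:
            raise ValueError("recording and lead field disagree on sensor count")
        self.recording = recording
        self.leadfield = leadfield

    def _solve(self, lam: float) -> ReconstructionResult:  # pragma: no cover
        raise NotImplementedError

    def fit(self, lam: float) -> SourceReconstructionResults:
        return SourceReconstructionResults(self, self._solve(lam))

    def fit_grid(
        self,
        score: Callable[[np.ndarray], float] | None = None,
        truth: np.ndarray | None = None,
        grid_lo: float = DEFAULT_GRID_LO,
        grid_hi: float = DEFAULT_GRID_HI,
        n: int = DEFAULT_GRID_N,
    ) -> SourceReconstructionResults:
        """Fit over the log-spaced lambda grid, keep the best-scoring fit.

        Either a ``score(estimate)`` callable or a reference ``truth`` map
        (scored by r^2) must be given.
        """
        if score is None:
            if truth is None:
                raise ValueError("provide a score function or a truth map")
            score = lambda est: r_squared(truth, est)  # noqa: E731
        lam_star, table = lambda_grid_search(
            lambda lam: self._solve(lam).x_hat,
            grid_lo=grid_lo, grid_hi=grid_hi, n=n, score=score,
        )
        res = self._solve(lam_star)
        return SourceReconstructionResults(self, res, lam_star=lam_star,
                                           grid_table=table)


class ConnectomeSpectrumTomography(_InverseModel):
    """Spectral-sparsity source reconstruction (the CSET estimator).

    Minimizes ||b - A x||^2 + lam ||U^T x||_1 after depth normalization of A
    and unit normalization of b, then rescales to physical units.
    """

    method_tag = "cset"

    def __init__(
        self,
        recording: SensorRecording,
        leadfield: LeadField,
        basis: SpectralBasis,
        tol: float = 1e-4,
        max_iter: int = 10_000,
    ):
        super().__init__(recording, leadfield)
        if basis.n_vertices != leadfield.n_sources:
            raise ValueError("basis and lead field disagree on source count")
        self.basis = basis
        self.tol = tol
        self.max_iter = max_iter

    @classmethod
    def from_scenario(cls, scenario: Scenario, **kw) -> "ConnectomeSpectrumTomography":
        return cls(scenario.recording, scenario.leadfield, scenario.basis, **kw)

    def _solve(self, lam: float) -> ReconstructionResult:
        cfg = SolverConfig(lam=lam, tol=self.tol, max_iter=self.max_iter)
        return solve_cset(self.leadfield, self.recording, self.basis, cfg)


class _BaselineModel(_InverseModel):
    """Baselines run on the raw lead field by default; ``share_depth_norm``
    applies the spectral method's per-source unit normalization instead."""

    def __init__(self, recording: SensorRecording, leadfield: LeadField,
                 noise: NoiseModel, share_depth_norm: bool = False):
        if share_depth_norm:
            from .forward import depth_normalize

            leadfield = depth_normalize(leadfield)
        super().__init__(recording, leadfield)
        if noise.sigma <= 0:
            raise ValueError("baseline solvers need a positive noise sigma")
        self.noise = noise

    @classmethod
    def from_scenario(cls, scenario: Scenario, **kw):
        noise = scenario.noise
        if noise.sigma <= 0:
            noise = NoiseModel(sigma=1.0, n_sensors=scenario.recording.n_sensors)
        return cls(scenario.recording, scenario.leadfield, noise, **kw)

    def _solve(self, lam: float) -> ReconstructionResult:
        return _bl.BASELINE_SOLVERS[self.method_tag](
            self.leadfield, self.recording, self.noise, lam
        )


class MinimumNorm(_BaselineModel):
    """Tikhonov minimum-norm estimate (MNE)."""

    method_tag = "mne"


class DSPM(_BaselineModel):
    """Noise-normalized minimum norm (dSPM)."""

    method_tag = "dspm"


class SLORETA(_BaselineModel):
    """Resolution-standardized minimum norm (sLORETA)."""

    method_tag = "sloreta"


MODEL_REGISTRY = {
    "cset": ConnectomeSpectrumTomography,
    "mne": MinimumNorm,
    "dspm": DSPM,
    "sloreta": SLORETA,
}
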
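"""Synthetic cortex, connectome, lead field and simulation scenarios.

Everything the reconstruction pipeline consumes can be generated here with no
external data: a near-uniform triangulated sphere standing in for the cortical
surface, a sparse integer-weighted connectome whose long-range edges prefer
distant vertex pairs (emulating streamline counts), an analytic dipole lead
field with sensors on an outer sphere, ground-truth source maps that are
sparse in the connectome spectrum, and Gaussian sensor noise at a stated SNR.

What this emulates and what it does not: the geometry is a convex sphere, not
a folded cortex, so there is no sulcal depth variation or source cancellation
from opposing walls; the lead field is a homogeneous-medium dipole model, not
a layered head; noise is i.i.d. across sensors.  Defaults (N = 800 vertices,
M = 64 sensors, 5 active harmonics, 3 dB SNR) are a desk-scale stand-in for
the ~8000-node / 128-electrode setting of high-resolution EEG studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import ConvexHull

from .forward import (
    LeadField,
    NoiseModel,
    SensorRecording,
    add_noise_at_snr,
    map_to_source_activity,
    project_forward,
    synth_leadfield,
)
from .graph import ConnectomeGraph, SpectralBasis, combine_short_long_range, spectral_basis


@dataclass
class Mesh:
    """Closed triangulated surface with outward unit vertex normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected mesh edges as an (E, 2) index array."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)


@dataclass
class Scenario:
    """A complete simulated recording session."""

    graph: ConnectomeGraph
    basis: SpectralBasis
    leadfield: LeadField
    truth: np.ndarray
    truth_coeffs: np.ndarray | None
    recording: SensorRecording
    recording_clean: SensorRecording
    noise: NoiseModel
    seed: int
    params: dict = field(default_factory=dict)


def _fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Near-uniform points on a sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return radius * pts


def make_synthetic_cortex(
    n_vertices: int,
    seed: int | np.random.Generator = 0,
    radius: float = 80.0,
    jitter: float = 0.02,
) -> Mesh:
    """Near-uniform triangulated sphere with outward unit normals.

    Points are placed on a golden-angle lattice, jittered tangentially (so the
    mesh stays convex and every vertex stays on the hull), and triangulated by
    the convex hull; the result is a closed 2-sphere mesh (V - E + F = 2) at
    any requested vertex count >= 12.
    """
    if n_vertices < 12:
        raise ValueError("at least 12 vertices required")
    rng = np.random.default_rng(seed)
    pts = _fibonacci_sphere(n_vertices, 1.0)
    if jitter > 0:
        pts = pts + jitter * rng.normal(size=pts.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    hull = ConvexHull(pts)
    if len(hull.vertices) != n_vertices:
        # extremely unlikely for points on a sphere; regenerate without jitter
        pts = _fibonacci_sphere(n_vertices, 1.0)
        hull = ConvexHull(pts)
    vertices = pts * radius
    normals = pts.copy()  # radial outward normals for a sphere-like surface
    return Mesh(vertices=vertices, faces=hull.simplices.copy(), normals=normals)


def _gumbel_topk(log_weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sample k indices without replacement with probability proportional to
    exp(log_weights) via the Gumbel top-k trick (fast and seed-stable)."""
    g = rng.gumbel(size=log_weights.size)
    return np.argpartition(-(log_weights + g), k - 1)[:k]


def sample_long_range_edges(
    mesh: Mesh,
    n_long_range: int,
    weight_scale: float = 20.0,
    seed: int | np.random.Generator = 0,
    distance_exponent: float = 2.0,
) -> sp.csr_matrix:
    """Symmetric sparse matrix of long-range edges with integer weights.

    Vertex pairs are sampled preferentially at large Euclidean distance
    (probability ~ d^distance_exponent); weights are positive integers drawn
    from a geometric distribution of mean ``weight_scale``, emulating
    streamline counts.
    """
    if n_long_range < 0:
        raise ValueError("n_long_range must be nonnegative")
    rng = np.random.default_rng(seed)
    n = mesh.n_vertices
    if n_long_range == 0:
        return sp.csr_matrix((n, n))
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(mesh.vertices[iu] - mesh.vertices[ju], axis=1)
    logw = distance_exponent * np.log(np.maximum(d, 1e-12))
    k = min(n_long_range, iu.size)
    pick = _gumbel_topk(logw, k, rng)
    weights = rng.geometric(min(1.0, 1.0 / weight_scale), size=k).astype(float)
    W = sp.coo_matrix((weights, (iu[pick], ju[pick])), shape=(n, n))
    return (W + W.T).tocsr()


def make_synthetic_connectome(
    mesh: Mesh,
    n_long_range: int = 1600,
    weight_scale: float = 20.0,
    seed: int | np.random.Generator = 0,
    mix_ratio: float = 1.0,
    short_range_sigma: float | None = None,
    distance_exponent: float = 2.0,
) -> ConnectomeGraph:
    """Sparse integer-weighted connectome on a synthetic cortex.

    Short-range edges are the mesh edges (Gaussian distance kernel); long-range
    edges come from :func:`sample_long_range_edges`; the two edge sets are
    combined after per-set normalization to unit mean edge weight.
    """
    W_long = sample_long_range_edges(
        mesh, n_long_range, weight_scale=weight_scale, seed=seed,
        distance_exponent=distance_exponent,
    )
    return combine_short_long_range(
        mesh.vertices,
        W_long,
        mesh.edges(),
        short_range_sigma=short_range_sigma,
        mix_ratio=mix_ratio,
    )


def make_sparse_spectrum_source(
    basis: SpectralBasis,
    k_active: int,
    amplitude_decay: float = 0.8,
    seed: int | np.random.Generator = 0,
    rank_bias: float = 2.0,
    return_coeffs: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Source map with exactly ``k_active`` nonzero graph Fourier coefficients.

    Active harmonics are drawn with probability ~ 1/(1 + rank)^rank_bias (a
    low-graph-frequency bias, matching the smoothness of real activity maps);
    amplitudes decay geometrically with random signs.
    """
    n = basis.n_vertices
    if not 1 <= k_active <= n:
        raise ValueError("k_active must be in [1, N]")
    rng = np.random.default_rng(seed)
    logw = -rank_bias * np.log1p(np.arange(n, dtype=float))
    idx = np.sort(_gumbel_topk(logw, k_active, rng))
    amps = amplitude_decay ** np.arange(k_active)
    signs = rng.choice([-1.0, 1.0], size=k_active)
    coeffs = np.zeros(n)
    coeffs[idx] = signs * amps
    x = basis.U @ coeffs
    return (x, coeffs) if return_coeffs else x


def make_scenario(
    n_vertices: int = 800,
    n_sensors: int = 64,
    k_active: int = 5,
    snr_db: float = 3.0,
    seed: int = 0,
    n_long_range: int | None = None,
    weight_scale: float = 20.0,
    mix_ratio: float = 1.0,
    nonnegative: bool = True,
    rank_bias: float = 2.0,
    mismatched_truth_basis: bool = False,
    conductivity: float = 0.33,
    source_radius: float = 80.0,
    sensor_radius: float = 100.0,
) -> Scenario:
    """End-to-end simulated session: cortex -> connectome -> harmonics ->
    lead field -> planted sparse-spectrum truth -> forward projection ->
    sensor noise at ``snr_db``.  Fully reproducible from ``seed``.

    By default the truth map is standardized and shifted to be nonnegative
    (the shaping applied to statistical activation maps before forward
    projection); ``nonnegative=False`` keeps the raw signed sparse-spectrum
    map (whose graph Fourier coefficients are exactly k_active-sparse).  With
    ``mismatched_truth_basis=True`` the truth is sparse in the harmonics of a
    connectome with independently re-sampled long-range edges, while the
    scenario's reconstruction basis stays that of the observed connectome
    (a robustness probe).
    """
    ss = np.random.SeedSequence(seed)
    s_mesh, s_conn, s_src, s_noise, s_alt = [int(s) for s in ss.generate_state(5)]
    if n_long_range is None:
        n_long_range = 2 * n_vertices
    mesh = make_synthetic_cortex(n_vertices, seed=s_mesh, radius=source_radius)
    graph = make_synthetic_connectome(
        mesh, n_long_range=n_long_range, weight_scale=weight_scale,
        seed=s_conn, mix_ratio=mix_ratio,
    )
    basis = spectral_basis(graph)
    sensors = _fibonacci_sphere(n_sensors, sensor_radius)
    lf = synth_leadfield(mesh.vertices, mesh.normals, sensors, conductivity)

    if mismatched_truth_basis:
        alt_graph = make_synthetic_connectome(
            mesh, n_long_range=n_long_range, weight_scale=weight_scale,
            seed=s_alt, mix_ratio=mix_ratio,
        )
        truth_basis = spectral_basis(alt_graph)
    else:
        truth_basis = basis
    truth, coeffs = make_sparse_spectrum_source(
        truth_basis, k_active, seed=s_src, rank_bias=rank_bias, return_coeffs=True
    )
    if nonnegative:
        truth = map_to_source_activity(truth)
        coeffs = None
    rec_clean = project_forward(lf, truth)
    rec, noise = add_noise_at_snr(rec_clean, snr_db, seed=s_noise)
    return Scenario(
        graph=graph,
        basis=basis,
        leadfield=lf,
        truth=truth,
        truth_coeffs=coeffs,
        recording=rec,
        recording_clean=rec_clean,
        noise=noise,
        seed=seed,
        params={
            "n_vertices": n_vertices,
            "n_sensors": n_sensors,
            "k_active": k_active,
            "snr_db": snr_db,
            "n_long_range": n_long_range,
            "weight_scale": weight_scale,
            "mix_ratio": mix_ratio,
            "nonnegative": nonnegative,
            "rank_bias": rank_bias,
            "mismatched_truth_basis": mismatched_truth_basis,
            "noise_seed": s_noise,
        },
    )
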
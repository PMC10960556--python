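"""Structural connectome graphs, normalized Laplacian, and the graph Fourier transform.

The structural connectome is modelled as an undirected weighted graph whose
vertices are points on the cortical surface and whose edge weights combine
long-range white-matter connectivity (streamline counts) with short-range
cortical neighbourhood connectivity (a Gaussian kernel of Euclidean distance
restricted to mesh edges).  The *connectome harmonics* are the eigenvectors of
the symmetric normalized graph Laplacian

    L = I - D^{-1/2} W D^{-1/2} = U diag(lambda) U^T,

ordered by ascending eigenvalue; projecting a vertex-domain signal onto them
is the graph Fourier transform (GFT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


@dataclass
class ConnectomeGraph:
    """A vertex-embedded undirected weighted graph.

    Parameters
    ----------
    coords : (N, 3) float array
        Vertex positions in mm.
    W : (N, N) array or sparse matrix
        Symmetric nonnegative weight matrix with zero diagonal.  Long-range
        entries are in streamline-count units, short-range entries are
        dimensionless kernel values.
    node_labels : sequence of str, optional
        Per-vertex identifiers.
    """

    coords: np.ndarray
    W: sp.spmatrix | np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        W = sp.csr_matrix(self.W) if not sp.issparse(self.W) else self.W.tocsr()
        W = W.astype(float)
        if W.shape != (self.n_vertices, self.n_vertices):
            raise ValueError("W must be N x N with N = len(coords)")
        if (abs(W - W.T) > 1e-10 * max(1.0, abs(W).max())).nnz > 0:
            raise ValueError("W must be symmetric")
        if W.diagonal().any():
            raise ValueError("W must have zero diagonal")
        if W.nnz and W.data.min() < 0:
            raise ValueError("edge weights must be nonnegative")
        self.W = W
        n_comp, _ = connected_components(W, directed=False)
        if n_comp != 1:
            raise ValueError(
                f"connectome graph must be connected; found {n_comp} components"
            )

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def degrees(self) -> np.ndarray:
        """Weighted vertex degrees (row sums of W)."""
        return np.asarray(self.W.sum(axis=1)).ravel()


@dataclass
class SpectralBasis:
    """Orthonormal connectome-harmonic basis.

    Harmonics are the columns of ``U`` ordered by ascending eigenvalue of the
    normalized Laplacian; eigenvalues lie in [0, 2] and the first is 0 for a
    connected graph.
    """

    U: np.ndarray
    eigvals: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.eigvals = np.asarray(self.eigvals, dtype=float)
        n = self.U.shape[0]
        if self.U.shape != (n, n) or self.eigvals.shape != (n,):
            raise ValueError("U must be N x N and eigvals length N")
        if np.any(np.diff(self.eigvals) < -1e-10):
            raise ValueError("eigenvalues must be sorted ascending")

    @property
    def n_vertices(self) -> int:
        return self.U.shape[0]


def _unit_mean_edge_weight(W: sp.spmatrix) -> sp.spmatrix:
    """Rescale a symmetric weight matrix so its mean (off-diagonal, nonzero)
    edge weight is 1.  Each undirected edge is counted once."""
    Wu = sp.triu(W, k=1)
    if Wu.nnz == 0:
        return W.copy()
    return W / Wu.data.mean()


def short_range_weights(
    coords: np.ndarray, mesh_edges: np.ndarray, sigma: float
) -> sp.csr_matrix:
    """Gaussian kernel of Euclidean distance on mesh edges.

    weight(i, j) = exp(-d_ij^2 / (2 sigma^2)) for each mesh edge (i, j).
    """
    coords = np.asarray(coords, dtype=float)
    edges = np.asarray(mesh_edges, dtype=int)
    if edges.size == 0:
        n = coords.shape[0]
        return sp.csr_matrix((n, n))
    if edges.min() < 0 or edges.max() >= coords.shape[0]:
        raise ValueError("mesh_edges reference invalid vertices")
    if sigma <= 0:
        raise ValueError("short_range_sigma must be positive")
    if np.any(edges[:, 0] == edges[:, 1]):
        raise ValueError("mesh_edges must not contain self-loops")
    # deduplicate undirected edges so repeated face edges are counted once
    canon = np.sort(edges, axis=1)
    canon = np.unique(canon, axis=0)
    d = np.linalg.norm(coords[canon[:, 0]] - coords[canon[:, 1]], axis=1)
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    n = coords.shape[0]
    i, j = canon[:, 0], canon[:, 1]
    S = sp.coo_matrix((w, (i, j)), shape=(n, n))
    return (S + S.T).tocsr()


def combine_short_long_range(
    coords: np.ndarray,
    long_range_W: sp.spmatrix | np.ndarray,
    mesh_edges: np.ndarray,
    short_range_sigma: float | None = None,
    mix_ratio: float = 1.0,
    node_labels: list[str] | None = None,
) -> ConnectomeGraph:
    """Combine long-range (tractography-like) and short-range (mesh-distance)
    edge sets into a single connectome graph.

    Each edge set is rescaled to unit mean edge weight and combined as

        W = normalize(long_range_W) + mix_ratio * normalize(short_range_W).

    Parameters
    ----------
    short_range_sigma : float, optional
        Gaussian kernel bandwidth (mm); default is the mean mesh edge length.
    mix_ratio : float
        Relative weight of the short-range edge set (>= 0).
    """
    coords = np.asarray(coords, dtype=float)
    if mix_ratio < 0:
        raise ValueError("mix_ratio must be nonnegative")
    L = sp.csr_matrix(long_range_W) if not sp.issparse(long_range_W) else long_range_W.tocsr()
    if L.nnz and L.data.min() < 0:
        raise ValueError("long-range weights must be nonnegative")
    W = _unit_mean_edge_weight(L)
    if mix_ratio > 0:
        edges = np.asarray(mesh_edges, dtype=int)
        if short_range_sigma is None:
            if edges.size == 0:
                raise ValueError("mesh_edges required when mix_ratio > 0")
            d = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
            short_range_sigma = float(d.mean())
        S = short_range_weights(coords, edges, short_range_sigma)
        W = W + mix_ratio * _unit_mean_edge_weight(S)
    W = sp.csr_matrix(W)
    W.setdiag(0)
    W.eliminate_zeros()
    return ConnectomeGraph(coords=coords, W=W, node_labels=node_labels)


def normalized_laplacian(g: ConnectomeGraph) -> np.ndarray:
    """Symmetric normalized graph Laplacian L = I - D^{-1/2} W D^{-1/2}."""
    deg = g.degrees()
    if np.any(deg <= 0):
        bad = int(np.flatnonzero(deg <= 0)[0])
        raise ValueError(f"isolated vertex (zero degree) at index {bad}")
    d_isqrt = 1.0 / np.sqrt(deg)
    W = g.W.toarray()
    L = -W * d_isqrt[:, None] * d_isqrt[None, :]
    np.fill_diagonal(L, 1.0)
    # exact symmetry for the eigensolver
    return 0.5 * (L + L.T)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: flip each column so its entry of largest
    absolute value is positive; ties broken by the lowest vertex index."""
    # argmax of |U| per column; np.argmax breaks ties at the lowest index
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def eigendecompose(L: np.ndarray, symmetry_tol: float = 1e-10) -> SpectralBasis:
    """Full eigendecomposition of a symmetric matrix into a SpectralBasis.

    Eigenvalues are returned in ascending order and eigenvector signs follow a
    deterministic convention so spectra are reproducible across linear-algebra
    backends.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("L must be square")
    scale = max(1.0, np.abs(L).max())
    if np.abs(L - L.T).max() > symmetry_tol * scale:
        raise ValueError("L must be symmetric")
    eigvals, U = np.linalg.eigh(0.5 * (L + L.T))
    return SpectralBasis(U=_fix_signs(U), eigvals=eigvals)


def spectral_basis(g: ConnectomeGraph) -> SpectralBasis:
    """Convenience: normalized Laplacian eigendecomposition of a graph."""
    return eigendecompose(normalized_laplacian(g))


def gft(basis: SpectralBasis, x: np.ndarray) -> np.ndarray:
    """Graph Fourier transform: spectral coefficients U^T x.

    ``x`` may be an N-vector or an N x T matrix (transformed column-wise).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != basis.n_vertices:
        raise ValueError(
            f"signal length {x.shape[0]} != number of vertices {basis.n_vertices}"
        )
    return basis.U.T @ x


def igft(basis: SpectralBasis, coeffs: np.ndarray) -> np.ndarray:
    """Inverse graph Fourier transform: U @ coeffs."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[0] != basis.n_vertices:
        raise ValueError(
            f"coefficient length {coeffs.shape[0]} != number of vertices "
            f"{basis.n_vertices}"
        )
    return basis.U @ coeffs
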
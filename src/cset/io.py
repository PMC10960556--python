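"""Readers/writers for connectomes, lead fields, recordings and bases.

Two formats per object: a single-file binary container of named arrays
(NumPy ``.npz``) that round-trips at full precision, and plain-text formats
for inspection — sparse coordinate triplets (``i j weight``, 0-based) for
connectome weights, and delimited tables with a sensor-label header for
recordings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .forward import LeadField, SensorRecording
from .graph import ConnectomeGraph, SpectralBasis


# ---------------------------------------------------------------------------
# connectome

def write_connectome(path: str | Path, g: ConnectomeGraph) -> None:
    """Write a connectome to a binary container (coords, sparse W, labels)."""
    W = g.W.tocoo()
    labels = np.asarray(g.node_labels if g.node_labels is not None else [], dtype=str)
    np.savez(
        path,
        kind="connectome",
        coords=g.coords,
        w_row=W.row,
        w_col=W.col,
        w_data=W.data,
        n=g.n_vertices,
        labels=labels,
    )


def read_connectome(path: str | Path) -> ConnectomeGraph:
    with np.load(path, allow_pickle=False) as z:
        n = int(z["n"])
        W = sp.coo_matrix((z["w_data"], (z["w_row"], z["w_col"])), shape=(n, n))
        labels = [str(s) for s in z["labels"]] if z["labels"].size else None
        return ConnectomeGraph(coords=z["coords"], W=W.tocsr(), node_labels=labels)


def write_connectome_triplets(path: str | Path, g: ConnectomeGraph) -> None:
    """Write edge weights as text triplets ``i j weight`` (0-based, upper
    triangle once per undirected edge)."""
    W = sp.triu(g.W, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write(f"# n_vertices {g.n_vertices}\n")
        for i, j, w in zip(W.row, W.col, W.data):
            fh.write(f"{i} {j} {float(w)!r}\n")


def read_connectome_triplets(
    path: str | Path, coords: np.ndarray
) -> ConnectomeGraph:
    """Read a text triplet edge list; vertex positions supplied separately."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    rows, cols, data = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed triplet at line {lineno}: {line!r}")
            try:
                i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise ValueError(
                    f"malformed triplet at line {lineno}: {line!r}"
                ) from None
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"vertex index out of range at line {lineno}")
            rows.append(i)
            cols.append(j)
            data.append(w)
    W = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    W = W + W.T
    return ConnectomeGraph(coords=coords, W=W.tocsr())


# ---------------------------------------------------------------------------
# lead field

def write_leadfield(path: str | Path, lf: LeadField) -> None:
    np.savez(
        path,
        kind="leadfield",
        A=lf.A,
        sensor_positions=(
            lf.sensor_positions if lf.sensor_positions is not None else np.zeros((0, 3))
        ),
        sensor_labels=np.asarray(lf.sensor_labels, dtype=str),
        reference=lf.reference,
        depth_reference_norms=(
            lf.depth_reference_norms
            if lf.depth_reference_norms is not None
            else np.zeros(0)
        ),
    )


def read_leadfield(path: str | Path) -> LeadField:
    with np.load(path, allow_pickle=False) as z:
        pos = z["sensor_positions"]
        norms = z["depth_reference_norms"]
        return LeadField(
            A=z["A"],
            sensor_positions=pos if pos.size else None,
            sensor_labels=[str(s) for s in z["sensor_labels"]],
            reference=str(z["reference"]),
            depth_reference_norms=norms if norms.size else None,
        )


# ---------------------------------------------------------------------------
# recordings

def write_recording(path: str | Path, rec: SensorRecording) -> None:
    np.savez(
        path,
        kind="recording",
        b=rec.b,
        times=rec.times if rec.times is not None else np.zeros(0),
        montage_ids=np.asarray(rec.montage_ids, dtype=str),
    )


def read_recording(path: str | Path) -> SensorRecording:
    with np.load(path, allow_pickle=False) as z:
        times = z["times"]
        return SensorRecording(
            b=z["b"],
            times=times if times.size else None,
            montage_ids=[str(s) for s in z["montage_ids"]],
        )


def write_recording_text(path: str | Path, rec: SensorRecording,
                         delimiter: str = "\t") -> None:
    """Delimited text: header row of sensor labels, one row per time point,
    first column the time stamp."""
    B = rec.as_matrix()
    times = rec.times if rec.times is not None else np.arange(rec.n_times, dtype=float)
    with open(path, "w") as fh:
        fh.write(delimiter.join(["time"] + list(rec.montage_ids)) + "\n")
        for t in range(B.shape[1]):
            row = [repr(float(times[t]))] + [repr(float(v)) for v in B[:, t]]
            fh.write(delimiter.join(row) + "\n")


def read_recording_text(path: str | Path, delimiter: str = "\t") -> SensorRecording:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        if not header or header[0] != "time":
            raise ValueError("recording text file must start with a 'time' header")
        labels = header[1:]
        times, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(delimiter)
            if len(parts) != len(labels) + 1:
                raise ValueError(f"ragged row at line {lineno}")
            times.append(float(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    B = np.asarray(rows, dtype=float).T  # (M, T)
    t = np.asarray(times)
    if B.shape[1] == 1:
        return SensorRecording(b=B[:, 0], times=t, montage_ids=labels)
    return SensorRecording(b=B, times=t, montage_ids=labels)


# ---------------------------------------------------------------------------
# spectral basis

def write_basis(path: str | Path, basis: SpectralBasis) -> None:
    np.savez(path, kind="basis", U=basis.U, eigvals=basis.eigvals)


def read_basis(path: str | Path) -> SpectralBasis:
    with np.load(path, allow_pickle=False) as z:
        return SpectralBasis(U=z["U"], eigvals=z["eigvals"])


# ---------------------------------------------------------------------------
# meshes (ASCII OFF)

def write_off(path: str | Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(vertices)} {len(faces)} 0\n")
        for v in vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in faces:
            fh.write("3 " + " ".join(str(i) for i in f) + "\n")


def read_off(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines or lines[0] != "OFF":
        raise ValueError("not an ASCII OFF file")
    nv, nf, _ = (int(x) for x in lines[1].split())
    verts = np.array([[float(x) for x in ln.split()] for ln in lines[2 : 2 + nv]])
    faces = []
    for ln in lines[2 + nv : 2 + nv + nf]:
        parts = [int(x) for x in ln.split()]
        if parts[0] != 3:
            raise ValueError("only triangular faces supported")
        faces.append(parts[1:4])
    return verts, np.asarray(faces, dtype=int)
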
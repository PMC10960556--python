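"""Forward model: synthetic dipole lead field, normalizations, and EEG simulation.

The lead field A maps N normally-oriented cortical current dipoles to M scalp
sensors.  The synthetic lead field uses the infinite-homogeneous-medium dipole
potential

    V(r) = (1 / 4 pi sigma) * p . (r - r0) / |r - r0|^3,

with a unit dipole moment p along each vertex normal, followed by
common-average referencing (every column of A sums to zero).  Two
normalizations precede source reconstruction: per-source (depth)
unit-normalization of the lead-field columns, and per-time-point unit L2
normalization of the recording; the solution is rescaled afterwards so the
estimate is on the physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LeadField:
    """M x N gain matrix with sensor geometry and referencing metadata.

    ``column_norms`` caches the L2 norm of each source column of the *current*
    A.  After :func:`depth_normalize` these are all 1 and the pre-normalization
    norms are kept in ``depth_reference_norms`` for the final rescaling.
    """

    A: np.ndarray
    sensor_positions: np.ndarray | None = None
    sensor_labels: list[str] | None = None
    reference: str = "common-average"
    depth_reference_norms: np.ndarray | None = None
    column_norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be an M x N matrix")
        self.column_norms = np.linalg.norm(self.A, axis=0)
        if np.any(self.column_norms == 0):
            bad = int(np.flatnonzero(self.column_norms == 0)[0])
            raise ValueError(f"lead field has an all-zero source column ({bad})")
        if self.sensor_labels is None:
            self.sensor_labels = [f"S{i:03d}" for i in range(self.A.shape[0])]
        if len(self.sensor_labels) != self.A.shape[0]:
            raise ValueError("one label per sensor required")

    @property
    def n_sensors(self) -> int:
        return self.A.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A.shape[1]


@dataclass
class SensorRecording:
    """Sensor potentials: M-vector (single time point) or M x T matrix."""

    b: np.ndarray
    times: np.ndarray | None = None
    montage_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if self.b.ndim not in (1, 2):
            raise ValueError("b must be a vector or an M x T matrix")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("recording contains non-finite values")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.ndim != 1 or self.times.size != self.n_times:
                raise ValueError("times must be a T-vector")
            if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
        if self.montage_ids is None:
            self.montage_ids = [f"S{i:03d}" for i in range(self.n_sensors)]
        if len(self.montage_ids) != self.n_sensors:
            raise ValueError("one montage id per sensor required")

    @property
    def n_sensors(self) -> int:
        return self.b.shape[0]

    @property
    def n_times(self) -> int:
        return 1 if self.b.ndim == 1 else self.b.shape[1]

    def as_matrix(self) -> np.ndarray:
        """The data as an M x T matrix (T = 1 for a single time point)."""
        return self.b[:, None] if self.b.ndim == 1 else self.b


@dataclass
class NoiseModel:
    """I.i.d. Gaussian sensor noise with covariance sigma^2 * I."""

    sigma: float
    n_sensors: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def covariance(self) -> np.ndarray:
        return self.sigma**2 * np.eye(self.n_sensors)


def common_average_reference(A: np.ndarray) -> np.ndarray:
    """Remove the across-sensor mean from each column (idempotent projection)."""
    return A - A.mean(axis=0, keepdims=True)


def dipole_potentials(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_pos: np.ndarray,
    conductivity: float,
) -> np.ndarray:
    """Infinite homogeneous medium potential of point dipoles at sensors.

    Returns an (n_sensors, n_dipoles) matrix.
    """
    r = sensor_pos[:, None, :] - dipole_pos[None, :, :]  # (M, N, 3)
    dist = np.linalg.norm(r, axis=2)
    if np.any(dist == 0):
        raise ValueError("sensor coincident with a source vertex")
    num = np.einsum("mnk,nk->mn", r, dipole_moment)
    return num / (4.0 * np.pi * conductivity * dist**3)


def synth_leadfield(
    vertices: np.ndarray,
    normals: np.ndarray,
    sensors: np.ndarray,
    conductivity: float = 0.33,
    sensor_labels: list[str] | None = None,
) -> LeadField:
    """Analytic dipole lead field for normally oriented unit sources.

    Sources sit at mesh ``vertices`` with unit dipole moments along
    ``normals``; sensors must lie strictly outside the source surface.  The
    result is common-average referenced.
    """
    vertices = np.asarray(vertices, dtype=float)
    normals = np.asarray(normals, dtype=float)
    sensors = np.asarray(sensors, dtype=float)
    norms = np.linalg.norm(normals, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("normals must be unit length")
    r_src = np.linalg.norm(vertices, axis=1).max()
    r_sen = np.linalg.norm(sensors, axis=1).min()
    if r_sen <= r_src:
        raise ValueError("sensors must lie strictly outside the source surface")
    A = dipole_potentials(vertices, normals, sensors, conductivity)
    A = common_average_reference(A)
    return LeadField(
        A=A,
        sensor_positions=sensors,
        sensor_labels=sensor_labels,
        reference="common-average",
    )


def depth_normalize(lf: LeadField) -> LeadField:
    """Unit-normalize each source column of the lead field (depth weighting).

    Least-squares inverses favour superficial sources whose gain vectors have
    large norms; dividing each per-source gain vector by its L2 norm removes
    that bias.  The original norms are retained on the result
    (``depth_reference_norms``) so the solution can be rescaled back to
    physical units.
    """
    norms = np.linalg.norm(lf.A, axis=0)
    if np.any(norms == 0):
        raise ValueError("cannot depth-normalize a zero source column")
    return LeadField(
        A=lf.A / norms,
        sensor_positions=lf.sensor_positions,
        sensor_labels=lf.sensor_labels,
        reference=lf.reference,
        depth_reference_norms=norms,
    )


def normalize_recording(rec: SensorRecording) -> tuple[SensorRecording, np.ndarray]:
    """Unit-normalize each time-point vector; return the recording and scales.

    Makes the choice of the regularization weight independent of the
    measurement scale; the per-time-point L2 norms are returned for the final
    rescaling.
    """
    B = rec.as_matrix()
    scales = np.linalg.norm(B, axis=0)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        raise ValueError(f"zero recording vector at time index {int(zero[0])}")
    Bn = B / scales
    b_out = Bn[:, 0] if rec.b.ndim == 1 else Bn
    out = SensorRecording(b=b_out, times=rec.times, montage_ids=rec.montage_ids)
    return out, scales


def map_to_source_activity(raw_map: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize a statistical map and shift it to be nonnegative.

    The map is divided by its standard deviation (sample convention,
    ``ddof=1``, by default; configurable) and shifted by its minimum so the
    result is >= 0 with min 0.
    """
    raw = np.asarray(raw_map, dtype=float)
    s = raw.std(ddof=ddof)
    if s == 0:
        raise ValueError("constant map has zero standard deviation")
    y = raw / s
    return y - y.min()


def project_forward(lf: LeadField, x: np.ndarray,
                    times: np.ndarray | None = None) -> SensorRecording:
    """Noise-free forward projection b = A x."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != lf.n_sources:
        raise ValueError(
            f"source dimension {x.shape[0]} != lead field columns {lf.n_sources}"
        )
    return SensorRecording(b=lf.A @ x, times=times, montage_ids=lf.sensor_labels)


def add_noise_at_snr(
    rec: SensorRecording, snr_db: float, seed: int | np.random.Generator
) -> tuple[SensorRecording, NoiseModel]:
    """Add i.i.d. Gaussian sensor noise at a requested SNR in decibels.

    The noise variance is ``mean(b**2) / 10**(snr_db / 10)`` with the mean
    taken over all sensors and time points.  ``snr_db = inf`` is the noiseless
    flag and returns the input unchanged with a zero-sigma noise model.
    """
    if not (np.isfinite(snr_db) or np.isposinf(snr_db)):
        raise ValueError("snr_db must be finite or +inf")
    B = rec.as_matrix()
    signal_power = np.mean(B**2)
    if signal_power == 0:
        raise ValueError("cannot set an SNR on an all-zero recording")
    if np.isposinf(snr_db):
        return rec, NoiseModel(sigma=0.0, n_sensors=rec.n_sensors)
    sigma = float(np.sqrt(signal_power / 10.0 ** (snr_db / 10.0)))
    rng = np.random.default_rng(seed)
    noisy = B + rng.normal(0.0, sigma, size=B.shape)
    b_out = noisy[:, 0] if rec.b.ndim == 1 else noisy
    out = SensorRecording(b=b_out, times=rec.times, montage_ids=rec.montage_ids)
    return out, NoiseModel(sigma=sigma, n_sensors=rec.n_sensors)


def subsample_montage(
    lf: LeadField, rec: SensorRecording, keep: list[str]
) -> tuple[LeadField, SensorRecording]:
    """Restrict the lead field and recording to a sensor subset.

    The common-average reference is re-applied to the retained subset so the
    forward/inverse pair stays internally consistent.
    """
    if len(keep) < 2:
        raise ValueError("at least 2 sensors must be kept")
    labels = list(lf.sensor_labels)
    try:
        idx = np.array([labels.index(k) for k in keep])
    except ValueError as e:
        raise ValueError(f"unknown sensor label in keep: {e}") from None
    A = common_average_reference(lf.A[idx])
    B = rec.as_matrix()[idx]
    B = B - B.mean(axis=0, keepdims=True)
    b_out = B[:, 0] if rec.b.ndim == 1 else B
    lf_out = LeadField(
        A=A,
        sensor_positions=None if lf.sensor_positions is None else lf.sensor_positions[idx],
        sensor_labels=[labels[i] for i in idx],
        reference="common-average",
    )
    rec_out = SensorRecording(b=b_out, times=rec.times,
                              montage_ids=[labels[i] for i in idx])
    return lf_out, rec_out
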
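"""Domain types for the coil QA protocol.

All types are plain dataclasses validated on construction.  Array axis
conventions, used consistently on disk and in memory:

* k-space: ``[kx, ky, channel, time]`` with the DC sample at index
  ``matrix // 2`` after the centering shift.
* image domain: ``[row, col, ...]`` where the row index runs
  anterior -> posterior and the column index right -> left; the voxel at
  ``(matrix // 2, matrix // 2)`` sits at the magnet isocenter.

All indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "MissingInputError",
    "AcquisitionSpec",
    "CSIRawData",
    "NoiseRecord",
    "NoiseModel",
    "SignalMap",
    "SensitivityMap",
    "SNRMap",
    "GFactorMap",
    "TxMap",
    "PhantomSpec",
    "LoopSpec",
    "CoilLayout",
    "GroundTruth",
]


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


class MissingInputError(KeyError):
    """A required record (e.g. the noise measurement) is absent."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _finite(a: np.ndarray, name: str) -> None:
    _check(np.all(np.isfinite(a)), f"{name} contains non-finite values")


@dataclass
class AcquisitionSpec:
    """CSI acquisition geometry and timing.

    Defaults mirror the protocol's reference sequence: axial CSI,
    36x36 cm FOV, 24x24 matrix, 20 mm slice, 5000 Hz spectral bandwidth,
    1024 FID points, TR 1000 ms, nominal flip 70 deg, carrier at the
    ethylene-glycol center peak (13C at 3T, ~32.13 MHz).
    """

    fov_mm: tuple[float, float] = (360.0, 360.0)
    matrix: tuple[int, int] = (24, 24)
    slice_thickness_mm: float = 20.0
    spectral_bw_hz: float = 5000.0
    n_fid_points: int = 1024
    te_ms: float = 2.7
    tr_ms: float = 1000.0
    nominal_flip_deg: float = 70.0
    center_freq_hz: float = 32.13e6
    nucleus: str = "13C"

    def __post_init__(self) -> None:
        self.fov_mm = (float(self.fov_mm[0]), float(self.fov_mm[1]))
        self.matrix = (int(self.matrix[0]), int(self.matrix[1]))
        _check(self.matrix[0] >= 1 and self.matrix[1] >= 1,
               "matrix entries must be >= 1")
        _check(self.fov_mm[0] > 0 and self.fov_mm[1] > 0, "fov_mm must be > 0")
        _check(self.spectral_bw_hz > 0, "spectral_bw_hz must be > 0")
        _check(self.n_fid_points >= 2, "n_fid_points must be >= 2")
        _check(self.te_ms >= 0, "te_ms must be >= 0")
        _check(self.center_freq_hz > 0, "center_freq_hz must be > 0")

    @property
    def dwell_ms(self) -> float:
        """Sampling interval of the FID in ms (1 / spectral bandwidth)."""
        return 1000.0 / self.spectral_bw_hz

    @property
    def voxel_size_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def times_ms(self) -> np.ndarray:
        """FID sample times in ms, measured from the start of sampling."""
        return np.arange(self.n_fid_points) * self.dwell_ms

    def ppm_to_hz(self, ppm: float) -> float:
        return ppm * self.center_freq_hz * 1e-6


@dataclass
class CSIRawData:
    """Raw phase-encoded CSI k-space data, ``[kx, ky, channel, time]``."""

    kspace: np.ndarray
    acq: AcquisitionSpec
    channel_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.kspace = np.asarray(self.kspace, dtype=np.complex128)
        _check(self.kspace.ndim == 4,
               "kspace must be 4-D [kx, ky, channel, time]")
        nkx, nky, nch, nt = self.kspace.shape
        _check((nkx, nky) == self.acq.matrix,
               f"kspace spatial dims {(nkx, nky)} != acq.matrix {self.acq.matrix}")
        _check(nt == self.acq.n_fid_points,
               f"kspace time dim {nt} != acq.n_fid_points {self.acq.n_fid_points}")
        _check(nch >= 1, "need at least 1 channel")
        _finite(self.kspace, "kspace")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(nch)]
        _check(len(self.channel_labels) == nch,
               "channel_labels length != number of channels")

    @property
    def n_channels(self) -> int:
        return self.kspace.shape[2]


@dataclass
class NoiseRecord:
    """Noise-only multi-channel FID, ``[channel, samples]``."""

    fid: np.ndarray
    spectral_bw_hz: float
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        self.fid = np.asarray(self.fid, dtype=np.complex128)
        _check(self.fid.ndim == 2, "fid must be 2-D [channel, samples]")
        if self.n_samples is None:
            self.n_samples = self.fid.shape[1]
        _check(self.n_samples == self.fid.shape[1],
               f"n_samples field ({self.n_samples}) does not match fid array "
               f"({self.fid.shape[1]} samples)")
        _check(self.n_samples >= 64,
               "need n_samples >= 64 for covariance estimation")
        _check(self.spectral_bw_hz > 0, "spectral_bw_hz must be > 0")
        _finite(self.fid, "fid")

    @property
    def n_channels(self) -> int:
        return self.fid.shape[0]


@dataclass
class NoiseModel:
    """Channel noise covariance Psi with its bandwidth scaling state.

    ``psi`` is the complex covariance E[n_i conj(n_j)].  ``neb_factor`` is
    the receiver's noise-equivalent bandwidth factor; ``scaled`` records
    whether ``psi`` has already been divided by it.
    """

    psi: np.ndarray
    neb_factor: float = 1.0
    scaled: bool = False

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=np.complex128)
        _check(self.psi.ndim == 2 and self.psi.shape[0] == self.psi.shape[1],
               "psi must be a square matrix")
        _finite(self.psi, "psi")
        herm_err = np.max(np.abs(self.psi - self.psi.conj().T))
        scale = max(np.max(np.abs(self.psi)), 1e-300)
        _check(herm_err <= 1e-8 * scale, "psi is not Hermitian within tolerance")
        d = np.diagonal(self.psi)
        _check(np.all(np.abs(d.imag) <= 1e-12 * np.abs(d.real).max()),
               "psi diagonal must be real")
        _check(np.all(d.real > 0), "psi diagonal must be > 0")
        _check(0 < self.neb_factor <= 1.5,
               "neb_factor must lie in (0, 1.5]")

    @property
    def n_channels(self) -> int:
        return self.psi.shape[0]


@dataclass
class SignalMap:
    """Per-voxel, per-channel complex signal at the first in-phase time."""

    s: np.ndarray
    inphase_time_ms: float
    inphase_index: int
    acq: Optional[AcquisitionSpec] = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.complex128)
        _check(self.s.ndim == 3, "s must be 3-D [ny, nx, channel]")
        _finite(self.s, "s")
        _check(self.inphase_index >= 0, "inphase_index must be >= 0")
        if self.acq is not None:
            _check(self.s.shape[:2] == self.acq.matrix,
                   "signal dims do not match acq.matrix")
            _check(self.inphase_index < self.acq.n_fid_points,
                   "inphase_index outside the FID")

    @property
    def n_channels(self) -> int:
        return self.s.shape[2]


@dataclass
class SensitivityMap:
    """Complex coil sensitivity profiles b with a support mask."""

    b: np.ndarray
    mask: np.ndarray
    norm_convention: str = "sos-unit"

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.complex128)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check(self.b.ndim == 3, "b must be 3-D [ny, nx, channel]")
        _check(self.mask.shape == self.b.shape[:2],
               "mask dims do not match b")
        _finite(self.b, "b")
        outside = ~self.mask
        _check(np.all(self.b[outside] == 0), "b must be zero outside the mask")
        if self.mask.any():
            sos = np.sqrt(np.sum(np.abs(self.b) ** 2, axis=-1))
            _check(np.all(sos[self.mask] > 0),
                   "each masked voxel needs at least one nonzero channel")

    @property
    def n_channels(self) -> int:
        return self.b.shape[2]


@dataclass
class SNRMap:
    """Scalar per-voxel SNR image."""

    snr: np.ndarray
    mask: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        self.snr = np.asarray(self.snr, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check(self.snr.ndim == 2, "snr must be 2-D")
        _check(self.mask.shape == self.snr.shape, "mask dims do not match snr")
        _finite(self.snr, "snr")
        _check(np.all(self.snr >= 0), "snr must be non-negative")
        _check(np.all(self.snr[~self.mask] == 0), "snr must be 0 outside mask")
        _check(self.n_channels >= 1, "n_channels must be >= 1")


@dataclass
class GFactorMap:
    """SENSE geometry-factor map; undefined voxels are NaN."""

    g: np.ndarray
    accel_R: int
    direction: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check(self.direction in ("row", "col"),
               "direction must be 'row' or 'col'")
        _check(self.accel_R >= 1, "accel_R must be >= 1")
        _check(self.g.shape == self.mask.shape, "g and mask dims differ")
        defined = self.mask & np.isfinite(self.g)
        _check(np.all(self.g[defined] >= 1 - 1e-6),
               "g-factor below 1 inside mask")

    @property
    def defined(self) -> np.ndarray:
        return self.mask & np.isfinite(self.g)


@dataclass
class TxMap:
    """Flip-angle scale relative to nominal (beta = actual / nominal)."""

    beta: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        _check(self.beta.ndim == 2, "beta must be 2-D")
        _finite(self.beta, "beta")
        _check(np.all(self.beta >= 0), "beta must be >= 0")


@dataclass
class PhantomSpec:
    """Uniform conductive phantom filled with ethylene glycol.

    The 13C resonance of ethylene glycol is a 1:2:1 triplet with
    J_CH ~ 142 Hz; T2* ~ 80-90 ms and T1 ~ 700 ms at 3T room temperature.
    """

    geometry: str = "cylinder"
    diameter_mm: float = 250.0
    center_mm: tuple[float, float] = (0.0, 0.0)
    signal_amplitude: float = 1.0
    t2star_ms: float = 85.0
    t1_ms: float = 700.0
    j_hz: float = 142.0
    line_amplitudes: tuple[float, float, float] = (1.0, 2.0, 1.0)
    # semiaxes for the head-shaped phantom (row/AP, col/RL); ignored for
    # the cylinder, which uses diameter_mm
    axes_mm: tuple[float, float] = (190.0, 150.0)

    def __post_init__(self) -> None:
        _check(self.geometry in ("cylinder", "head_ellipse"),
               "geometry must be 'cylinder' or 'head_ellipse'")
        _check(self.diameter_mm > 0, "diameter_mm must be > 0")
        _check(self.t2star_ms > 0, "t2star_ms must be > 0")
        _check(self.t1_ms > 0, "t1_ms must be > 0")
        _check(self.j_hz > 0, "j_hz must be > 0")
        la = np.asarray(self.line_amplitudes, dtype=float)
        _check(np.all(la >= 0) and la.sum() > 0,
               "line_amplitudes must be non-negative and not all zero")


@dataclass
class LoopSpec:
    """A circular loop element: center (mm, 3-vector), radius, unit normal."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        _check(self.radius_mm > 0, "loop radius must be > 0")
        n = np.asarray(self.normal, dtype=float)
        _check(abs(np.linalg.norm(n) - 1.0) < 1e-6,
               "loop normal must have unit length")


@dataclass
class CoilLayout:
    """A receive layout: a list of loops, or a uniform volume coil."""

    loops: Optional[list[LoopSpec]] = None
    uniform: bool = False
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.uniform:
            _check(not self.loops, "uniform layout takes no loops")
        else:
            _check(bool(self.loops), "non-uniform layout needs loops")

    @property
    def n_channels(self) -> int:
        return 1 if self.uniform else len(self.loops)


@dataclass
class GroundTruth:
    """Simulator-side truth for recovery tests.

    ``snr_true`` is the analytic SNR of the optimally combined first
    in-phase sample *before* spectral filtering; the rectangular low-pass
    filter of the reconstruction chain rescales the signal by
    1/sqrt(band fraction) while preserving the noise standard deviation,
    so the SNR expected from the full pipeline with a band retaining a
    fraction ``p`` of spectral points is ``snr_true / sqrt(p)``.
    """

    b_true: np.ndarray
    psi_true: np.ndarray
    snr_true: np.ndarray
    signal_params: PhantomSpec
    mask: Optional[np.ndarray] = None
    inphase_time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.b_true = np.asarray(self.b_true, dtype=np.complex128)
        self.psi_true = np.asarray(self.psi_true, dtype=np.complex128)
        self.snr_true = np.asarray(self.snr_true, dtype=float)
        _check(np.all(self.snr_true >= 0), "snr_true must be >= 0")
        # positive definiteness
        try:
            np.linalg.cholesky(self.psi_true)
        except np.linalg.LinAlgError as e:
            raise ValidationError("psi_true is not positive definite") from e

    def expected_pipeline_snr(self, band_fraction: float = 1.0) -> np.ndarray:
        """Analytic SNR after the noise-std-preserving spectral filter."""
        _check(0 < band_fraction <= 1, "band_fraction must be in (0, 1]")
        return self.snr_true / np.sqrt(band_fraction)
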
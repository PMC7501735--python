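"""Synthetic multi-channel CSI acquisitions with known ground truth.

Emulates the protocol's test objects — a uniform ethylene-glycol phantom
(250 mm cylinder or head-shaped ellipse), loop-array or uniform-volume
receive profiles, and complex Gaussian noise with a prescribed channel
covariance and optional receiver-filter coloring — so every stage of the
QA chain can be verified against analytic truth without scanner data.

Coil receive profiles use quasi-static Biot-Savart fields: at the 13C
Larmor frequency (~32 MHz) sample loading has a negligible effect on the
field pattern, so wavelength and loss effects are not modeled; coil- vs
sample-noise regimes are represented entirely through the channel noise
covariance.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import (
    AcquisitionSpec,
    CoilLayout,
    CSIRawData,
    GroundTruth,
    LoopSpec,
    NoiseModel,
    NoiseRecord,
    PhantomSpec,
    ValidationError,
)
from .filters import apply_coloring
from . import recon

__all__ = [
    "voxel_grid",
    "phantom_mask",
    "loop_sensitivity",
    "layout_sensitivities",
    "ethylene_glycol_fid",
    "steady_state_signal",
    "complex_gaussian",
    "simulate_noise",
    "simulate_csi",
    "make_layout",
    "uniform_covariance",
]


def voxel_grid(acq: AcquisitionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-center coordinates (y_mm, x_mm) as 2-D arrays.

    The voxel at index ``matrix // 2`` (the DC voxel) sits at the
    isocenter; rows run anterior -> posterior (y), columns right -> left (x).
    """
    ny, nx = acq.matrix
    dy, dx = acq.voxel_size_mm
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    return np.meshgrid(y, x, indexing="ij")


def phantom_mask(spec: PhantomSpec, acq: AcquisitionSpec,
                 supersample: int = 8) -> np.ndarray:
    """Partial-volume support mask: per-voxel area fraction inside the phantom.

    Estimated by ``supersample``x``supersample`` subsampling of each voxel;
    1 deep inside the phantom, 0 outside, fractional on the boundary.
    """
    ny, nx = acq.matrix
    dy, dx = acq.voxel_size_mm
    cy, cx = spec.center_mm
    if spec.geometry == "cylinder":
        ay = ax = spec.diameter_mm / 2.0
    else:
        ay, ax = spec.axes_mm[0] / 2.0, spec.axes_mm[1] / 2.0
    # the phantom must fit inside the FOV
    if (abs(cy) + ay > acq.fov_mm[0] / 2) or (abs(cx) + ax > acq.fov_mm[1] / 2):
        raise ValidationError("phantom extends beyond the field of view")

    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    y0 = (np.arange(ny) - ny // 2) * dy
    x0 = (np.arange(nx) - nx // 2) * dx
    ys = (y0[:, None] + off[None, :] * dy).ravel()
    xs = (x0[:, None] + off[None, :] * dx).ravel()
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    inside = ((Y - cy) / ay) ** 2 + ((X - cx) / ax) ** 2 <= 1.0
    return inside.reshape(ny, s, nx, s).mean(axis=(1, 3))


def _loop_frame(loop: LoopSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.asarray(loop.normal, dtype=float)
    n = n / np.linalg.norm(n)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2, n


def loop_sensitivity(loop: LoopSpec, acq: AcquisitionSpec,
                     slice_z_mm: float = 0.0, n_segments: int = 180) -> np.ndarray:
    """Quasi-static receive profile of a circular loop over the image slice.

    The magnitude is |B| per unit current from numerical Biot-Savart line
    integration over the loop (arbitrary units, proportional to T/A); the
    phase is that of the circularly polarized transverse component
    (Bx - i*By).  Voxels landing on the wire are evaluated at a small
    offset along the loop normal and flagged with a warning.
    """
    e1, e2, nrm = _loop_frame(loop)
    a = loop.radius_mm
    c = np.asarray(loop.center_mm, dtype=float)
    theta = np.linspace(0, 2 * np.pi, n_segments + 1)
    pts = c[None, :] + a * (np.cos(theta)[:, None] * e1[None, :]
                            + np.sin(theta)[:, None] * e2[None, :])
    mid = 0.5 * (pts[1:] + pts[:-1])          # segment midpoints
    dl = pts[1:] - pts[:-1]                    # segment vectors

    Y, X = voxel_grid(acq)
    r = np.stack([X.ravel(), Y.ravel(),
                  np.full(X.size, slice_z_mm)], axis=1)  # [nvox, 3] (x, y, z)

    # guard against voxels on the wire path
    d2 = np.sum((r[:, None, :] - mid[None, :, :]) ** 2, axis=2)
    eps = 1e-6 * a
    on_wire = d2.min(axis=1) < eps ** 2
    if np.any(on_wire):
        warnings.warn("voxel center on the wire path; evaluating at a "
                      "small offset along the loop normal")
        r[on_wire] += 1e-3 * a * nrm

    sep = r[:, None, :] - mid[None, :, :]                # [nvox, nseg, 3]
    dist3 = np.sum(sep ** 2, axis=2) ** 1.5
    cross = np.cross(np.broadcast_to(dl[None, :, :], sep.shape), sep)
    B = np.sum(cross / dist3[:, :, None], axis=1)        # [nvox, 3] ~ (Bx,By,Bz)
    mag = np.linalg.norm(B, axis=1)
    phase = np.angle(B[:, 0] - 1j * B[:, 1])
    ny, nx = acq.matrix
    return (mag * np.exp(1j * phase)).reshape(ny, nx)


def layout_sensitivities(coils: CoilLayout, acq: AcquisitionSpec,
                         slice_z_mm: float = 0.0) -> np.ndarray:
    """Stack of channel profiles ``[ny, nx, channel]`` for a layout."""
    ny, nx = acq.matrix
    if coils.uniform:
        return np.ones((ny, nx, 1), dtype=np.complex128)
    b = np.empty((ny, nx, coils.n_channels), dtype=np.complex128)
    for i, loop in enumerate(coils.loops):
        b[:, :, i] = loop_sensitivity(loop, acq, slice_z_mm=slice_z_mm)
    return b


def ethylene_glycol_fid(t_ms: np.ndarray, spec: PhantomSpec,
                        te_ms: float) -> np.ndarray:
    """Complex FID envelope of the ethylene glycol 13C triplet.

    Three lines at offsets {-J, 0, +J} with weights ``line_amplitudes``
    (normalized to unit sum) and a common T2* decay; for the natural
    1:2:1 triplet this reduces to
    ``A * cos^2(pi*J*(t+TE)) * exp(-(t+TE)/T2*)``.

    ``t_ms`` counts from the start of sampling; TE is the delay between
    excitation and the first sample.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    if np.any(t_ms < 0) or te_ms < 0:
        raise ValidationError("times must be non-negative")
    tau_s = (t_ms + te_ms) / 1000.0
    w = np.asarray(spec.line_amplitudes, dtype=float)
    w = w / w.sum()
    offsets = np.array([-spec.j_hz, 0.0, spec.j_hz])
    mod = sum(wk * np.exp(2j * np.pi * fk * tau_s)
              for wk, fk in zip(w, offsets))
    env = np.exp(-tau_s / (spec.t2star_ms / 1000.0))
    return spec.signal_amplitude * mod * env


def steady_state_signal(flip_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Relative steady-state signal sin(a)(1-E1)/(1-cos(a)E1), E1=exp(-TR/T1)."""
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return float(np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1))


def _cholesky_pd(psi: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(psi)
    except np.linalg.LinAlgError as e:
        raise ValidationError("noise covariance is not positive definite") from e


def complex_gaussian(psi: np.ndarray, shape: tuple[int, ...],
                     rng: np.random.Generator) -> np.ndarray:
    """Zero-mean circular complex Gaussian with channel covariance ``psi``.

    The channel axis is the *last* axis of the returned array; real and
    imaginary parts each carry covariance psi/2 so that
    E[n_i conj(n_j)] = psi[i, j].
    """
    n = psi.shape[0]
    L = _cholesky_pd(np.asarray(psi, dtype=np.complex128))
    z = (rng.standard_normal(shape + (n,))
         + 1j * rng.standard_normal(shape + (n,))) / np.sqrt(2.0)
    return z @ L.conj().T


def simulate_noise(psi, n_samples: int, seed: int,
                   coloring=None, spectral_bw_hz: float = 5000.0) -> NoiseRecord:
    """Simulate a noise-only multi-channel FID record.

    ``psi`` may be a matrix or a :class:`NoiseModel`; ``coloring`` is an
    optional receiver-filter spec (see :mod:`csiqa.filters`) applied along
    time, shaping the PSD like a scanner's digital receive filter.
    """
    if isinstance(psi, NoiseModel):
        psi = psi.psi
    psi = np.asarray(psi, dtype=np.complex128)
    rng = np.random.default_rng(seed)
    fid = complex_gaussian(psi, (n_samples,), rng).T  # [channel, samples]
    if coloring is not None:
        fid = apply_coloring(fid, coloring)
    return NoiseRecord(fid=fid, spectral_bw_hz=spectral_bw_hz)


def simulate_csi(phantom: PhantomSpec, coils: CoilLayout,
                 acq: AcquisitionSpec, psi, seed: int, *,
                 steady_state: bool = True,
                 n_noise_samples: int = 2048,
                 coloring=None,
                 slice_z_mm: float = 0.0,
                 noiseless: bool = False
                 ) -> tuple[CSIRawData, NoiseRecord, GroundTruth]:
    """Simulate a full CSI acquisition plus its companion noise record.

    Per-voxel FID = support fraction x amplitude x steady-state factor x
    triplet envelope, weighted by each channel's receive profile; the
    image stack is transformed to k-space with the exact inverse of the
    reconstruction convention, and complex Gaussian noise with channel
    covariance ``psi`` is added independently at every k-space sample.

    The returned :class:`GroundTruth` carries the true profiles, the true
    covariance, and the analytic SNR of the optimally combined first
    in-phase sample (see ``GroundTruth.expected_pipeline_snr`` for the
    spectral-filter scaling).
    """
    if isinstance(psi, NoiseModel):
        psi = psi.psi
    psi = np.asarray(psi, dtype=np.complex128)
    if psi.shape[0] != coils.n_channels:
        raise ValidationError("psi dimension does not match the coil layout")
    _cholesky_pd(psi)

    mask_frac = phantom_mask(phantom, acq)
    b_true = layout_sensitivities(coils, acq, slice_z_mm=slice_z_mm)
    ss = (steady_state_signal(acq.nominal_flip_deg, acq.tr_ms, phantom.t1_ms)
          if steady_state else 1.0)
    # unit-amplitude envelope; the amplitude enters once via `amp`
    from dataclasses import replace as _dc_replace
    env = ethylene_glycol_fid(acq.times_ms,
                              _dc_replace(phantom, signal_amplitude=1.0),
                              acq.te_ms)                          # [time]

    amp = mask_frac * phantom.signal_amplitude * ss               # [ny, nx]
    img = (amp[:, :, None, None] * b_true[:, :, :, None]
           * env[None, None, None, :])
    ksp = recon.image_to_kspace(img)

    rng = np.random.default_rng(seed)
    if not noiseless:
        nkx, nky, _, nt = ksp.shape
        noise_k = complex_gaussian(psi, (nkx, nky, nt), rng)      # [...,ch]
        noise_k = np.moveaxis(noise_k, -1, 2)
        if coloring is not None:
            noise_k = apply_coloring(noise_k, coloring)
        ksp = ksp + noise_k
    raw = CSIRawData(kspace=ksp, acq=acq)

    noise_rec = simulate_noise(psi, n_noise_samples,
                               seed=int(rng.integers(2 ** 31)),
                               coloring=coloring,
                               spectral_bw_hz=acq.spectral_bw_hz)

    # analytic SNR of the optimal combination at the snapped in-phase sample
    idx, t_ip = recon.first_inphase_sample(phantom.j_hz, acq.te_ms, acq)
    a_ip = np.abs(amp * env[idx])                                  # [ny, nx]
    psi_inv_b = np.linalg.solve(psi, b_true.reshape(-1, psi.shape[0]).T)
    quad = np.real(np.einsum("vn,nv->v", b_true.reshape(-1, psi.shape[0]).conj(),
                             psi_inv_b)).reshape(a_ip.shape)
    snr_true = np.sqrt(2.0) * a_ip * np.sqrt(np.maximum(quad, 0.0))

    gt = GroundTruth(b_true=b_true, psi_true=psi, snr_true=snr_true,
                     signal_params=phantom, mask=mask_frac > 0.5,
                     inphase_time_ms=idx * acq.dwell_ms)
    return raw, noise_rec, gt


def uniform_covariance(n: int, sigma2: float = 1.0, rho: float = 0.0,
                       block: slice | None = None) -> np.ndarray:
    """Covariance with equal variances and uniform correlation ``rho``.

    If ``block`` is given, the correlation applies only within that
    channel block (e.g. the top half of an array), the rest being
    uncorrelated — emulating arrays whose mutual coupling is confined to
    one module.
    """
    psi = np.eye(n, dtype=np.complex128)
    if rho != 0.0:
        if block is None:
            block = slice(0, n)
        idx = np.arange(n)[block]
        for i in idx:
            for j in idx:
                if i != j:
                    psi[i, j] = rho
    return sigma2 * psi


def make_layout(name: str) -> CoilLayout:
    """Shipped synthetic layouts mirroring the benchmarked coil classes.

    * ``"volume"``: uniform unit sensitivity (volume coil).
    * ``"array14"``: 14 loops of 80 mm diameter on a 250 mm circle around
      the head-sized cylinder (close-fitting helmet array class).
    * ``"array8"``: two opposed paddles of 4 loops each (flexible
      two-paddle array class).
    * ``"single_loop"``: one 80 mm surface loop below the phantom.
    """
    if name == "volume":
        return CoilLayout(uniform=True, name="volume")
    if name == "array14":
        loops = []
        ring = 125.0
        for k in range(14):
            phi = 2 * np.pi * k / 14
            c = (ring * np.cos(phi), ring * np.sin(phi), 0.0)
            nrm = (-np.cos(phi), -np.sin(phi), 0.0)
            loops.append(LoopSpec(center_mm=c, radius_mm=40.0, normal=nrm))
        return CoilLayout(loops=loops, name="array14")
    if name == "array8":
        loops = []
        for ysign in (+1.0, -1.0):
            for x in (-97.5, -32.5, 32.5, 97.5):
                loops.append(LoopSpec(center_mm=(x, 130.0 * ysign, 0.0),
                                      radius_mm=40.0,
                                      normal=(0.0, -ysign, 0.0)))
        return CoilLayout(loops=loops, name="array8")
    if name == "single_loop":
        return CoilLayout(loops=[LoopSpec(center_mm=(0.0, -130.0, 0.0),
                                          radius_mm=40.0,
                                          normal=(0.0, 1.0, 0.0))],
                          name="single_loop")
    raise ValidationError(f"unknown layout {name!r}")
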
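"""SNR maps, summary statistics, SENSE g-factors and transmit SNR loss.

The SNR definition follows the real-channel-noise convention: for a
single receiver

    SNR = sqrt(2) |s| / sigma,

with sigma^2 the scaled complex noise variance.  For arrays, channels
are combined with the SNR-optimal (Roemer) matched filter built from the
sensitivity profiles b and the scaled noise covariance Psi:

    SNR = sqrt(2) |b^H Psi^-1 s| / sqrt(b^H Psi^-1 b),

which reduces exactly to the single-channel form for n = 1 and yields
Rician background statistics regardless of channel count — the property
that makes SNR comparable across volume coils and arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .datamodel import (
    AcquisitionSpec,
    GFactorMap,
    NoiseModel,
    SensitivityMap,
    SignalMap,
    SNRMap,
    TxMap,
    ValidationError,
)
from .phantom import steady_state_signal

__all__ = [
    "snr_map_single",
    "snr_map_array",
    "sum_of_squares_snr",
    "combined_snr",
    "SNRSummary",
    "snr_summary",
    "sense_gfactor",
    "smooth_txmap",
    "tx_snr_loss",
]

SQRT2 = np.sqrt(2.0)


def _require_scaled(noise: NoiseModel) -> None:
    if not noise.scaled:
        raise ValidationError(
            "noise model must be bandwidth-scaled before SNR computation "
            "(apply noisecal.scale_covariance, factor 1.0 for an ideal "
            "flat receiver)")


def snr_map_single(s: SignalMap, noise: NoiseModel,
                   mask: np.ndarray | None = None) -> SNRMap:
    """Single-receiver SNR map: sqrt(2) |s| / sigma."""
    if s.n_channels != 1:
        raise ValidationError(
            f"signal has {s.n_channels} channels; use snr_map_array for "
            "array data")
    _require_scaled(noise)
    sigma = float(np.sqrt(np.real(noise.psi[0, 0])))
    snr = SQRT2 * np.abs(s.s[:, :, 0]) / sigma
    if mask is None:
        mask = np.ones(snr.shape, dtype=bool)
    snr = np.where(mask, snr, 0.0)
    return SNRMap(snr=snr, mask=np.asarray(mask, dtype=bool), n_channels=1)


def snr_map_array(s: SignalMap, b: SensitivityMap,
                  noise: NoiseModel) -> SNRMap:
    """Optimal-combination SNR map for array data.

    sqrt(2) |b^H Psi^-1 s| / sqrt(b^H Psi^-1 b), evaluated per masked
    voxel through a Hermitian (Cholesky) factorization of Psi — the
    inverse is never formed explicitly.  This is the Roemer matched
    filter for the convention Psi_ij = E[n_i conj(n_j)] used throughout
    this package; the transpose-conjugate way of writing the same
    expression corresponds to the opposite covariance conjugation
    convention and has identical modulus for real-valued Psi.
    """
    if s.n_channels != b.n_channels:
        raise ValidationError("signal and sensitivity channel counts differ")
    _require_scaled(noise)
    if noise.n_channels != s.n_channels:
        raise ValidationError("noise model channel count differs from data")
    try:
        cho = cho_factor(noise.psi)
    except np.linalg.LinAlgError as e:
        cond = np.linalg.cond(noise.psi)
        raise ValidationError(
            f"noise covariance is singular (condition number {cond:.3e})"
        ) from e

    ny, nx, nch = s.s.shape
    mask = b.mask
    sf = s.s.reshape(-1, nch)
    bf = b.b.reshape(-1, nch)
    w = cho_solve(cho, bf.T)                         # Psi^-1 b, [nch, nvox]
    num = np.abs(np.einsum("vn,nv->v", sf.conj(), w))  # |b^H Psi^-1 s|
    den2 = np.real(np.einsum("vn,nv->v", bf.conj(), w))
    snr = np.zeros(ny * nx)
    ok = mask.ravel() & (den2 > 0)
    snr[ok] = SQRT2 * num[ok] / np.sqrt(den2[ok])
    return SNRMap(snr=snr.reshape(ny, nx), mask=mask, n_channels=nch)


def sum_of_squares_snr(s: SignalMap, noise: NoiseModel,
                       mask: np.ndarray | None = None) -> SNRMap:
    """Root-sum-of-squares combination, for statistics comparisons.

    sqrt(2) * ||s|| / sigma_rms with sigma_rms the root mean channel
    noise std.  Background values follow a non-central chi law with 2n
    degrees of freedom — channel-count dependent, which is why the
    optimal combination is preferred for cross-coil comparisons.
    """
    _require_scaled(noise)
    sigma = float(np.sqrt(np.mean(np.real(np.diagonal(noise.psi)))))
    snr = SQRT2 * np.sqrt(np.sum(np.abs(s.s) ** 2, axis=-1)) / sigma
    if mask is None:
        mask = np.ones(snr.shape, dtype=bool)
    snr = np.where(mask, snr, 0.0)
    return SNRMap(snr=snr, mask=np.asarray(mask, dtype=bool),
                  n_channels=s.n_channels)


def combined_snr(s: np.ndarray, w: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """SNR of an arbitrary linear combination w at each voxel.

    sqrt(2) |w^H s| / sqrt(w^H Psi w); the matched filter
    w = Psi^-1 b* maximizes this over all w.  ``s`` is [..., channel],
    ``w`` either [channel] or broadcastable to ``s``.
    """
    w = np.asarray(w)
    num = np.abs(np.sum(np.conj(w) * s, axis=-1))
    den = np.sqrt(np.real(np.einsum("...i,ij,...j->...", np.conj(w), psi, w)))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = SQRT2 * num / den
    return np.where(den > 0, out, 0.0)


@dataclass
class SNRSummary:
    """Benchmark summary of an SNR map.

    ``center``: mean over the 3x3 voxel block around the grid center;
    ``surface``: maximum over the mask; profiles: per-position mean over
    the three central lines, anterior-posterior (along rows) and
    right-left (along columns).
    """

    center: float
    surface: float
    profile_ap: np.ndarray
    profile_rl: np.ndarray


def snr_summary(snr_map: SNRMap, mask: np.ndarray | None = None) -> SNRSummary:
    """Summary statistics matching the benchmark conventions."""
    mask = snr_map.mask if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    snr = snr_map.snr
    ny, nx = snr.shape
    r0, c0 = ny // 2, nx // 2
    rows = slice(r0 - 1, r0 + 2)
    cols = slice(c0 - 1, c0 + 2)
    if not mask[rows, cols].all():
        warnings.warn("central 3x3 block extends outside the mask; "
                      "center SNR undefined")
        center = float("nan")
    else:
        center = float(snr[rows, cols].mean())
    surface = float(snr[mask].max())
    profile_ap = snr[:, cols].mean(axis=1)
    profile_rl = snr[rows, :].mean(axis=0)
    return SNRSummary(center=center, surface=surface,
                      profile_ap=profile_ap, profile_rl=profile_rl)


def sense_gfactor(b: SensitivityMap, noise: NoiseModel, R: int,
                  direction: str, mask: np.ndarray | None = None,
                  cond_limit: float = 1e10) -> GFactorMap:
    """SENSE geometry-factor map for uniform undersampling at rate R.

    For each set of R voxels aliased along the chosen axis, with S the
    (n_channels x R) sensitivity matrix of the in-mask set members,

        g_rho = sqrt([(S^H Psi^-1 S)^-1]_rho_rho * [S^H Psi^-1 S]_rho_rho).

    Voxels outside the mask, or in sets whose aliasing system is
    singular, are NaN (flagged undefined, never clipped).
    """
    if direction not in ("row", "col"):
        raise ValidationError("direction must be 'row' or 'col'")
    if R < 1:
        raise ValidationError("R must be >= 1")
    if R > b.n_channels:
        raise ValidationError(
            f"acceleration R={R} exceeds the {b.n_channels} channels")
    mask = b.mask if mask is None else np.asarray(mask, dtype=bool)
    axis = 0 if direction == "row" else 1
    n_axis = b.b.shape[axis]
    if n_axis % R:
        raise ValidationError(f"R={R} does not divide matrix size {n_axis}")

    psi_chol = cho_factor(noise.psi)
    g = np.full(b.b.shape[:2], np.nan)
    barr = b.b if axis == 0 else np.transpose(b.b, (1, 0, 2))
    marr = mask if axis == 0 else mask.T
    garr = g if axis == 0 else g.T
    n0, n1 = barr.shape[:2]
    step = n0 // R
    for j in range(n1):
        for i0 in range(step):
            idx = i0 + step * np.arange(R)
            members = idx[marr[idx, j]]
            if members.size == 0:
                continue
            S = barr[members, j, :].T                       # [nch, k]
            ShPiS = S.conj().T @ cho_solve(psi_chol, S)     # [k, k]
            if np.linalg.cond(ShPiS) > cond_limit:
                continue                                     # stays NaN
            Minv = np.linalg.inv(ShPiS)
            vals = np.sqrt(np.abs(np.real(np.diagonal(Minv))
                                  * np.real(np.diagonal(ShPiS))))
            garr[members, j] = vals
    return GFactorMap(g=g, accel_R=R, direction=direction, mask=mask)


def smooth_txmap(tx: TxMap, region_mm: float, acq: AcquisitionSpec,
                 mask: np.ndarray | None = None) -> TxMap:
    """Smooth a flip-angle map by first-order local polynomial fitting.

    Per voxel, an ordinary least-squares plane is fit over the square
    region of side ``region_mm`` (masked voxels only, uniform weights)
    and evaluated at the voxel.  Regions with fewer than 3 masked voxels
    fall back to the nearest masked neighbor, with a warning.
    """
    vy, vx = acq.voxel_size_mm
    half = int(round(region_mm / min(vy, vx) / 2))
    if 2 * half + 1 < 2:
        raise ValidationError("region must span at least 2 voxels")
    beta = tx.beta
    ny, nx = beta.shape
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    out = np.zeros_like(beta)
    fallback = 0
    my, mx = np.nonzero(mask)
    for i in range(ny):
        for j in range(nx):
            i0, i1 = max(0, i - half), min(ny, i + half + 1)
            j0, j1 = max(0, j - half), min(nx, j + half + 1)
            sub = mask[i0:i1, j0:j1]
            if sub.sum() < 3:
                if my.size == 0:
                    raise ValidationError("mask is empty")
                k = np.argmin((my - i) ** 2 + (mx - j) ** 2)
                out[i, j] = beta[my[k], mx[k]]
                fallback += 1
                continue
            yy, xx = np.nonzero(sub)
            A = np.column_stack([np.ones(yy.size), yy + i0 - i, xx + j0 - j])
            z = beta[i0:i1, j0:j1][sub]
            coef, *_ = np.linalg.lstsq(A, z, rcond=None)
            out[i, j] = coef[0]
    if fallback:
        warnings.warn(f"{fallback} voxel(s) used the nearest-neighbor "
                      "fallback (fewer than 3 masked voxels in region)")
    return TxMap(beta=np.maximum(out, 0.0), smoothed=True)


def tx_snr_loss(beta, t1_ms: float, tr_ms: float,
                nominal_flip_deg: float) -> np.ndarray:
    """Relative steady-state SNR loss from transmit inhomogeneity.

    loss = 1 - S(beta * alpha) / S(alpha) with
    S(a) = sin(a)(1 - E1)/(1 - cos(a) E1), E1 = exp(-TR/T1); beta is the
    flip-angle scale relative to nominal (a TxMap or array).
    """
    if isinstance(beta, TxMap):
        beta = beta.beta
    beta = np.asarray(beta, dtype=float)
    ref = steady_state_signal(nominal_flip_deg, tr_ms, t1_ms)
    a = np.deg2rad(nominal_flip_deg) * beta
    e1 = np.exp(-tr_ms / t1_ms)
    sig = np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1)
    return 1.0 - sig / ref
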
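"""Self-describing HDF5 container for raw CSI data, noise records and
derived maps.

Layout (schema version 1):

* file attributes: ``schema_version``, ``kind``
* ``/raw``: ``kspace_re``, ``kspace_im`` (float64, ``[kx, ky, channel, time]``)
  with all acquisition attributes (units encoded in names, e.g. ``fov_mm``)
* ``/noise``: ``fid_re``, ``fid_im`` plus ``spectral_bw_hz``, ``n_samples``
* ``/derived/<name>``: derived maps, each with its own ``kind`` attribute

Complex data are stored as paired float64 real/imag datasets so the files
remain portable to any HDF5 reader.  Roundtrips are bit-exact.
"""

from __future__ import annotations

import numpy as np
import h5py

from .datamodel import (
    AcquisitionSpec,
    CSIRawData,
    GFactorMap,
    MissingInputError,
    NoiseModel,
    NoiseRecord,
    SensitivityMap,
    SignalMap,
    SNRMap,
    TxMap,
    ValidationError,
)

SCHEMA_VERSION = 1

__all__ = ["write_container", "read_container", "read_noise",
            "write_derived", "read_derived", "SCHEMA_VERSION"]

_ACQ_FIELDS = ("fov_mm", "matrix", "slice_thickness_mm", "spectral_bw_hz",
               "n_fid_points", "te_ms", "tr_ms", "nominal_flip_deg",
               "center_freq_hz", "nucleus")


def _store_complex(grp: h5py.Group, name: str, arr: np.ndarray) -> None:
    grp.create_dataset(f"{name}_re", data=np.ascontiguousarray(arr.real))
    grp.create_dataset(f"{name}_im", data=np.ascontiguousarray(arr.imag))


def _load_complex(grp: h5py.Group, name: str) -> np.ndarray:
    return np.asarray(grp[f"{name}_re"]) + 1j * np.asarray(grp[f"{name}_im"])


def _write_acq(grp: h5py.Group, acq: AcquisitionSpec) -> None:
    for f in _ACQ_FIELDS:
        grp.attrs[f] = getattr(acq, f)


def _read_acq(grp: h5py.Group) -> AcquisitionSpec:
    kw = {}
    for f in _ACQ_FIELDS:
        v = grp.attrs[f]
        if f in ("fov_mm", "matrix"):
            v = tuple(np.asarray(v).tolist())
        elif f == "nucleus":
            v = str(v)
        elif f in ("matrix", "n_fid_points"):
            v = int(v)
        else:
            v = float(v)
        kw[f] = v
    kw["n_fid_points"] = int(kw["n_fid_points"])
    return AcquisitionSpec(**kw)


def _write_noise_group(grp: h5py.Group, noise: NoiseRecord) -> None:
    _store_complex(grp, "fid", noise.fid)
    grp.attrs["spectral_bw_hz"] = noise.spectral_bw_hz
    grp.attrs["n_samples"] = noise.n_samples


def _read_noise_group(grp: h5py.Group) -> NoiseRecord:
    return NoiseRecord(fid=_load_complex(grp, "fid"),
                       spectral_bw_hz=float(grp.attrs["spectral_bw_hz"]),
                       n_samples=int(grp.attrs["n_samples"]))


def write_container(data, path, *, noise: NoiseRecord | None = None) -> None:
    """Write a typed object to an HDF5 container.

    ``data`` may be a :class:`CSIRawData` (optionally bundled with its
    companion ``noise`` record), a :class:`NoiseRecord`, or any derived
    map type.  Invariants are re-validated before writing.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if isinstance(data, CSIRawData):
            f.attrs["kind"] = "csi_raw"
            raw = f.create_group("raw")
            _store_complex(raw, "kspace", data.kspace)
            _write_acq(raw, data.acq)
            raw.attrs["channel_labels"] = [str(c) for c in data.channel_labels]
            if noise is not None:
                _write_noise_group(f.create_group("noise"), noise)
        elif isinstance(data, NoiseRecord):
            if noise is not None:
                raise ValidationError("noise= only applies to CSIRawData")
            f.attrs["kind"] = "noise_record"
            _write_noise_group(f.create_group("noise"), data)
        else:
            if noise is not None:
                raise ValidationError("noise= only applies to CSIRawData")
            grp = f.require_group("derived").create_group("map")
            _write_map(f, grp, data)


def _write_map(f: h5py.File, grp: h5py.Group, data) -> None:
    if isinstance(data, NoiseModel):
        f.attrs["kind"] = grp.attrs["kind"] = "noise_model"
        _store_complex(grp, "psi", data.psi)
        grp.attrs["neb_factor"] = data.neb_factor
        grp.attrs["scaled"] = data.scaled
    elif isinstance(data, SignalMap):
        f.attrs["kind"] = grp.attrs["kind"] = "signal_map"
        _store_complex(grp, "s", data.s)
        grp.attrs["inphase_time_ms"] = data.inphase_time_ms
        grp.attrs["inphase_index"] = data.inphase_index
        if data.acq is not None:
            _write_acq(grp, data.acq)
    elif isinstance(data, SensitivityMap):
        f.attrs["kind"] = grp.attrs["kind"] = "sensitivity_map"
        _store_complex(grp, "b", data.b)
        grp.create_dataset("mask", data=data.mask)
        grp.attrs["norm_convention"] = data.norm_convention
    elif isinstance(data, SNRMap):
        f.attrs["kind"] = grp.attrs["kind"] = "snr_map"
        grp.create_dataset("snr", data=data.snr)
        grp.create_dataset("mask", data=data.mask)
        grp.attrs["n_channels"] = data.n_channels
    elif isinstance(data, GFactorMap):
        f.attrs["kind"] = grp.attrs["kind"] = "gfactor_map"
        grp.create_dataset("g", data=data.g)
        grp.create_dataset("mask", data=data.mask)
        grp.attrs["accel_R"] = data.accel_R
        grp.attrs["direction"] = data.direction
    elif isinstance(data, TxMap):
        f.attrs["kind"] = grp.attrs["kind"] = "tx_map"
        grp.create_dataset("beta", data=data.beta)
        grp.attrs["smoothed"] = data.smoothed
    else:
        raise ValidationError(f"unsupported record type {type(data).__name__}")


def _read_map(grp: h5py.Group):
    kind = grp.attrs["kind"]
    if kind == "noise_model":
        return NoiseModel(psi=_load_complex(grp, "psi"),
                          neb_factor=float(grp.attrs["neb_factor"]),
                          scaled=bool(grp.attrs["scaled"]))
    if kind == "signal_map":
        acq = _read_acq(grp) if "fov_mm" in grp.attrs else None
        return SignalMap(s=_load_complex(grp, "s"),
                         inphase_time_ms=float(grp.attrs["inphase_time_ms"]),
                         inphase_index=int(grp.attrs["inphase_index"]),
                         acq=acq)
    if kind == "sensitivity_map":
        return SensitivityMap(b=_load_complex(grp, "b"),
                              mask=np.asarray(grp["mask"], dtype=bool),
                              norm_convention=str(grp.attrs["norm_convention"]))
    if kind == "snr_map":
        return SNRMap(snr=np.asarray(grp["snr"]),
                      mask=np.asarray(grp["mask"], dtype=bool),
                      n_channels=int(grp.attrs["n_channels"]))
    if kind == "gfactor_map":
        return GFactorMap(g=np.asarray(grp["g"]),
                          accel_R=int(grp.attrs["accel_R"]),
                          direction=str(grp.attrs["direction"]),
                          mask=np.asarray(grp["mask"], dtype=bool))
    if kind == "tx_map":
        return TxMap(beta=np.asarray(grp["beta"]),
                     smoothed=bool(grp.attrs["smoothed"]))
    raise ValidationError(f"unknown record kind {kind!r}")


def read_container(path):
    """Read an HDF5 container back into its typed object.

    Invariants are re-validated on load; any inconsistency between the
    stored metadata and array shapes raises :class:`ValidationError`.
    Unknown schema versions raise loudly rather than guessing.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported schema version {version} (expected {SCHEMA_VERSION})")
        kind = f.attrs["kind"]
        if kind == "csi_raw":
            raw = f["raw"]
            return CSIRawData(
                kspace=_load_complex(raw, "kspace"),
                acq=_read_acq(raw),
                channel_labels=[str(c) for c in raw.attrs["channel_labels"]])
        if kind == "noise_record":
            return _read_noise_group(f["noise"])
        return _read_map(f["derived/map"])


def read_noise(path) -> NoiseRecord:
    """Read the companion noise record bundled in a raw-data container.

    Raises :class:`MissingInputError` when the container has no noise
    group — the QA protocol cannot run without the noise measurement.
    """
    with h5py.File(path, "r") as f:
        if "noise" not in f:
            raise MissingInputError(
                f"container {path!s} has no noise record; the protocol "
                "requires a noise-only acquisition")
        return _read_noise_group(f["noise"])


def read_ismrmrd(path, acq: AcquisitionSpec) -> CSIRawData:
    """Optional adapter: map an ISMRMRD HDF5 raw file to :class:`CSIRawData`.

    Requires the ``ismrmrd`` package (not a core dependency).  Each
    acquisition's readout is taken as one FID; its ``kspace_encode_step_1``
    and ``kspace_encode_step_2`` indices address the phase-encode grid.
    The acquisition metadata are supplied by the caller, since CSI
    protocols rarely fill every ISMRMRD header field consistently.
    """
    try:
        import ismrmrd  # noqa: F401
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading ISMRMRD files requires the optional 'ismrmrd' package"
        ) from e
    dset = ismrmrd.Dataset(str(path), create_if_needed=False)
    nkx, nky = acq.matrix
    first = dset.read_acquisition(0)
    nch = first.data.shape[0]
    k = np.zeros((nkx, nky, nch, acq.n_fid_points), dtype=np.complex128)
    for i in range(dset.number_of_acquisitions()):
        a = dset.read_acquisition(i)
        ix = int(a.idx.kspace_encode_step_1)
        iy = int(a.idx.kspace_encode_step_2)
        k[ix, iy, :, :] = a.data[:, :acq.n_fid_points]
    return CSIRawData(kspace=k, acq=acq)


def write_derived(path, name: str, data) -> None:
    """Append a derived map under ``/derived/<name>`` of an existing file."""
    with h5py.File(path, "a") as f:
        f.attrs.setdefault("schema_version", SCHEMA_VERSION)
        grp = f.require_group("derived")
        if name in grp:
            del grp[name]
        sub = grp.create_group(name)
        root_kind = f.attrs.get("kind", None)
        _write_map(f, sub, data)
        if root_kind is not None:  # keep the file's primary kind
            f.attrs["kind"] = root_kind


def read_derived(path, name: str):
    with h5py.File(path, "r") as f:
        if "derived" not in f or name not in f["derived"]:
            raise MissingInputError(f"no derived record {name!r} in {path!s}")
        return _read_map(f["derived"][name])
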
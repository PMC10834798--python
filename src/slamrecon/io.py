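"""Container formats: HDF5 k-space, NIfTI label masks, YAML configs, exports.

The HDF5 layout is fixed: datasets ``samples`` (complex [M, T]), ``k_index``
([M, 3] int16) and ``averages`` ([M] int16); attributes ``fov_mm``,
``matrix``, ``dwell_s``, ``tr_s``, ``gated``, ``seed`` and ``shift_voxels``.
Masks are uint8 NIfTI label volumes with an RAS affine encoding the FOV and
voxel size; label-name maps travel in a YAML sidecar.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .acquisition import KSpaceData, Protocol
from .core import AcquisitionGeometry, Fid, GeometryError, SchemaError
from .phantom import CompartmentMask

_REQUIRED_DATASETS = ("samples", "k_index", "averages")
_REQUIRED_ATTRS = ("fov_mm", "matrix", "dwell_s")

DEFAULT_LABEL_NAMES = {0: "other", 1: "heart", 2: "chest_wall"}


def write_kspace(data: KSpaceData, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=data.samples)
        f.create_dataset("k_index", data=data.k_index.astype(np.int16))
        f.create_dataset("averages", data=data.averages.astype(np.int16))
        f.attrs["fov_mm"] = np.asarray(data.geometry.fov_mm)
        f.attrs["matrix"] = np.asarray(data.geometry.matrix)
        f.attrs["dwell_s"] = data.dwell_s
        f.attrs["shift_voxels"] = np.asarray(data.shift_voxels)
        for key in ("tr_s", "gated", "seed", "noise_sigma"):
            if key in data.protocol and data.protocol[key] is not None:
                f.attrs[key] = data.protocol[key]
        if data.cardiac_phase_log is not None:
            f.create_dataset("cardiac_phase_log", data=data.cardiac_phase_log)


def read_kspace(path: str | Path) -> KSpaceData:
    """Read a k-space container; complex64 data are upcast with a flag."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise SchemaError(f"missing dataset {name!r} in {path}")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise SchemaError(f"missing attribute {name!r} in {path}")
        raw = f["samples"][()]
        upcast = str(raw.dtype) if raw.dtype != np.complex128 else None
        geometry = AcquisitionGeometry(
            tuple(f.attrs["fov_mm"]), tuple(int(v) for v in f.attrs["matrix"]))
        protocol = {k: (bool(f.attrs[k]) if k == "gated" else f.attrs[k].item()
                        if hasattr(f.attrs[k], "item") else f.attrs[k])
                    for k in ("tr_s", "gated", "seed", "noise_sigma")
                    if k in f.attrs}
        phase_log = (f["cardiac_phase_log"][()]
                     if "cardiac_phase_log" in f else None)
        return KSpaceData(
            samples=raw.astype(np.complex128),
            k_index=f["k_index"][()],
            averages=f["averages"][()],
            dwell_s=float(f.attrs["dwell_s"]),
            geometry=geometry,
            protocol=protocol,
            shift_voxels=tuple(f.attrs.get("shift_voxels", (0.0, 0.0, 0.0))),
            cardiac_phase_log=phase_log,
            upcast_from=upcast,
        )


def _mask_affine(geometry: AcquisitionGeometry) -> np.ndarray:
    """RAS affine: diagonal voxel size, origin at the first voxel centre."""
    aff = np.eye(4)
    for a in range(3):
        aff[a, a] = geometry.voxel_mm[a]
        aff[a, 3] = -geometry.fov_mm[a] / 2.0 + geometry.voxel_mm[a] / 2.0
    return aff


def write_mask(mask: CompartmentMask, path: str | Path,
               sidecar: str | Path | None = None) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.uint8),
                          _mask_affine(mask.geometry))
    nib.save(img, str(path))
    sidecar = sidecar or Path(str(path)).with_suffix("").with_suffix(".labels.yaml")
    with open(sidecar, "w") as f:
        yaml.safe_dump({int(k): str(v) for k, v in mask.label_names.items()}, f)


def read_mask(path: str | Path, geometry: AcquisitionGeometry,
              sidecar: str | Path | None = None,
              label_names: dict[int, str] | None = None) -> CompartmentMask:
    """Load a NIfTI label mask, validating grid and affine against ``geometry``.

    No silent resampling: a shape or affine mismatch raises; use
    ``resample_mask_majority`` explicitly for localizer-grid masks.
    """
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise SchemaError("mask voxels are not integer labels")
        labels = np.round(labels).astype(np.uint16)
    if tuple(labels.shape) != tuple(geometry.matrix):
        raise GeometryError(
            f"mask grid {labels.shape} != acquisition matrix "
            f"{geometry.matrix}; resample explicitly if intended")
    if not np.allclose(img.affine, _mask_affine(geometry), atol=0.1):
        raise GeometryError("mask affine inconsistent with declared FOV")
    names = dict(label_names or DEFAULT_LABEL_NAMES)
    if sidecar is None:
        candidate = Path(str(path)).with_suffix("").with_suffix(".labels.yaml")
        if candidate.exists():
            sidecar = candidate
    if sidecar is not None:
        with open(sidecar) as f:
            names = {int(k): str(v) for k, v in yaml.safe_load(f).items()}
    return CompartmentMask(labels, names, geometry)


def resample_mask_majority(
    labels: np.ndarray, source_geometry: AcquisitionGeometry,
    target_geometry: AcquisitionGeometry,
    label_names: dict[int, str] | None = None,
) -> CompartmentMask:
    """Majority-vote downsampling of a localizer-grid label volume.

    Each target voxel takes the most frequent source label among the source
    voxels whose centres fall inside it; ties go to the lower label.
    """
    if tuple(source_geometry.fov_mm) != tuple(target_geometry.fov_mm):
        raise GeometryError("source and target FOV differ")
    src = np.asarray(labels)
    if tuple(src.shape) != tuple(source_geometry.matrix):
        raise GeometryError("labels do not match source geometry")
    tgt_shape = target_geometry.matrix
    out = np.zeros(tgt_shape, dtype=src.dtype)
    # map each source voxel centre to its containing target voxel
    bins = []
    for a in range(3):
        centers = source_geometry.axis_centers(a)
        idx = np.floor(
            (centers + target_geometry.fov_mm[a] / 2.0)
            / target_geometry.voxel_mm[a]
        ).astype(int)
        bins.append(np.clip(idx, 0, tgt_shape[a] - 1))
    bx, by, bz = np.meshgrid(*bins, indexing="ij")
    flat_tgt = np.ravel_multi_index((bx.ravel(), by.ravel(), bz.ravel()),
                                    tgt_shape)
    flat_lab = src.ravel()
    for t in np.unique(flat_tgt):
        vals = flat_lab[flat_tgt == t]
        labs, counts = np.unique(vals, return_counts=True)
        out.ravel()[t] = labs[np.argmax(counts)]  # ties: lower label wins
    return CompartmentMask(out, dict(label_names or DEFAULT_LABEL_NAMES),
                           target_geometry)


# ---------------------------------------------------------------------------
# YAML configs


def protocol_to_yaml(protocol: Protocol, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(protocol.to_dict(), f)


def protocol_from_yaml(path: str | Path) -> Protocol:
    with open(path) as f:
        d = yaml.safe_load(f) or {}
    return Protocol(**d)


def phantom_params_to_yaml(params: dict, path: str | Path) -> None:
    """Persist ``build_default_phantom`` keyword arguments."""
    with open(path, "w") as f:
        yaml.safe_dump(params, f)


def phantom_params_from_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


# ---------------------------------------------------------------------------
# spectrum exports


def export_spectrum_csv(fid: Fid, path: str | Path) -> None:
    """Write (frequency Hz, real, imaginary) rows of the spectrum."""
    freq, spec = fid.spectrum()
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["freq_hz", "real", "imag"])
        for fr, s in zip(freq, spec):
            w.writerow([f"{fr:.6f}", f"{s.real:.10e}", f"{s.imag:.10e}"])


def export_jmrui_txt(fid: Fid, path: str | Path, name: str = "slamrecon") -> None:
    """Minimal jMRUI-compatible text export of the time-domain signal."""
    with open(path, "w") as f:
        f.write("jMRUI Data Textfile\n\n")
        f.write(f"Filename: {name}\n\n")
        f.write(f"PointsInDataset: {len(fid)}\n")
        f.write("DatasetsInFile: 1\n")
        f.write(f"SamplingInterval: {fid.dwell_s * 1e3:.6f}\n")
        f.write("ZeroOrderPhase: 0\nBeginTime: 0\n")
        f.write("TransmitterFrequency: 49.9E6\nMagneticField: 3E0\n")
        f.write("TypeOfNucleus: 31P\n\n")
        f.write("Signal and FFT\nsig(real)\tsig(imag)\tfft(real)\tfft(imag)\n")
        f.write("Signal 1 out of 1 in file\n")
        _, spec = fid.spectrum()
        for s, sp in zip(fid.data, spec):
            f.write(f"{s.real:.6e}\t{s.imag:.6e}\t{sp.real:.6e}\t{sp.imag:.6e}\n")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=default, allow_nan=True)
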
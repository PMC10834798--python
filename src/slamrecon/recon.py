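"""Reconstruction: per-voxel Fourier (FT-MRS) and per-compartment (SLAM).

The compartment solver reduces the phase-encoded signal equation to C linear
unknowns per time point, with encoding matrix
``E[m, c] = n(k_m) * sum_{r in c} exp(-2i pi k_m . r / N)`` and row weights
``1/sqrt(n(k_m))`` whitening the summed-average noise.  The system is solved
per time point by an SVD pseudoinverse with a relative singular-value cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .acquisition import KSpaceData
from .core import (
    AcquisitionGeometry,
    ConsistencyError,
    Fid,
    IllConditionedError,
    SelectionError,
    UnderDeterminedError,
    UnsupportedOperationError,
)
from .phantom import CompartmentMask, rasterize_masks


@dataclass
class SpectralGrid:
    """Per-voxel FIDs on the acquisition matrix, shape (Nx, Ny, Nz, T)."""

    fids: np.ndarray
    dwell_s: float
    geometry: AcquisitionGeometry
    log: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if tuple(self.fids.shape[:3]) != tuple(self.geometry.matrix):
            raise ConsistencyError("grid shape does not match acquisition matrix")

    def voxel_fid(self, index: tuple[int, int, int]) -> Fid:
        return Fid(self.fids[tuple(index)], self.dwell_s,
                   meta={"voxel_index": tuple(int(i) for i in index)})


@dataclass
class SlamSystem:
    encoding: np.ndarray            # complex [M, C]
    weights: np.ndarray             # [M], 1/sqrt(n(k))
    labels: list[int]
    names: list[str]
    voxel_counts: list[int]

    @property
    def n_compartments(self) -> int:
        return self.encoding.shape[1]


@dataclass
class CompartmentSpectra:
    """One per-voxel-normalised FID per compartment plus conditioning info."""

    fids: dict[str, Fid]
    conditioning: dict[str, Any]

    def __getitem__(self, name: str) -> Fid:
        return self.fids[name]


def _grid_from_samples(kspace: KSpaceData) -> np.ndarray:
    """Place acquired samples on the full grid (zero-filled), FFT index order."""
    n = kspace.geometry.matrix
    grid = np.zeros((*n, kspace.n_time), dtype=np.complex128)
    idx = kspace.k_index % np.array(n)
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = kspace.samples
    return grid


def recon_ft(kspace: KSpaceData) -> SpectralGrid:
    """Inverse spatial DFT of the (summed, zero-filled) k-space data.

    Normalised so a noiseless unweighted acquisition of a voxel-aligned object
    returns the true voxel FIDs; any acquisition weighting stays in the data
    as the inherent apodization.
    """
    grid = _grid_from_samples(kspace)
    fids = np.fft.ifftn(grid, axes=(0, 1, 2))
    return SpectralGrid(
        fids, kspace.dwell_s, kspace.geometry,
        log={"method": "ft", "shift_voxels": tuple(kspace.shift_voxels)},
    )


def septal_voxel_index(mask: CompartmentMask, heart_label: int | None = None,
                       chest_label: int | None = None) -> tuple[int, int, int]:
    """Deterministic mid-septal voxel choice.

    Among heart voxels with no face-adjacent chest-wall voxel, take the one
    nearest (in mm) to the heart-label centroid; ties break on the lowest
    linear index.  Falls back to all heart voxels if every candidate touches
    the chest wall.
    """
    name_to_label = {v: k for k, v in mask.label_names.items()}
    if heart_label is None:
        heart_label = name_to_label.get("heart")
    if chest_label is None:
        chest_label = name_to_label.get("chest_wall")
    if heart_label is None:
        raise SelectionError("mask has no heart compartment")
    heart = mask.labels == heart_label
    if not np.any(heart):
        raise SelectionError("mask contains no heart voxels")

    candidates = heart.copy()
    if chest_label is not None:
        chest = mask.labels == chest_label
        touches = np.zeros_like(heart)
        for axis in range(3):
            for step in (-1, 1):
                shifted = np.roll(chest, step, axis=axis)
                # roll wraps; suppress the wrapped plane
                sl = [slice(None)] * 3
                sl[axis] = 0 if step == 1 else -1
                shifted[tuple(sl)] = False
                touches |= shifted
        pure = heart & ~touches
        if np.any(pure):
            candidates = pure

    voxel = np.array(mask.geometry.voxel_mm)
    idx = np.argwhere(candidates)
    centroid = np.argwhere(heart).mean(axis=0)
    d2 = np.sum(((idx - centroid) * voxel) ** 2, axis=1)
    lin = np.ravel_multi_index(idx.T, mask.labels.shape)
    order = np.lexsort((lin, np.round(d2, 9)))
    return tuple(int(v) for v in idx[order[0]])


def select_septal_voxel(
    grid: SpectralGrid,
    mask: CompartmentMask,
    override_index: tuple[int, int, int] | None = None,
) -> Fid:
    """FID of the mid-septal voxel (or an explicit override index)."""
    if tuple(mask.labels.shape) != tuple(grid.geometry.matrix):
        raise ConsistencyError("mask grid does not match spectral grid")
    index = override_index or septal_voxel_index(mask)
    return grid.voxel_fid(index)


def build_slam_system(mask: CompartmentMask, kspace: KSpaceData) -> SlamSystem:
    """Encoding matrix mapping compartment FIDs to acquired k-space rows.

    A mask carrying an offset (from ``shift_mask``) describes anatomy in a
    shifted FOV frame.  When the mask has continuous-space provenance the
    encoding is built from the anatomy rasterized in the original frame and
    the full offset is applied as a linear k-space phase, making FOV-shift
    compensation exact even for fractional-voxel shifts; without provenance
    the (integer-rolled) labels are used directly.
    """
    n = kspace.geometry.matrix
    if tuple(mask.labels.shape) != tuple(n):
        raise ConsistencyError("mask grid does not match acquisition matrix")
    offset_vox = np.asarray(mask.offset_mm) / np.array(mask.geometry.voxel_mm)
    label_source = mask
    phase_vox = np.zeros(3)
    if np.any(offset_vox != 0) and mask.phantom is not None:
        label_source = rasterize_masks(mask.phantom,
                                       cardiac_phase=mask.cardiac_phase)
        phase_vox = offset_vox
    labels = label_source.present_labels
    m = kspace.n_encodes
    if m < len(labels):
        raise UnderDeterminedError(
            f"{m} encodes < {len(labels)} compartments; system under-determined"
        )
    idx = kspace.k_index % np.array(n)
    cols = []
    for lab in labels:
        f = np.fft.fftn(label_source.indicator(lab))
        cols.append(f[idx[:, 0], idx[:, 1], idx[:, 2]])
    encoding = np.stack(cols, axis=1) * kspace.averages[:, None]
    if np.any(phase_vox != 0):
        phase = np.exp(-2j * np.pi * (kspace.k_index @ (phase_vox / np.array(n))))
        encoding = encoding * phase[:, None]
    mask = label_source
    weights = 1.0 / np.sqrt(kspace.averages.astype(float))
    names = [mask.label_names.get(lab, f"label_{lab}") for lab in labels]
    counts = [mask.voxel_count(lab) for lab in labels]
    return SlamSystem(encoding, weights, labels, names, counts)


def recon_slam(
    kspace: KSpaceData, mask: CompartmentMask, rcond: float = 1e-8
) -> CompartmentSpectra:
    """Weighted-least-squares compartment spectra via a truncated SVD solve.

    Per time point t: ``min || diag(w) (s(., t) - E rho(t)) ||_2`` with
    ``w = 1/sqrt(n(k))``.  Because each column of E sums the encoding phases
    over the compartment's voxels, the solution is already the mean signal
    per voxel of that compartment (for full unweighted k-space it equals the
    average of the Fourier-reconstructed voxel FIDs), so no further
    normalization is applied.
    """
    system = build_slam_system(mask, kspace)
    ew = system.weights[:, None] * system.encoding
    sw = system.weights[:, None] * kspace.samples
    u, s, vh = np.linalg.svd(ew, full_matrices=False)
    keep = s > rcond * s[0]
    rank = int(np.count_nonzero(keep))
    c = system.n_compartments
    if rank < c:
        # name compartments dominating the truncated right-singular directions
        bad = set()
        for i in np.nonzero(~keep)[0]:
            weights = np.abs(vh[i])
            for j in np.nonzero(weights > 1.0 / np.sqrt(2 * c))[0]:
                bad.add(system.names[j])
        raise IllConditionedError(
            f"effective rank {rank} < {c} compartments at rcond={rcond}; "
            f"collapsing: {sorted(bad)}",
            singular_values=s, compartments=sorted(bad),
        )
    inv = (vh.conj().T[:, keep] / s[keep]) @ u[:, keep].conj().T
    rho = inv @ sw                                   # [C, T]
    fids = {}
    for i, name in enumerate(system.names):
        fids[name] = Fid(
            rho[i], kspace.dwell_s,
            meta={"compartment": name, "label": system.labels[i],
                  "voxel_count": system.voxel_counts[i]},
        )
    conditioning = {
        "singular_values": s,
        "effective_rank": rank,
        "rcond": rcond,
        "condition_number": float(s[0] / s[-1]) if s[-1] > 0 else np.inf,
        "compartments": list(system.names),
    }
    return CompartmentSpectra(fids, conditioning)


def shift_mask(mask: CompartmentMask, delta_voxels) -> CompartmentMask:
    """Mask matching data shifted by ``shift_fov(delta_voxels)``.

    Re-rasterizes the continuous-space compartment geometry displaced by
    ``delta * voxel_mm`` when provenance is available; falls back to a
    circular roll for integer shifts.
    """
    delta = np.asarray(delta_voxels, dtype=float)
    if np.all(delta == 0):
        return mask
    if mask.phantom is not None:
        voxel = np.array(mask.geometry.voxel_mm)
        offset = np.asarray(mask.offset_mm) + delta * voxel
        return rasterize_masks(
            mask.phantom, cardiac_phase=mask.cardiac_phase,
            offset_mm=tuple(offset),
        )
    if np.allclose(delta, np.round(delta)):
        shifted = np.roll(mask.labels, tuple(int(d) for d in np.round(delta)),
                          axis=(0, 1, 2))
        return CompartmentMask(shifted, dict(mask.label_names), mask.geometry)
    raise UnsupportedOperationError(
        "fractional mask shift requires continuous-space provenance"
    )
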
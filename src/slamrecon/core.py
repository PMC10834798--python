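"""Shared low-level types: acquisition geometry, FIDs, and the error hierarchy."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class SlamreconError(Exception):
    """Base class for all package errors."""


class ParameterError(SlamreconError, ValueError):
    """An argument is out of its documented domain."""


class ConsistencyError(SlamreconError):
    """Inputs are individually valid but mutually inconsistent."""


class GeometryError(SlamreconError):
    """Spatial metadata (FOV/matrix/affine) does not match."""


class UnderDeterminedError(SlamreconError):
    """Fewer phase encodes than compartments."""


class IllConditionedError(SlamreconError):
    """The compartment system lost rank at the requested truncation level."""

    def __init__(self, message: str, singular_values=None, compartments=None):
        super().__init__(message)
        self.singular_values = singular_values
        self.compartments = compartments or []


class SelectionError(SlamreconError):
    """Voxel selection impossible (e.g. no heart voxels in the mask)."""


class FitError(SlamreconError):
    """Spectral fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CorrectionError(SlamreconError):
    """Blood/saturation correction produced a non-physical result."""


class PairingError(SlamreconError):
    """Test-retest pairing incomplete."""


class UndefinedStatisticError(SlamreconError):
    """The requested statistic is undefined for this input."""


class SchemaError(SlamreconError):
    """A container file is missing a required dataset or attribute."""


class UnsupportedOperationError(SlamreconError):
    """Operation requires provenance/metadata the object does not carry."""


class ConfigurationError(SlamreconError):
    """Processing parameters incompatible with the data."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Cartesian phase-encoding geometry of the CSI acquisition.

    The field of view is centred on the scanner origin, so voxel centres along
    axis ``a`` lie at ``(i + 0.5) * voxel - fov/2`` for ``i = 0 .. N-1``.
    Axis 1 is the anterior-posterior ("y") phase-encode direction.
    """

    fov_mm: tuple[float, float, float] = (240.0, 240.0, 200.0)
    matrix: tuple[int, int, int] = (8, 16, 8)

    def __post_init__(self):
        if len(self.fov_mm) != 3 or len(self.matrix) != 3:
            raise ParameterError("fov_mm and matrix must have three entries")
        object.__setattr__(self, "fov_mm", tuple(float(v) for v in self.fov_mm))
        object.__setattr__(self, "matrix", tuple(int(v) for v in self.matrix))
        for n in self.matrix:
            if n < 2 or n % 2:
                raise ParameterError(f"matrix entries must be even and >= 2, got {n}")
        for v in self.fov_mm:
            if v <= 0:
                raise ParameterError("fov_mm entries must be positive")

    @property
    def voxel_mm(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.fov_mm, self.matrix))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.matrix))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        n = self.matrix[axis]
        d = self.voxel_mm[axis]
        return (np.arange(n) + 0.5) * d - self.fov_mm[axis] / 2.0

    def voxel_centers(self) -> np.ndarray:
        """All voxel centres as an ``(Nx, Ny, Nz, 3)`` array in mm."""
        ax = [self.axis_centers(a) for a in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def k_indices(self) -> np.ndarray:
        """Signed k-space grid indices, shape ``(Nvox, 3)``, -N/2 .. N/2-1."""
        ranges = [np.arange(-n // 2, n // 2) for n in self.matrix]
        kx, ky, kz = np.meshgrid(*ranges, indexing="ij")
        return np.stack([kx.ravel(), ky.ravel(), kz.ravel()], axis=-1)


@dataclass
class Fid:
    """A complex time-domain signal sampled uniformly from t = 0.

    ``lb_hz`` records the cumulative exponential line-broadening applied so
    linewidths can be book-kept after fitting.
    """

    data: np.ndarray
    dwell_s: float
    lb_hz: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 1:
            raise ParameterError("Fid data must be one-dimensional")
        if self.dwell_s <= 0:
            raise ParameterError("dwell_s must be positive")

    def __len__(self) -> int:
        return self.data.size

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.data.size) * self.dwell_s

    @property
    def bandwidth_hz(self) -> float:
        return 1.0 / self.dwell_s

    def spectrum(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (frequency axis Hz ascending, complex spectrum).

        Plain unnormalised FFT, frequency-shifted so index 0 is the most
        negative frequency.
        """
        spec = np.fft.fftshift(np.fft.fft(self.data))
        freq = np.fft.fftshift(np.fft.fftfreq(self.data.size, self.dwell_s))
        return freq, spec

    def copy_with(self, data: np.ndarray, **meta) -> "Fid":
        new = Fid(np.asarray(data), self.dwell_s, self.lb_hz, dict(self.meta))
        new.meta.update(meta)
        return new


def check_uniform_time_axis(time_axis_s: np.ndarray) -> float:
    """Validate a uniform time axis starting at 0 and return the dwell time."""
    t = np.asarray(time_axis_s, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ParameterError("time axis must be 1-D with at least two samples")
    if abs(t[0]) > 1e-15:
        raise ParameterError("time axis must start at 0")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-15) or steps[0] <= 0:
        raise ParameterError("time axis must be uniformly increasing")
    return float(steps[0])
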
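"""Forward simulation of acquisition-weighted 3D phase-encoded CSI.

Conventions (fixed, documented):

* signed k-space indices k in -N/2 .. N/2-1 per axis; forward encoding uses
  ``exp(-2i pi k . r / N)`` over voxel indices r;
* acquisition-weighted repeats are SUMMED, not averaged, so the per-encode
  average count acts as the k-space apodization window; the Fourier recon
  divides by nothing and the compartment solver models n(k) in its system
  matrix;
* ``shift_fov`` multiplies samples by ``exp(-2i pi k . delta / N)``, which
  moves the reconstructed object toward *positive* voxel index by ``delta``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .core import AcquisitionGeometry, ConsistencyError, ParameterError
from .phantom import PhantomDefinition, compartment_fid

_WINDOWS = {}


def _register(name):
    def deco(fn):
        _WINDOWS[name] = fn
        return fn
    return deco


@_register("uniform")
def _w_uniform(k: np.ndarray, n: int) -> np.ndarray:
    return np.ones_like(k, dtype=float)


@_register("hann")
def _w_hann(k: np.ndarray, n: int) -> np.ndarray:
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * k / n))


@_register("hamming")
def _w_hamming(k: np.ndarray, n: int) -> np.ndarray:
    return 0.54 + 0.46 * np.cos(2.0 * np.pi * k / n)


@dataclass(frozen=True)
class AWScheme:
    """Acquisition-weighting scheme: averages per signed k-space index.

    ``averages_grid`` is indexed by ``k + N/2`` per axis (most negative k
    first).  Points with zero averages are not acquired.
    """

    matrix: tuple[int, int, int]
    averages_grid: np.ndarray
    max_averages: int
    window: str

    @property
    def k_index(self) -> np.ndarray:
        """Acquired signed k indices, shape (M, 3), in C scan order."""
        idx = np.argwhere(self.averages_grid > 0)
        return idx - np.array([n // 2 for n in self.matrix])

    @property
    def averages(self) -> np.ndarray:
        """Average count per acquired encode, aligned with ``k_index``."""
        return self.averages_grid[self.averages_grid > 0].astype(int)

    def averages_at(self, k: np.ndarray) -> np.ndarray:
        k = np.atleast_2d(k)
        idx = k + np.array([n // 2 for n in self.matrix])
        return self.averages_grid[idx[:, 0], idx[:, 1], idx[:, 2]]

    @property
    def total_readouts(self) -> int:
        return int(self.averages_grid.sum())


def build_aw_scheme(
    matrix: tuple[int, int, int] = (8, 16, 8),
    max_averages: int = 10,
    window: str = "hann",
) -> AWScheme:
    """Separable rounded k-space weighting, ``max_averages`` at the centre."""
    if max_averages < 1:
        raise ParameterError("max_averages must be >= 1")
    try:
        wfn = _WINDOWS[window]
    except KeyError:
        raise ParameterError(
            f"unknown window {window!r}; choose from {sorted(_WINDOWS)}"
        ) from None
    matrix = tuple(int(n) for n in matrix)
    axes = [wfn(np.arange(-n // 2, n // 2), n) for n in matrix]
    w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    grid = np.rint(max_averages * w).astype(int)
    return AWScheme(matrix, grid, int(max_averages), window)


@dataclass(frozen=True)
class Protocol:
    """Timing, gating, noise and excitation settings for one acquisition."""

    tr_s: float = 0.9
    gated: bool = False
    rr_mean_s: float = 0.95
    rr_sd_s: float = 0.06
    noise_sigma: float = 0.0
    seed: int = 0
    saturation: bool = True
    excitation_center_hz: float | None = -250.0
    excitation_bw_hz: float = 1500.0
    t1_saturation: bool = False
    flip_angle_deg: float = 30.0

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ParameterError("tr_s must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    def in_band(self, freq_hz: float) -> bool:
        if self.excitation_center_hz is None:
            return True
        half = self.excitation_bw_hz / 2.0
        return abs(freq_hz - self.excitation_center_hz) <= half

    def steady_state_factor(self, t1_s: float | None) -> float:
        """Partial-saturation amplitude factor (1-E)/(1-E cos alpha)."""
        if not self.t1_saturation or t1_s is None:
            return 1.0
        e = np.exp(-self.tr_s / t1_s)
        alpha = np.deg2rad(self.flip_angle_deg)
        return float((1.0 - e) / (1.0 - e * np.cos(alpha)))

    def to_dict(self) -> dict[str, Any]:
        return {
            "tr_s": self.tr_s, "gated": self.gated, "rr_mean_s": self.rr_mean_s,
            "rr_sd_s": self.rr_sd_s, "noise_sigma": self.noise_sigma,
            "seed": self.seed, "saturation": self.saturation,
            "excitation_center_hz": self.excitation_center_hz,
            "excitation_bw_hz": self.excitation_bw_hz,
            "t1_saturation": self.t1_saturation,
            "flip_angle_deg": self.flip_angle_deg,
        }


@dataclass
class KSpaceData:
    """Acquired/simulated CSI samples (sum over averages) per phase encode."""

    samples: np.ndarray           # complex, [M, T]
    k_index: np.ndarray           # int, [M, 3], signed
    averages: np.ndarray          # int, [M]
    dwell_s: float
    geometry: AcquisitionGeometry
    protocol: dict[str, Any] = field(default_factory=dict)
    shift_voxels: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cardiac_phase_log: np.ndarray | None = None
    upcast_from: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        self.k_index = np.asarray(self.k_index, dtype=int)
        self.averages = np.asarray(self.averages, dtype=int)
        m = self.samples.shape[0]
        if self.k_index.shape != (m, 3) or self.averages.shape != (m,):
            raise ConsistencyError("samples, k_index and averages disagree on M")
        if m > self.geometry.n_voxels:
            raise ConsistencyError("more encodes than grid points")
        uniq = np.unique(self.k_index, axis=0)
        if uniq.shape[0] != m:
            raise ConsistencyError("duplicate k-space indices")
        if np.any(self.averages < 1):
            raise ConsistencyError("acquired encodes must have >= 1 average")

    @property
    def n_encodes(self) -> int:
        return self.samples.shape[0]

    @property
    def n_time(self) -> int:
        return self.samples.shape[1]


def effective_components(phantom: PhantomDefinition, name: str, protocol: Protocol):
    """Compartment components after excitation-band and T1-saturation scaling."""
    out = []
    for c in phantom.effective_components(name):
        if not protocol.in_band(c.freq_offset_hz):
            continue  # ideal band edge: out-of-band resonances excited to zero
        f = protocol.steady_state_factor(c.t1_s)
        out.append(replace(c, amplitude=c.amplitude * f))
    return tuple(out)


def _structure_factor_grid(weight: np.ndarray) -> np.ndarray:
    """FFT of a spatial weight volume: F(k) = sum_r w[r] e^{-2i pi k.r/N}.

    Returned in unsigned FFT index order; index signed k with ``k % N``.
    """
    return np.fft.fftn(weight)


def _single_structure_factor(weight: np.ndarray, k: np.ndarray) -> complex:
    """Structure factor of one signed k index, without a full FFT."""
    phases = [
        np.exp(-2j * np.pi * k[a] * np.arange(weight.shape[a]) / weight.shape[a])
        for a in range(3)
    ]
    return complex(np.einsum("i,j,k,ijk->", *phases, weight.astype(complex)))


def _cardiac_phase_sequence(protocol: Protocol, rng: np.random.Generator):
    """Cardiac phase of consecutive readouts, one TR apart.

    Readouts march through heartbeats whose durations are drawn from the
    R-R model, so successive phases are strongly correlated (TR and the
    cardiac period are close but incommensurate).  This is what couples the
    cardiac phase to the fixed k-space ordering differently in every scan:
    the few central-k readouts of one scan share only a couple of effective
    heart positions, the source of ungated between-scan variability.

    The scan-mean R-R interval is drawn once per scan (the subject's heart
    rate that day) with small beat-to-beat jitter on top: a scan whose R-R
    happens to be nearly commensurate with TR is effectively pseudo-gated at
    a random cardiac phase, the worst case for reproducibility.
    """
    rr_scan = max(float(rng.normal(protocol.rr_mean_s, protocol.rr_sd_s)), 0.3)
    beat_jitter = 0.01
    rr = max(float(rng.normal(rr_scan, beat_jitter)), 0.3)
    beat_start = -float(rng.uniform()) * rr  # random phase at scan start
    t = 0.0
    while True:
        while t >= beat_start + rr:
            beat_start += rr
            rr = max(float(rng.normal(rr_scan, beat_jitter)), 0.3)
        yield (t - beat_start) / rr
        t += protocol.tr_s


def simulate_acquisition(
    phantom: PhantomDefinition,
    scheme: AWScheme,
    protocol: Protocol,
    n_time: int = 512,
    dwell_s: float = 1.0 / 4000.0,
) -> KSpaceData:
    """Simulate the phase-encoded acquisition, one FID per readout.

    Each readout sees the phantom frozen at a cardiac phase: exactly 0 when
    gated, otherwise the phase a TR-spaced readout train reaches as it
    marches through heartbeats drawn from the protocol's R-R model.
    Complex Gaussian noise of SD ``noise_sigma`` per real/imaginary channel
    is added per readout; repeats are summed.  Deterministic for a fixed
    protocol seed.
    """
    geom = phantom.geometry
    if tuple(scheme.matrix) != tuple(geom.matrix):
        raise ConsistencyError(
            f"scheme matrix {scheme.matrix} != phantom matrix {geom.matrix}"
        )
    if n_time < 256:
        raise ParameterError("n_time must be >= 256")

    t = np.arange(n_time) * dwell_s
    rho = {}
    for c in phantom.compartments:
        comps = effective_components(phantom, c.name, protocol)
        rho[c.name] = (compartment_fid(comps, t).data if comps
                       else np.zeros(n_time, dtype=complex))

    sat = None
    if protocol.saturation and phantom.saturation_slabs:
        from .phantom import saturation_weights

        sat = saturation_weights(phantom)

    # The "other" compartment's spectrum fills every voxel not claimed by a
    # named compartment, so the object is piecewise-constant on the label
    # map (up to sub-compartment structure such as the blood cavity) -- the
    # premise of the compartment reconstruction.
    points = geom.voxel_centers()

    def supports(theta: float) -> dict[str, np.ndarray]:
        out = {}
        claimed = np.zeros(geom.matrix, dtype=bool)
        for c in phantom.compartments:
            if c.name == "other":
                continue
            delta = (phantom.motion.displacement_mm(theta, c.motion_amplitude_mm)
                     if c.motion_amplitude_mm > 0 else np.zeros(3))
            inside = c.contains(points, delta)
            if np.any(inside & claimed):
                if theta % 1.0 == 0.0:
                    raise ConsistencyError(
                        f"compartment {c.name!r} overlaps another at rest")
                inside = inside & ~claimed  # moving tissue presses into rest
            claimed |= inside
            out[c.name] = inside.astype(float)
        for c in phantom.compartments:
            if c.name == "other":
                out["other"] = (~claimed).astype(float)
        if sat is not None:
            out = {k: v * sat for k, v in out.items()}
        return out

    moving = (not protocol.gated) and any(
        c.motion_amplitude_mm > 0 for c in phantom.compartments)

    k_index = scheme.k_index
    averages = scheme.averages
    m = k_index.shape[0]
    nmat = np.array(geom.matrix)
    kmod = tuple((k_index % nmat).T)

    static_supports = supports(0.0)
    base = np.zeros((m, n_time), dtype=np.complex128)
    for name, w in static_supports.items():
        base += np.outer(_structure_factor_grid(w)[kmod], rho[name])

    rng = np.random.default_rng(protocol.seed)
    phase_gen = _cardiac_phase_sequence(protocol, rng)
    samples = np.zeros((m, n_time), dtype=np.complex128)
    phase_log = []
    for i in range(m):
        n_avg = int(averages[i])
        for _ in range(n_avg):
            theta = 0.0 if protocol.gated else next(phase_gen)
            phase_log.append(theta)
            if moving and theta != 0.0:
                s = np.zeros(n_time, dtype=np.complex128)
                for name, w in supports(theta).items():
                    f = _single_structure_factor(w, k_index[i])
                    s += f * rho[name]
            else:
                s = base[i].copy()
            if protocol.noise_sigma > 0:
                s = s + protocol.noise_sigma * (
                    rng.standard_normal(n_time)
                    + 1j * rng.standard_normal(n_time)
                )
            samples[i] += s

    return KSpaceData(
        samples=samples,
        k_index=k_index,
        averages=averages,
        dwell_s=dwell_s,
        geometry=geom,
        protocol=protocol.to_dict(),
        cardiac_phase_log=np.asarray(phase_log),
    )


def shift_fov(kspace: KSpaceData, delta_voxels) -> KSpaceData:
    """Apply a (possibly fractional) FOV shift as a linear k-space phase.

    ``samples(k) <- samples(k) * exp(-2i pi k . delta / N)``; positive delta
    moves the reconstructed object toward positive voxel index.  The cumulative
    shift is recorded in the metadata.
    """
    delta = np.asarray(delta_voxels, dtype=float)
    if delta.shape != (3,):
        raise ParameterError("delta_voxels must have three entries")
    n = np.array(kspace.geometry.matrix, dtype=float)
    phase = np.exp(-2j * np.pi * (kspace.k_index @ (delta / n)))
    return KSpaceData(
        samples=kspace.samples * phase[:, None],
        k_index=kspace.k_index.copy(),
        averages=kspace.averages.copy(),
        dwell_s=kspace.dwell_s,
        geometry=kspace.geometry,
        protocol=dict(kspace.protocol),
        shift_voxels=tuple(np.asarray(kspace.shift_voxels) + delta),
        cardiac_phase_log=kspace.cardiac_phase_log,
    )


def scan_duration(scheme: AWScheme, protocol: Protocol) -> float:
    """Total scan time in seconds: one TR per readout, summed over averages."""
    return scheme.total_readouts * protocol.tr_s
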
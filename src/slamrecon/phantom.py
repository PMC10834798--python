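"""Digital thorax phantom: compartment geometry, spectral ground truth, motion.

The phantom stands in for a scanned subject: a heart compartment (myocyte
signal plus a blood pool), a chest wall with strong PCr, and an ATP-dominant
"other"/liver compartment, all defined as continuous-space shapes in scanner
millimetre coordinates so masks can be re-rasterized at arbitrary sub-voxel
displacements (cardiac motion, FOV-shift compensation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .core import (
    AcquisitionGeometry,
    ConsistencyError,
    Fid,
    ParameterError,
    check_uniform_time_axis,
)

# Chemical-shift defaults in Hz relative to PCr at ~49.9 MHz (3T 31P).
# Literature values, configuration rather than measured quantities.
FREQ_PCR = 0.0
FREQ_GAMMA_ATP = -128.0
FREQ_ALPHA_ATP = -380.0
FREQ_BETA_ATP = -825.0
FREQ_DPG2 = 270.0
FREQ_DPG3 = 320.0

# J-coupling multiplets: gamma/alpha-ATP doublets, beta-ATP triplet.
DOUBLET = ((-8.5, 0.5), (8.5, 0.5))
TRIPLET = ((-17.0, 0.25), (0.0, 0.5), (17.0, 0.25))
SINGLET = ((0.0, 1.0),)

# Longitudinal relaxation defaults (s); literature values, configurable.
T1_DEFAULTS = {"PCr": 5.8, "ATP": 3.1, "DPG": 2.0}


@dataclass(frozen=True)
class SpectralComponent:
    """One resonance (or J-coupled multiplet) of a compartment spectrum.

    The time-domain model is
    ``a * exp(i phi) * sum_m rel_m * exp((-d + 2i pi (f + sub_m)) t)``
    with the multiplet relative amplitudes ``rel_m`` summing to one.
    """

    name: str
    freq_offset_hz: float
    amplitude: float
    damping_s: float
    phase_rad: float = 0.0
    multiplet: tuple[tuple[float, float], ...] = SINGLET
    t1_s: float | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ParameterError(f"{self.name}: amplitude must be >= 0")
        if self.damping_s < 0:
            raise ParameterError(f"{self.name}: damping must be >= 0")
        rel = sum(r for _, r in self.multiplet)
        if abs(rel - 1.0) > 1e-12:
            raise ParameterError(
                f"{self.name}: multiplet relative amplitudes sum to {rel}, not 1"
            )
        if self.t1_s is not None and self.t1_s <= 0:
            raise ParameterError(f"{self.name}: t1 must be positive")

    @property
    def fwhm_hz(self) -> float:
        """Lorentzian full width at half maximum."""
        return self.damping_s / math.pi


@dataclass(frozen=True)
class Box:
    """Axis-aligned box; membership is half-open, [lo, hi) per axis."""

    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.size_mm):
            raise ParameterError("box size must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        h = np.asarray(self.size_mm) / 2.0
        return np.all((p >= c - h) & (p < c + h), axis=-1)

    def translated(self, delta_mm) -> "Box":
        c = tuple(np.asarray(self.center_mm) + np.asarray(delta_mm, dtype=float))
        return Box(c, self.size_mm)


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.semiaxes_mm):
            raise ParameterError("ellipsoid semiaxes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        a = np.asarray(self.semiaxes_mm)
        return np.sum(((p - c) / a) ** 2, axis=-1) <= 1.0

    def translated(self, delta_mm) -> "Ellipsoid":
        c = tuple(np.asarray(self.center_mm) + np.asarray(delta_mm, dtype=float))
        return Ellipsoid(c, self.semiaxes_mm)


@dataclass(frozen=True)
class Carved:
    """Outer shape with an inner shape removed (e.g. a ventricular cavity)."""

    outer: "Box | Ellipsoid"
    inner: "Box | Ellipsoid"

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.outer.contains(points) & ~self.inner.contains(points)

    def translated(self, delta_mm) -> "Carved":
        return Carved(self.outer.translated(delta_mm),
                      self.inner.translated(delta_mm))


@dataclass(frozen=True)
class Intersection:
    """Points inside both shapes (e.g. a cavity slab clipped to the heart)."""

    a: "Box | Ellipsoid | Carved | Intersection"
    b: "Box | Ellipsoid | Carved | Intersection"

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.a.contains(points) & self.b.contains(points)

    def translated(self, delta_mm) -> "Intersection":
        return Intersection(self.a.translated(delta_mm),
                            self.b.translated(delta_mm))


Shape = Box | Ellipsoid | Carved | Intersection


@dataclass(frozen=True)
class CompartmentSpec:
    """Named compartment: shapes, spectral components and motion amplitude.

    ``label_as`` rasterizes this compartment under another compartment's
    mask label (the blood cavity is part of the segmented "heart" even
    though its spectral content differs).
    """

    name: str
    shapes: tuple[Shape, ...]
    components: tuple[SpectralComponent, ...]
    motion_amplitude_mm: float = 0.0
    label_as: str | None = None

    def __post_init__(self):
        if not self.shapes:
            raise ParameterError(f"compartment {self.name!r}: geometry is empty")
        if self.motion_amplitude_mm < 0:
            raise ParameterError("motion amplitude must be >= 0")

    def contains(self, points: np.ndarray, delta_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
        d = np.asarray(delta_mm, dtype=float)
        out = np.zeros(np.asarray(points).shape[:-1], dtype=bool)
        for s in self.shapes:
            out |= s.translated(d).contains(points)
        return out


def _raised_cosine(theta: np.ndarray | float) -> np.ndarray | float:
    return (1.0 - np.cos(2.0 * np.pi * np.asarray(theta, dtype=float))) / 2.0


@dataclass(frozen=True)
class MotionModel:
    """Periodic cardiac displacement; zero at theta = 0 (diastasis).

    The default axis points anterior (toward the chest wall, negative y):
    away from diastasis the heart approaches the chest wall, which is what
    makes ungated acquisitions contamination-sensitive.
    """

    amplitude_mm: float = 8.0
    axis: tuple[float, float, float] = (0.0, -1.0, 0.0)
    phase_function: Callable[[float], float] = _raised_cosine

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise ParameterError("motion amplitude must be >= 0")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ParameterError("motion axis must be non-zero")
        object.__setattr__(self, "axis", tuple(a / n))

    def displacement_mm(self, theta: float, amplitude_mm: float | None = None) -> np.ndarray:
        amp = self.amplitude_mm if amplitude_mm is None else amplitude_mm
        frac = float(self.phase_function(theta % 1.0))
        return amp * frac * np.asarray(self.axis)


@dataclass(frozen=True)
class SaturationSlab:
    """Planar saturation band: signal inside is scaled by (1 - efficiency)."""

    axis: int
    center_mm: float
    thickness_mm: float
    efficiency: float = 1.0

    def __post_init__(self):
        if self.axis not in (0, 1, 2):
            raise ParameterError("slab axis must be 0, 1 or 2")
        if self.thickness_mm <= 0:
            raise ParameterError("slab thickness must be positive")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ParameterError("slab efficiency must be in [0, 1]")

    def weight(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)[..., self.axis]
        inside = np.abs(p - self.center_mm) <= self.thickness_mm / 2.0
        return np.where(inside, 1.0 - self.efficiency, 1.0)


@dataclass(frozen=True)
class PhantomDefinition:
    geometry: AcquisitionGeometry
    compartments: tuple[CompartmentSpec, ...]
    blood_components: tuple[SpectralComponent, ...] = ()
    blood_fraction: float = 0.0
    saturation_slabs: tuple[SaturationSlab, ...] = ()
    motion: MotionModel = field(default_factory=MotionModel)

    def __post_init__(self):
        if not 0.0 <= self.blood_fraction <= 1.0:
            raise ParameterError("blood fraction must be in [0, 1]")

    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def effective_components(self, name: str) -> tuple[SpectralComponent, ...]:
        """Spectral components of one compartment (blood lives in its own
        cavity compartment, created by the phantom builder)."""
        return tuple(self.compartment(name).components)


@dataclass
class CompartmentMask:
    """Integer label volume on the MRSI grid.

    Label 0 is background and belongs to the "other" compartment.  When built
    from a phantom the mask keeps provenance so it can be re-rasterized at
    fractional displacements.
    """

    labels: np.ndarray
    label_names: dict[int, str]
    geometry: AcquisitionGeometry
    phantom: PhantomDefinition | None = None
    cardiac_phase: float = 0.0
    offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if tuple(self.labels.shape) != tuple(self.geometry.matrix):
            raise ConsistencyError(
                f"mask shape {self.labels.shape} != matrix {self.geometry.matrix}"
            )

    @property
    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels))

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def indicator(self, label: int) -> np.ndarray:
        return (self.labels == label).astype(float)


def compartment_fid(
    components: Sequence[SpectralComponent], time_axis_s: np.ndarray
) -> Fid:
    """Sum-of-damped-sinusoids FID for a list of spectral components."""
    dwell = check_uniform_time_axis(time_axis_s)
    t = np.asarray(time_axis_s, dtype=float)
    y = np.zeros(t.size, dtype=np.complex128)
    for c in components:
        for sub, rel in c.multiplet:
            y += (
                c.amplitude
                * rel
                * np.exp(1j * c.phase_rad)
                * np.exp((-c.damping_s + 2j * np.pi * (c.freq_offset_hz + sub)) * t)
            )
    return Fid(y, dwell)


def _has_motion(phantom: PhantomDefinition, cardiac_phase: float) -> bool:
    """True when some compartment is displaced by cardiac motion."""
    if not any(c.motion_amplitude_mm > 0 for c in phantom.compartments):
        return False
    frac = float(phantom.motion.phase_function(cardiac_phase % 1.0))
    return frac != 0.0


def rasterize_masks(
    phantom: PhantomDefinition,
    grid_shape: tuple[int, int, int] | None = None,
    cardiac_phase: float = 0.0,
    offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> CompartmentMask:
    """Label volume by voxel-centre sampling of the compartment shapes.

    ``offset_mm`` displaces every compartment (used for FOV-shift mask
    compensation); cardiac motion additionally displaces compartments with a
    non-zero motion amplitude.  Compartments named "other" rasterize to
    label 0, merging with the background.

    Overlapping geometries are an error in the rest configuration (phase 0,
    no offset).  At displaced phases moving tissue may press into a static
    neighbour; earlier-listed compartments then take the contested voxels.
    """
    geom = phantom.geometry
    if grid_shape is not None and tuple(grid_shape) != tuple(geom.matrix):
        raise ConsistencyError(
            f"grid_shape {tuple(grid_shape)} != phantom matrix {geom.matrix}"
        )
    points = geom.voxel_centers()
    labels = np.zeros(geom.matrix, dtype=np.uint8)
    claimed = np.zeros(geom.matrix, dtype=bool)
    names: dict[int, str] = {0: "other"}
    label_of: dict[str, int] = {"other": 0}
    next_label = 1
    for comp in phantom.compartments:
        delta = np.asarray(offset_mm, dtype=float)
        if comp.motion_amplitude_mm > 0:
            delta = delta + phantom.motion.displacement_mm(
                cardiac_phase, comp.motion_amplitude_mm
            )
        inside = comp.contains(points, delta)
        overlap = inside & claimed
        if np.any(overlap):
            if not _has_motion(phantom, cardiac_phase):
                raise ConsistencyError(
                    f"compartment {comp.name!r} overlaps another at "
                    f"{int(np.count_nonzero(overlap))} voxels"
                )
            inside = inside & ~claimed  # later tissue yields to prior claims
        claimed |= inside
        target = comp.label_as or comp.name
        if target == "other":
            label = 0
        elif target in label_of:
            label = label_of[target]
        else:
            label = next_label
            names[label] = target
            next_label += 1
        label_of[target] = label
        labels[inside] = label
    return CompartmentMask(
        labels, names, geom, phantom=phantom, cardiac_phase=cardiac_phase,
        offset_mm=tuple(np.asarray(offset_mm, dtype=float)),
    )


def saturation_weights(
    phantom: PhantomDefinition, geometry: AcquisitionGeometry | None = None
) -> np.ndarray:
    """Multiplicative spatial suppression map of all saturation slabs."""
    geom = geometry or phantom.geometry
    points = geom.voxel_centers()
    w = np.ones(geom.matrix, dtype=float)
    for slab in phantom.saturation_slabs:
        w *= slab.weight(points)
    return w


def _heart_components(pcr_gamma_ratio: float) -> tuple[SpectralComponent, ...]:
    return (
        SpectralComponent("PCr", FREQ_PCR, pcr_gamma_ratio, 35.0,
                          t1_s=T1_DEFAULTS["PCr"]),
        SpectralComponent("gATP", FREQ_GAMMA_ATP, 1.0, 50.0, multiplet=DOUBLET,
                          t1_s=T1_DEFAULTS["ATP"]),
        SpectralComponent("aATP", FREQ_ALPHA_ATP, 1.0, 50.0, multiplet=DOUBLET,
                          t1_s=T1_DEFAULTS["ATP"]),
        SpectralComponent("bATP", FREQ_BETA_ATP, 1.0, 55.0, multiplet=TRIPLET,
                          t1_s=T1_DEFAULTS["ATP"]),
    )


def default_blood_components() -> tuple[SpectralComponent, ...]:
    """Blood-pool signal at unit volume fraction: 2,3-DPG plus blood ATP.

    Blood gamma-ATP amplitude over the mean single-DPG-peak amplitude is the
    true blood-contamination coefficient kappa = 0.30, matching the default
    used by the ratio correction.
    """
    return (
        SpectralComponent("DPG2", FREQ_DPG2, 1.0, 60.0, t1_s=T1_DEFAULTS["DPG"]),
        SpectralComponent("DPG3", FREQ_DPG3, 1.0, 60.0, t1_s=T1_DEFAULTS["DPG"]),
        SpectralComponent("blood_gATP", FREQ_GAMMA_ATP, 0.30, 60.0,
                          multiplet=DOUBLET, t1_s=T1_DEFAULTS["ATP"]),
        SpectralComponent("blood_aATP", FREQ_ALPHA_ATP, 0.30, 60.0,
                          multiplet=DOUBLET, t1_s=T1_DEFAULTS["ATP"]),
        SpectralComponent("blood_bATP", FREQ_BETA_ATP, 0.30, 60.0,
                          multiplet=TRIPLET, t1_s=T1_DEFAULTS["ATP"]),
    )


def build_default_phantom(
    geometry: AcquisitionGeometry | None = None,
    motion_amplitude_mm: float = 8.0,
    blood_fraction: float = 0.2,
    seed: int | None = None,
    pcr_gamma_ratio: float = 2.0,
    position_jitter_mm: float = 0.0,
    with_saturation_slabs: bool = True,
) -> PhantomDefinition:
    """Three-compartment thorax phantom on the default 8x16x8 grid.

    Anterior (chest-wall) side is negative y.  Geometry is aligned so the
    heart occupies a 4x4x4 voxel block at cardiac phase 0.  ``seed`` only
    matters when ``position_jitter_mm`` > 0, in which case the heart centre is
    jittered to emulate between-subject anatomy.
    """
    if motion_amplitude_mm < 0:
        raise ParameterError("motion_amplitude_mm must be >= 0")
    if not 0.0 <= blood_fraction <= 1.0:
        raise ParameterError("blood_fraction must be in [0, 1]")
    geom = geometry or AcquisitionGeometry()

    jitter = np.zeros(3)
    if position_jitter_mm > 0:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-position_jitter_mm, position_jitter_mm, size=3)

    # Ellipsoidal heart directly behind the chest wall (prone position);
    # the curved anterior surface means a one-voxel FOV shift slides only a
    # small patch of chest wall into the segmented heart.
    heart_center = np.array([0.0, -15.0, 0.0]) + jitter
    heart_semi = np.array([60.0, 45.0, 50.0])
    heart_ell = Ellipsoid(tuple(heart_center), tuple(heart_semi))
    blood_pool: tuple[CompartmentSpec, ...] = ()
    heart_shapes: tuple[Shape, ...] = (heart_ell,)
    if blood_fraction > 0:
        # Ventricular anatomy along the anterior-posterior axis, in default
        # voxel rows: RV cavity (1), septum (1), LV cavity (2), posterior
        # wall (the rest), all clipped to the ellipsoid.  The thin
        # mid-septal wall lies between the two blood pools, so cardiac
        # motion beyond half a voxel sweeps cavity blood through the septal
        # voxel while the whole-heart compartment barely changes.
        # ``blood_fraction`` scales the blood signal density in the
        # cavities; the cavity geometry itself is anatomical.
        row = 15.0
        y0 = heart_center[1] - heart_semi[1]
        big = (4.0 * heart_semi[0], row, 4.0 * heart_semi[2])
        rv_slab = Box((heart_center[0], y0 + 0.5 * row, heart_center[2]), big)
        lv_slab = Box((heart_center[0], y0 + 2.5 * row + 7.5, heart_center[2]),
                      (big[0], 2.0 * row, big[2]))
        heart_shapes = (Carved(Carved(heart_ell, rv_slab), lv_slab),)
        blood = tuple(
            replace(b, amplitude=b.amplitude * blood_fraction)
            for b in default_blood_components()
        )
        blood_pool = (CompartmentSpec(
            "blood",
            shapes=(Intersection(heart_ell, rv_slab),
                    Intersection(heart_ell, lv_slab)),
            components=blood,
            motion_amplitude_mm=motion_amplitude_mm,
            label_as="heart",
        ),)
    heart = CompartmentSpec(
        "heart",
        shapes=heart_shapes,
        components=_heart_components(pcr_gamma_ratio),
        motion_amplitude_mm=motion_amplitude_mm,
    )
    chest = CompartmentSpec(
        "chest_wall",
        shapes=(Box((0.0, -82.5, 0.0), (150.0, 45.0, 150.0)),),
        # Amplitudes reflect skeletal-muscle PCr seen by a surface coil:
        # even after 85% saturation the residual chest PCr rivals the
        # myocardial signal, as in vivo.
        components=(
            SpectralComponent("PCr", FREQ_PCR, 16.0, 45.0,
                              t1_s=T1_DEFAULTS["PCr"]),
            SpectralComponent("gATP", FREQ_GAMMA_ATP, 3.0, 55.0,
                              multiplet=DOUBLET, t1_s=T1_DEFAULTS["ATP"]),
            SpectralComponent("aATP", FREQ_ALPHA_ATP, 3.0, 55.0,
                              multiplet=DOUBLET, t1_s=T1_DEFAULTS["ATP"]),
            SpectralComponent("bATP", FREQ_BETA_ATP, 3.0, 60.0,
                              multiplet=TRIPLET, t1_s=T1_DEFAULTS["ATP"]),
        ),
    )
    # Liver: ATP-dominant, no PCr (hepatocytes lack creatine kinase).
    liver = CompartmentSpec(
        "other",
        shapes=(Box((0.0, -15.0, -77.5), (180.0, 90.0, 45.0)),),
        components=(
            SpectralComponent("gATP", FREQ_GAMMA_ATP, 0.25, 60.0,
                              multiplet=DOUBLET, t1_s=T1_DEFAULTS["ATP"]),
            SpectralComponent("aATP", FREQ_ALPHA_ATP, 0.25, 60.0,
                              multiplet=DOUBLET, t1_s=T1_DEFAULTS["ATP"]),
            SpectralComponent("bATP", FREQ_BETA_ATP, 0.25, 65.0,
                              multiplet=TRIPLET, t1_s=T1_DEFAULTS["ATP"]),
        ),
    )
    blood = tuple(default_blood_components()) if blood_fraction > 0 else ()
    # Two overlapping slabs blanket the chest wall and one covers the outer
    # liver.  Suppression is partial and uniform across the chest-wall
    # compartment: residual chest PCr remains the contamination source (as
    # in vivo) without making the compartment internally heterogeneous.
    slabs = (
        (
            SaturationSlab(axis=1, center_mm=-97.5, thickness_mm=25.0,
                           efficiency=0.85),
            SaturationSlab(axis=1, center_mm=-75.0, thickness_mm=25.0,
                           efficiency=0.85),
            SaturationSlab(axis=2, center_mm=-87.5, thickness_mm=25.0,
                           efficiency=0.85),
        )
        if with_saturation_slabs
        else ()
    )
    return PhantomDefinition(
        geometry=geom,
        compartments=(heart, *blood_pool, chest, liver),
        blood_components=blood,
        blood_fraction=blood_fraction,
        saturation_slabs=slabs,
        motion=MotionModel(amplitude_mm=max(motion_amplitude_mm, 0.0)),
    )
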
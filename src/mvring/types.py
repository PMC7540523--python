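"""Core domain types for mitral-valve vortex-ring extraction.

Conventions
-----------
* Velocities are stored in SI units (m/s); lengths and positions are in mm;
  rates derived from velocity gradients (vorticity, Q) are in s^-1 / s^-2.
* Voxel indices are 0-based; the physical position of a voxel center is
  ``origin + index * spacing``; boxes are half-open per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

MaskProvenance = Literal[
    "reference", "subsampled-kd", "static-end-dia", "eroded", "dilated", "synthetic"
]

CoreShape = Literal["torus", "U", "bracket", "none"]


@dataclass(frozen=True)
class Grid:
    """Acquisition geometry: voxel lattice, spacing and cardiac timing.

    Parameters
    ----------
    shape : (nx, ny, nz) voxel counts, each >= 3 (central differences need
        interior voxels).
    spacing : per-axis voxel spacing in mm (anisotropic allowed).
    origin : physical position (mm) of voxel (0, 0, 0).
    frame_duration : time between cardiac frames in ms.
    n_frames : number of cardiac frames N (>= 1).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_duration: float = 33.3
    n_frames: int = 1

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 3 for s in self.shape):
            raise ValueError(f"grid shape must have 3 axes with >= 3 voxels, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def spacing_m(self) -> np.ndarray:
        """Spacing in meters, for SI velocity-gradient computations."""
        return self.spacing_mm * 1e-3

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def positions(self, indices: np.ndarray) -> np.ndarray:
        """Physical voxel-center positions (mm) for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * self.spacing_mm

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open voxel box [lower, upper) per axis."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(u <= l for l, u in zip(self.lower, self.upper)):
            raise ValueError(f"degenerate bounding box {self.lower}..{self.upper}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(u - l for l, u in zip(self.lower, self.upper))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))

    def contains_indices(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(indices)
        lo = np.asarray(self.lower)
        up = np.asarray(self.upper)
        return np.all((idx >= lo) & (idx < up), axis=1)

    def subgrid(self, grid: Grid) -> Grid:
        """Grid restricted to this box (origin shifted to the box corner)."""
        origin = tuple(
            grid.origin[a] + self.lower[a] * grid.spacing[a] for a in range(3)
        )
        return Grid(
            shape=self.shape,
            spacing=grid.spacing,
            origin=origin,
            frame_duration=grid.frame_duration,
            n_frames=grid.n_frames,
        )


@dataclass
class VelocitySeries:
    """Per-frame 3-component velocity volumes in SI m/s.

    ``frames`` has shape (N, nx, ny, nz, 3).
    """

    grid: Grid
    frames: np.ndarray
    units_in: str = "m/s"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        expected = (self.grid.n_frames, *self.grid.shape, 3)
        if self.frames.shape != expected:
            raise ValueError(
                f"velocity frames shape {self.frames.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("velocity series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class MaskSeries:
    """Per-frame binary left-ventricle masks aligned with a velocity grid."""

    grid: Grid
    frames: np.ndarray
    provenance: MaskProvenance = "reference"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames).astype(bool)
        expected = (self.grid.n_frames, *self.grid.shape)
        if self.frames.shape != expected:
            raise ValueError(f"mask frames shape {self.frames.shape} != expected {expected}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def union(self) -> np.ndarray:
        return np.any(self.frames, axis=0)


@dataclass
class HodgeSolution:
    """Vector potential and divergence-free field on a bounding box."""

    psi: np.ndarray  # (nx, ny, nz, 3)
    r: np.ndarray  # (nx, ny, nz, 3), discrete curl of psi
    residual: float  # relative solver residual


@dataclass
class QSeries:
    """Per-frame Q fields with frame thresholds and the vortex-frame window.

    ``vortex_frames`` is an ordered list of frame indices forming a cyclically
    contiguous window of the cardiac cycle; ``peak_frames`` holds the early
    (E) and late (A) diastolic peak frames of the max-Q curve.
    """

    grid: Grid
    q_frames: np.ndarray  # (N, nx, ny, nz), s^-2, smoothed and masked
    thresholds: np.ndarray  # (N,), s^-2
    max_curve: np.ndarray  # (N,)
    max_locations: np.ndarray  # (N, 3) voxel indices
    vortex_frames: list[int] = field(default_factory=list)
    peak_frames: tuple[int, int] = (0, 0)


@dataclass
class VortexCandidate:
    """Connected component of supra-threshold Q, scored by the w1 field."""

    voxels: np.ndarray  # (M, 3) voxel indices
    f_c: float = 0.0
    d_max: float = 0.0
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class VortexCore:
    """Ordered sub-voxel core polyline with shape label and tracking state."""

    points: np.ndarray  # (n, 3) positions in mm
    shape: CoreShape = "none"
    closed: bool = False
    frame: int = -1
    is_mv_ring: bool = False
    major_axis: float = 0.0
    minor_axis: float = 0.0
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 3:
            raise ValueError("core points must be (n, 3)")
        if self.points.size:
            self.centroid = self.points.mean(axis=0)

    @property
    def n_points(self) -> int:
        return 0 if self.points.size == 0 else int(self.points.shape[0])


@dataclass
class VortexRegion:
    """Voxel set of the vortex-ring region in one frame (box-grid indices)."""

    voxels: np.ndarray  # (M, 3) voxel indices
    frame: int

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def as_mask(self, shape: Sequence[int]) -> np.ndarray:
        m = np.zeros(tuple(shape), dtype=bool)
        if self.n_voxels:
            m[tuple(self.voxels.T)] = True
        return m


@dataclass
class VortexParams:
    """Six quantitative vortex-ring parameters for one frame.

    Units follow the reporting convention: volume in mL, vorticity in s^-1,
    kinetic energy in mJ (absolute) and J/m^3 (relative), angle in degrees.
    """

    frame: int
    vol: float = np.nan
    vort_max: float = np.nan
    vort_mean: float = np.nan
    ekin_abs: float = np.nan
    ekin_rel: float = np.nan
    alpha: float = np.nan
    ci: float = np.nan
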
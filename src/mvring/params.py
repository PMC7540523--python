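"""Quantitative mitral-valve vortex-ring parameters.

Per frame with a detected ring the package reports six parameters: ring
volume (mL), maximum (95th-percentile) and mean vorticity magnitude (s^-1)
over the ring region, absolute kinetic energy (mJ) and kinetic energy per
unit volume (J/m^3) assuming a blood density of 1060 kg/m^3, the angle of
the ring plane to the LV long axis (degrees), and the circularity index
(short / long principal axis of the fitted core ellipsoid).

Vorticity and kinetic energy are computed from the full, un-decomposed
velocity field; only the core tracing and the streamline region use the
divergence-free part.
"""

from __future__ import annotations

import numpy as np

from .hodge import discrete_curl
from .tracing import ellipsoid_axes
from .types import Grid, VelocitySeries, VortexCore, VortexParams, VortexRegion

__all__ = [
    "RHO_BLOOD",
    "vorticity_field",
    "vorticity_stats",
    "region_volume",
    "kinetic_energy",
    "angle_to_long_axis",
    "circularity_index",
    "parameter_timecourse",
    "peak_summaries",
]

RHO_BLOOD = 1060.0  # kg/m^3


def vorticity_field(velocity_frame: np.ndarray, grid: Grid) -> np.ndarray:
    """Vorticity (s^-1) of one full velocity frame by central differences."""
    return discrete_curl(velocity_frame, grid.spacing_m)


def vorticity_stats(region: VortexRegion, vorticity: np.ndarray) -> tuple[float, float]:
    """(vort_max, vort_mean) over the region's vorticity magnitudes.

    ``vort_max`` is the 95th percentile (linear interpolation between order
    statistics) to be robust to outliers; ``vort_mean`` the arithmetic mean.
    """
    if region.n_voxels == 0:
        raise ValueError("vorticity statistics undefined for an empty region")
    mags = np.linalg.norm(vorticity[tuple(region.voxels.T)], axis=1)
    return float(np.percentile(mags, 95)), float(np.mean(mags))


def region_volume(region: VortexRegion, grid: Grid) -> float:
    """Ring volume in mL: voxel count x voxel volume."""
    return region.n_voxels * grid.voxel_volume_mm3 / 1000.0


def kinetic_energy(
    region: VortexRegion, velocity_frame: np.ndarray, grid: Grid
) -> tuple[float, float]:
    """(ekin_abs mJ, ekin_rel J/m^3) of the blood inside the ring region."""
    if region.n_voxels == 0:
        raise ValueError("kinetic energy undefined for an empty region")
    v2 = np.sum(velocity_frame[tuple(region.voxels.T)] ** 2, axis=1)  # (m/s)^2
    voxel_m3 = grid.voxel_volume_mm3 * 1e-9
    ekin_j = 0.5 * RHO_BLOOD * float(np.sum(v2)) * voxel_m3
    vol_m3 = region.n_voxels * voxel_m3
    return ekin_j * 1e3, ekin_j / vol_m3


def angle_to_long_axis(core: VortexCore, long_axis: np.ndarray) -> float:
    """Angle (degrees, [0, 90]) between the fitted core plane and the axis.

    The plane is fitted by total least squares (normal = direction of least
    variance); a ring lying in the short-axis plane (normal parallel to the
    long axis) scores 90 degrees.
    """
    pts = np.asarray(core.points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 core points")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("core points are collinear")
    normal = vt[-1]
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cosang = np.clip(abs(normal @ axis), 0.0, 1.0)
    normal_angle = np.degrees(np.arccos(cosang))  # in [0, 90]
    return 90.0 - float(normal_angle)


def circularity_index(core: VortexCore) -> float:
    """Short-to-long principal-axis ratio of the fitted core ellipsoid."""
    major, minor, _ = ellipsoid_axes(core.points)
    return float(np.clip(minor / major, 0.0, 1.0))


def compute_params(
    frame: int,
    core: VortexCore,
    region: VortexRegion,
    velocity_frame: np.ndarray,
    grid: Grid,
    long_axis: np.ndarray,
) -> VortexParams:
    p = VortexParams(frame=frame)
    p.vol = region_volume(region, grid)
    if region.n_voxels:
        vort = vorticity_field(velocity_frame, grid)
        p.vort_max, p.vort_mean = vorticity_stats(region, vort)
        p.ekin_abs, p.ekin_rel = kinetic_energy(region, velocity_frame, grid)
    try:
        p.alpha = angle_to_long_axis(core, long_axis)
    except ValueError:
        pass
    try:
        p.ci = circularity_index(core)
    except ValueError:
        pass
    return p


def parameter_timecourse(
    cores: dict[int, VortexCore],
    regions: dict[int, VortexRegion],
    velocity: VelocitySeries,
    long_axis: np.ndarray,
) -> list[VortexParams]:
    """Parameters for every frame with a mitral-valve ring core and region."""
    out = []
    for frame in sorted(cores):
        core = cores[frame]
        if not core.is_mv_ring or frame not in regions:
            continue
        region = regions[frame]
        if region.n_voxels == 0:
            continue
        out.append(
            compute_params(frame, core, region, velocity.frames[frame], velocity.grid, long_axis)
        )
    return out


def peak_summaries(params: list[VortexParams]) -> dict[str, dict[str, float]]:
    """Per-period peak values: the frames split into contiguous membership
    periods (early diastolic first, late diastolic second); each parameter's
    peak is its maximum over the period's frames."""
    if not params:
        return {}
    frames = [p.frame for p in params]
    periods: list[list[VortexParams]] = [[params[0]]]
    for prev_f, p in zip(frames[:-1], params[1:]):
        if p.frame == prev_f + 1:
            periods[-1].append(p)
        else:
            periods.append([p])
    names = ["vol", "vort_max", "vort_mean", "ekin_abs", "ekin_rel", "alpha", "ci"]
    labels = ["E", "A"] + [f"period{k}" for k in range(3, len(periods) + 1)]
    out = {}
    for label, period in zip(labels, periods):
        summary = {}
        for name in names:
            values = np.array([getattr(p, name) for p in period], dtype=float)
            summary[name] = float(np.nanmax(values)) if np.any(np.isfinite(values)) else np.nan
        summary["frames"] = [p.frame for p in period]
        out[label] = summary
    return out
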
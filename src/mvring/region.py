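"""Vortex-ring region growing by streamlines and outlier-branch pruning.

Streamlines are seeded at the voxels containing mitral-valve ring core
points and their 26-neighborhood, integrated in both directions on the
instantaneous (frame-frozen) divergence-free velocity field, and every voxel
on their path with Q > 0 inside the LV mask becomes part of the ring region.
Thin branches left by outlier streamlines are eroded away by iteratively
removing voxels with fewer than eight occupied 26-neighbors.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .types import Grid, VortexCore, VortexRegion

__all__ = ["seed_points", "grow_region", "prune_region"]

_NEIGH26 = np.ones((3, 3, 3))
_NEIGH26[1, 1, 1] = 0.0


def seed_points(core: VortexCore, grid: Grid, mask: np.ndarray) -> np.ndarray:
    """Voxel-center seed positions (mm): core voxels + 26-neighborhood,
    restricted to the LV mask.  Returns an (n, 3) array (possibly empty)."""
    if core.n_points == 0:
        return np.empty((0, 3))
    idx = np.round((core.points - np.asarray(grid.origin)) / grid.spacing_mm).astype(int)
    offsets = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    all_idx = (idx[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    shape = np.asarray(grid.shape)
    inside = np.all((all_idx >= 0) & (all_idx < shape), axis=1)
    all_idx = all_idx[inside]
    all_idx = np.unique(all_idx, axis=0)
    in_mask = mask[tuple(all_idx.T)]
    return grid.positions(all_idx[in_mask])


def _integrate_batch(
    starts: np.ndarray,
    velocity_interp,
    q_interp,
    grid: Grid,
    sign: float,
    step_mm: float,
    max_len: int,
    mark: np.ndarray,
    mask: np.ndarray,
) -> None:
    """Batched RK4 integration of unit-speed streamlines; marks every voxel
    whose cell is entered while interpolated Q stays positive."""
    shape = np.asarray(grid.shape)
    origin = np.asarray(grid.origin)
    spacing = grid.spacing_mm

    def direction(p: np.ndarray) -> np.ndarray:
        v = velocity_interp(p)
        nrm = np.linalg.norm(v, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(nrm > 1e-12, v / nrm, 0.0)
        return sign * d

    pos = starts.copy()
    active = np.ones(pos.shape[0], dtype=bool)
    for _ in range(max_len):
        if not np.any(active):
            break
        p = pos[active]
        k1 = direction(p)
        k2 = direction(p + 0.5 * step_mm * k1)
        k3 = direction(p + 0.5 * step_mm * k2)
        k4 = direction(p + step_mm * k3)
        new = p + (step_mm / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        moved = np.linalg.norm(new - p, axis=1) > 1e-9
        qv = np.asarray(q_interp(new)).ravel()
        idx = np.round((new - origin) / spacing).astype(int)
        in_grid = np.all((idx >= 0) & (idx < shape), axis=1)
        ok = moved & in_grid & (qv > 0)
        idx_ok = idx[ok]
        if idx_ok.size:
            in_mask = mask[tuple(idx_ok.T)]
            ok_idx = idx_ok[in_mask]
            if ok_idx.size:
                mark[tuple(ok_idx.T)] = True
            # leaving the mask terminates the streamline
            ok_pos = np.flatnonzero(ok)
            ok[ok_pos[~in_mask]] = False
        sub = np.flatnonzero(active)
        pos[sub[ok]] = new[ok]
        active[sub[~ok]] = False


def grow_region(
    seeds: np.ndarray,
    r_field: np.ndarray,
    q_frame: np.ndarray,
    mask: np.ndarray,
    grid: Grid,
    frame: int = -1,
    max_len: int = 1000,
) -> VortexRegion:
    """Grow the ring region from seed positions on the divergence-free field.

    Each seed is integrated in both directions with 4th-order Runge-Kutta on
    the trilinearly interpolated, unit-normalized field (step 0.5 x minimum
    spacing); integration stops on interpolated Q <= 0, mask exit, or the
    step budget.  The region is the set of traversed voxels that lie in the
    mask and have Q > 0 at their center.
    """
    mark = np.zeros(grid.shape, dtype=bool)
    seeds = np.atleast_2d(seeds)
    if seeds.size == 0:
        return VortexRegion(voxels=np.empty((0, 3), dtype=int), frame=frame)
    axes = grid.axes_mm()
    vinterp = RegularGridInterpolator(
        axes, r_field, method="linear", bounds_error=False, fill_value=0.0
    )
    qinterp = RegularGridInterpolator(
        axes, q_frame, method="linear", bounds_error=False, fill_value=0.0
    )
    # seeds themselves count when valid
    sidx = np.round((seeds - np.asarray(grid.origin)) / grid.spacing_mm).astype(int)
    shape = np.asarray(grid.shape)
    ok = np.all((sidx >= 0) & (sidx < shape), axis=1)
    qs = np.asarray(qinterp(seeds)).ravel() > 0
    valid = ok & qs
    keep = sidx[valid]
    if keep.size:
        in_mask = mask[tuple(keep.T)]
        keep = keep[in_mask]
        if keep.size:
            mark[tuple(keep.T)] = True
    starts = seeds[valid]
    step_mm = 0.5 * float(min(grid.spacing))
    for sign in (+1.0, -1.0):
        _integrate_batch(starts, vinterp, qinterp, grid, sign, step_mm, max_len, mark, mask)
    mark &= mask
    mark &= q_frame > 0
    return VortexRegion(voxels=np.argwhere(mark), frame=frame)


def prune_region(voxels: np.ndarray, shape=None) -> np.ndarray:
    """Remove outlier-streamline branches: iteratively delete voxels with
    fewer than eight occupied 26-neighbors (simultaneous sweeps, order
    independent) until a fixpoint is reached.  May return an empty set."""
    vox = np.asarray(voxels, dtype=int)
    if vox.size == 0:
        return vox.reshape(0, 3)
    if shape is None:
        shape = tuple(vox.max(axis=0) + 2)
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(vox.T)] = True
    while True:
        counts = ndimage.convolve(vol.astype(np.uint8), _NEIGH26, mode="constant")
        new = vol & (counts >= 8)
        if np.array_equal(new, vol):
            break
        vol = new
    return np.argwhere(vol)
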
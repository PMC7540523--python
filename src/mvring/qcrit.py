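"""Q-criterion vortex identification and candidate selection.

The Q field is computed from the divergence-free velocity: with the velocity
gradient split into strain-rate S (symmetric) and spin Omega (antisymmetric)
parts, ``Q = 1/2 (||Omega||_F^2 - ||S||_F^2)``, and voxels with Q > 0 belong
to a vortex.  The Q series is smoothed in space (Gaussian then median) and in
time (cyclic Gaussian over the cardiac cycle), masked to the left ventricle,
thresholded with frame-specific thresholds derived from the per-frame Q
maxima, and reduced to at most two mitral-valve vortex-ring candidates per
frame using the first principal component of the thresholded Q series.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import Grid, MaskSeries, QSeries, VortexCandidate

__all__ = [
    "velocity_gradient_tensor",
    "q_field",
    "smooth_q_series",
    "apply_masks",
    "frame_thresholds",
    "vortex_frame_window",
    "threshold_regions",
    "first_principal_component",
    "candidate_factor",
    "select_candidates",
    "PCFields",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def velocity_gradient_tensor(field: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel velocity-gradient tensor, entry [..., i, j] = dv_i/dx_j.

    Second-order central differences in the interior, one-sided at faces.
    Pass spacing in meters for SI velocities to obtain s^-1.
    """
    rows = []
    for i in range(3):
        rows.append(np.stack(np.gradient(field[..., i], *spacing, edge_order=2), axis=-1))
    return np.stack(rows, axis=-2)


def q_field(field: np.ndarray, spacing) -> np.ndarray:
    """Q-criterion scalar volume (s^-2) of one vector volume."""
    g = velocity_gradient_tensor(field, spacing)
    s_t = 0.5 * (g + np.swapaxes(g, -1, -2))
    o_t = 0.5 * (g - np.swapaxes(g, -1, -2))
    return 0.5 * (np.sum(o_t**2, axis=(-2, -1)) - np.sum(s_t**2, axis=(-2, -1)))


def smooth_q_series(
    q_frames: np.ndarray,
    spatial_sigma: float = 1.0,
    median_size: int = 3,
    temporal_sigma: float = 1.0,
) -> np.ndarray:
    """Spatial Gaussian + median filtering, then cyclic temporal smoothing.

    The filter order is fixed: per-frame Gaussian blur (sigma in voxels per
    axis), per-frame median filter (cubic window), then a per-voxel Gaussian
    along the frame axis with cyclic boundary (the cardiac cycle is
    periodic).  This removes noise and vortex structures with a short
    lifetime before thresholding.
    """
    out = np.empty_like(q_frames)
    for f in range(q_frames.shape[0]):
        frame = q_frames[f]
        if spatial_sigma > 0:
            frame = ndimage.gaussian_filter(frame, sigma=spatial_sigma, mode="nearest")
        if median_size > 1:
            frame = ndimage.median_filter(frame, size=median_size, mode="nearest")
        out[f] = frame
    if temporal_sigma > 0 and q_frames.shape[0] > 1:
        out = ndimage.gaussian_filter1d(out, sigma=temporal_sigma, axis=0, mode="wrap")
    return out


def apply_masks(q_frames: np.ndarray, masks: MaskSeries) -> np.ndarray:
    """Zero Q outside the per-frame LV masks (excludes those voxels from
    maxima, thresholds and candidate regions)."""
    if q_frames.shape != masks.frames.shape:
        raise ValueError("Q frames and mask frames have different shapes")
    return np.where(masks.frames, q_frames, 0.0)


def frame_thresholds(
    q_frames: np.ndarray, masks: MaskSeries
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-specific Q thresholds from the per-frame maxima locations.

    For each frame n the argmax location of the masked Q field is recorded;
    the threshold of frame i is the mean over all N frames n of Q_i evaluated
    at those locations.  Returns (thresholds, max_curve, max_locations).
    For an all-zero frame the argmax is defined as the first mask voxel.
    """
    n = q_frames.shape[0]
    locations = np.zeros((n, 3), dtype=int)
    max_curve = np.zeros(n)
    for f in range(n):
        qf = q_frames[f]
        if np.any(qf != 0):
            loc = np.unravel_index(int(np.argmax(qf)), qf.shape)
        else:
            mask_idx = np.argwhere(masks.frames[f])
            if mask_idx.size == 0:
                mask_idx = np.array([[0, 0, 0]])
            loc = tuple(mask_idx[0])
        locations[f] = loc
        max_curve[f] = qf[loc]
    sampled = q_frames[:, locations[:, 0], locations[:, 1], locations[:, 2]]  # (i, n)
    thresholds = np.maximum(sampled.mean(axis=1), 0.0)
    return thresholds, max_curve, locations


def _local_maxima_cyclic(curve: np.ndarray) -> list[int]:
    n = len(curve)
    out = []
    for i in range(n):
        if curve[i] > curve[(i - 1) % n] and curve[i] >= curve[(i + 1) % n]:
            out.append(i)
    return out


def _cyclic_dist(i: int, j: int, n: int) -> int:
    d = abs(i - j) % n
    return min(d, n - d)


def vortex_frame_window(
    max_curve: np.ndarray,
    thresholds: np.ndarray,
    window_factor: float = 0.5,
    min_peak_separation: int = 3,
) -> tuple[list[int], tuple[int, int]]:
    """Diastolic-to-early-systolic vortex frames and the E/A peak frames.

    The two largest local maxima of the max-Q curve separated by at least
    ``min_peak_separation`` frames are taken as the early (E) and late (A)
    diastolic peaks.  The window is the cyclic arc connecting the peaks that
    avoids the global minimum of the curve (the quiet systolic phase),
    extended outward at both ends while ``max_curve >= window_factor *
    mean(thresholds)``.  Frames between the peaks (diastasis) are kept even
    when the curve dips there, matching the physiological E-diastasis-A
    course of transmitral inflow.
    """
    n = len(max_curve)
    if n < 3:
        raise ValueError("need at least 3 frames to identify vortex frames")
    floor = window_factor * float(np.mean(thresholds))
    peaks = _local_maxima_cyclic(max_curve)
    if not peaks:  # constant curve
        if np.all(max_curve >= floor) and np.any(max_curve > 0):
            g = int(np.argmax(max_curve))
            return list(range(n)), (g, g)
        raise ValueError("no vortex activity detected")
    peaks.sort(key=lambda i: max_curve[i], reverse=True)
    p1 = peaks[0]
    p2 = None
    for cand in peaks[1:]:
        if _cyclic_dist(p1, cand, n) >= min_peak_separation:
            p2 = cand
            break
    if p2 is None:
        p2 = p1

    if p1 == p2:
        window = [p1]
    else:
        # two cyclic arcs from p1 to p2; keep the one avoiding the global minimum
        arc_a = [(p1 + k) % n for k in range((p2 - p1) % n + 1)]
        arc_b = [(p2 + k) % n for k in range((p1 - p2) % n + 1)]
        gmin = int(np.argmin(max_curve))
        if gmin in arc_a and gmin not in arc_b:
            window = arc_b
        elif gmin in arc_b and gmin not in arc_a:
            window = arc_a
        else:  # minimum at a peak endpoint: take the shorter arc
            window = arc_a if len(arc_a) <= len(arc_b) else arc_b

    # extend both ends while the curve stays above the activity floor
    start, end = window[0], window[-1]
    while len(window) < n:
        prev = (start - 1) % n
        if prev == end or max_curve[prev] < floor:
            break
        start = prev
        window.insert(0, start)
    while len(window) < n:
        nxt = (end + 1) % n
        if nxt == start or max_curve[nxt] < floor:
            break
        end = nxt
        window.append(end)

    if len(window) < 2:
        raise ValueError("no vortex activity detected")
    # E peak = the earlier peak along the window's time order
    if p1 == p2:
        peak_frames = (p1, p1)
    else:
        peak_frames = (p1, p2) if window.index(p1) < window.index(p2) else (p2, p1)
    return window, peak_frames


def threshold_regions(
    q_frame: np.ndarray, thr: float, min_voxels: int = 5
) -> list[VortexCandidate]:
    """26-connected components of {Q > thr}; components below ``min_voxels``
    are discarded as sub-smoothing-scale debris."""
    labels, nlab = ndimage.label(q_frame > thr, structure=_CONN26)
    out = []
    for lab in range(1, nlab + 1):
        vox = np.argwhere(labels == lab)
        if vox.shape[0] >= min_voxels:
            out.append(VortexCandidate(voxels=vox))
    return out


class PCFields:
    """First principal-component map of the thresholded Q series.

    ``w1`` is the first left singular vector of the voxel x vortex-frame
    matrix of thresholded Q values (per-voxel temporal mean removed),
    reshaped to the volume and sign-fixed to be non-negative at the global
    Q maximum location.
    """

    def __init__(self, w1: np.ndarray, explained_variance_ratio: float,
                 w1_max_location: np.ndarray):
        self.w1 = w1
        self.explained_variance_ratio = float(explained_variance_ratio)
        self.w1_max_location = np.asarray(w1_max_location, dtype=float)


def first_principal_component(
    q_frames: np.ndarray,
    thresholds: np.ndarray,
    vortex_frames: list[int],
    grid: Grid,
) -> PCFields:
    """PCA of the thresholded Q fields over the vortex frames.

    Represents the 4D thresholded-Q information as one scalar 3D field per
    principal component; only the first component is retained.
    """
    if len(vortex_frames) < 2:
        raise ValueError("PCA needs at least 2 vortex frames")
    shape = q_frames.shape[1:]
    cols = []
    for f in vortex_frames:
        qf = q_frames[f]
        cols.append(np.where(qf > thresholds[f], qf, 0.0).ravel())
    x = np.column_stack(cols)  # (voxels, frames)
    if not np.any(x):
        raise ValueError("thresholded Q series is identically zero")
    x = x - x.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    w1 = u[:, 0]
    evr = float(s[0] ** 2 / np.sum(s**2)) if np.any(s) else 0.0
    # sign convention: w1 >= 0 at the location of the global masked-Q maximum
    sub = q_frames[vortex_frames]
    gmax_flat = int(np.argmax(sub.max(axis=0)))
    if w1[gmax_flat] < 0:
        w1 = -w1
    w1 = w1.reshape(shape)
    loc = np.unravel_index(int(np.argmax(w1)), shape)
    return PCFields(
        w1=w1,
        explained_variance_ratio=evr,
        w1_max_location=grid.positions(np.array(loc))[0],
    )


def candidate_factor(
    candidate: VortexCandidate,
    pc: PCFields,
    long_axis: np.ndarray,
    grid: Grid,
    d_floor: float = 1.0,
) -> VortexCandidate:
    """Candidate factor f_c = sum of w1 over the region / d_max.

    ``d_max`` is the largest distance (mm) from a region voxel to the w1
    maximum location, measured along the LV long axis; ``d_floor`` guards
    the division when the region sits at the w1 maximum.
    """
    if candidate.n_voxels == 0:
        raise ValueError("empty candidate region")
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pos = grid.positions(candidate.voxels)
    d_max = float(np.max(np.abs((pos - pc.w1_max_location) @ axis)))
    w1_sum = float(np.sum(pc.w1[tuple(candidate.voxels.T)]))
    candidate.d_max = d_max
    candidate.f_c = w1_sum / max(d_max, d_floor)
    candidate.centroid = pos.mean(axis=0)
    return candidate


def select_candidates(candidates: list[VortexCandidate]) -> list[VortexCandidate]:
    """Keep the (at most two) highest-f_c regions whose d_max is below twice
    the minimum d_max of all regions."""
    if not candidates:
        return []
    d_min = min(c.d_max for c in candidates)
    eligible = [c for c in candidates if c.d_max < 2.0 * d_min]
    eligible.sort(key=lambda c: c.f_c, reverse=True)
    return eligible[:2]
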
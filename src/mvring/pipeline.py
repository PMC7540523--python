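"""End-to-end mitral-valve vortex-ring extraction.

Four steps on a bounding box around the segmented left ventricle:

1. divergence-free part of the velocity by the vector-potential solve;
2. Q fields, smoothing, masking, frame thresholds, vortex-frame window and
   candidate selection via the first principal component of thresholded Q;
3. predictor-corrector core tracing with temporal tracking of ring
   membership;
4. streamline region growing from the core with branch pruning;

followed by the six quantitative ring parameters per detected frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hodge, qcrit, region as region_mod, tracing
from .io import RunConfig, bounding_box
from .params import compute_params
from .types import (
    BoundingBox,
    Grid,
    MaskSeries,
    QSeries,
    VelocitySeries,
    VortexCore,
    VortexParams,
    VortexRegion,
)

__all__ = ["ExtractionResult", "extract", "estimate_long_axis"]


@dataclass
class ExtractionResult:
    """Everything the extraction pipeline produced for one dataset."""

    box: BoundingBox
    box_grid: Grid
    q_series: QSeries
    cores: dict[int, VortexCore]
    regions: dict[int, VortexRegion]  # box-grid voxel indices
    params: list[VortexParams]
    long_axis: np.ndarray
    divfree: VelocitySeries | None = None
    regions_full: dict[int, VortexRegion] = field(default_factory=dict)

    def presence(self, n_frames: int) -> np.ndarray:
        out = np.zeros(n_frames, dtype=bool)
        for f, c in self.cores.items():
            if c.is_mv_ring:
                out[f] = True
        return out


def estimate_long_axis(masks: MaskSeries, frame: int = 0) -> np.ndarray:
    """LV long axis as the first principal axis of the end-diastolic mask
    voxel positions, oriented from base (wider cross-section) to apex."""
    vox = np.argwhere(masks.frames[frame])
    if vox.shape[0] < 3:
        raise ValueError("mask too small to estimate a long axis")
    pos = masks.grid.positions(vox)
    centered = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    # compare cross-section extents near the two ends; base is wider
    near_pos = centered[proj > 0.6 * proj.max()]
    near_neg = centered[proj < 0.6 * proj.min()]
    def width(sub):
        if sub.shape[0] < 3:
            return 0.0
        r = sub - np.outer(sub @ axis, axis)
        return float(np.mean(np.linalg.norm(r, axis=1)))
    if width(near_pos) >= width(near_neg):
        axis = -axis  # point from base toward apex
    return axis


def extract(
    velocity: VelocitySeries,
    masks: MaskSeries,
    config: RunConfig | None = None,
) -> ExtractionResult:
    """Run the full extraction pipeline.  Deterministic given its inputs."""
    config = config or RunConfig()
    grid = velocity.grid
    n = velocity.n_frames

    box = bounding_box(masks, margin=config.bbox_margin)
    box_grid = box.subgrid(grid)
    sl = box.slices
    box_masks = MaskSeries(
        grid=box_grid, frames=masks.frames[(slice(None), *sl)], provenance=masks.provenance
    )

    if config.long_axis is not None:
        long_axis = np.asarray(config.long_axis, dtype=float)
        long_axis = long_axis / np.linalg.norm(long_axis)
    else:
        long_axis = estimate_long_axis(masks)

    # Step 1: divergence-free field on the box
    divfree, _ = hodge.divergence_free_part(
        velocity, box, tol=config.hodge_tol, max_iter=config.hodge_max_iter
    )

    # Step 2: Q analysis and candidate selection
    q_raw = np.stack(
        [qcrit.q_field(divfree.frames[f], box_grid.spacing_m) for f in range(n)], axis=0
    )
    q_raw_masked = qcrit.apply_masks(q_raw, box_masks)
    q_smooth = qcrit.smooth_q_series(
        q_raw,
        spatial_sigma=config.spatial_sigma,
        median_size=config.median_size,
        temporal_sigma=config.temporal_sigma,
    )
    q_masked = qcrit.apply_masks(q_smooth, box_masks)
    thresholds, max_curve, max_locations = qcrit.frame_thresholds(q_masked, box_masks)
    vortex_frames, peak_frames = qcrit.vortex_frame_window(
        max_curve, thresholds, window_factor=config.window_factor
    )
    q_series = QSeries(
        grid=box_grid,
        q_frames=q_masked,
        thresholds=thresholds,
        max_curve=max_curve,
        max_locations=max_locations,
        vortex_frames=vortex_frames,
        peak_frames=peak_frames,
    )
    pc = qcrit.first_principal_component(q_masked, thresholds, vortex_frames, box_grid)
    candidates = {}
    for f in vortex_frames:
        regions = qcrit.threshold_regions(
            q_masked[f], thresholds[f], min_voxels=config.min_voxels
        )
        for r in regions:
            qcrit.candidate_factor(r, pc, long_axis, box_grid, d_floor=config.d_floor)
        candidates[f] = qcrit.select_candidates(regions)

    # Step 3: core tracing and temporal tracking
    vorticity = np.stack(
        [hodge.discrete_curl(divfree.frames[f], box_grid.spacing_m) for f in range(n)],
        axis=0,
    )
    trace_cfg = tracing.TraceConfig.for_grid(box_grid, **config.trace)
    cores = tracing.track_cores(candidates, q_series, vorticity, trace_cfg, box_grid)

    # Step 4: streamline region growing with pruning
    regions: dict[int, VortexRegion] = {}
    for f, core in cores.items():
        if not core.is_mv_ring:
            continue
        seeds = region_mod.seed_points(core, box_grid, box_masks.frames[f])
        # the region reflects the instantaneous vortex: streamlines terminate
        # on the unsmoothed Q of the divergence-free field (the smoothed Q is
        # only used for thresholds, candidates and tracing stability)
        reg = region_mod.grow_region(
            seeds, divfree.frames[f], q_raw_masked[f], box_masks.frames[f], box_grid, frame=f
        )
        pruned = region_mod.prune_region(reg.voxels, shape=box_grid.shape)
        regions[f] = VortexRegion(voxels=pruned, frame=f)

    # parameters from the full (un-decomposed) velocity restricted to the box
    params: list[VortexParams] = []
    for f in sorted(regions):
        core = cores[f]
        reg = regions[f]
        if reg.n_voxels == 0:
            continue
        params.append(
            compute_params(f, core, reg, velocity.frames[f][sl], box_grid, long_axis)
        )

    lower = np.asarray(box.lower)
    regions_full = {
        f: VortexRegion(voxels=r.voxels + lower, frame=f) for f, r in regions.items()
    }
    return ExtractionResult(
        box=box,
        box_grid=box_grid,
        q_series=q_series,
        cores=cores,
        regions=regions,
        params=params,
        long_axis=long_axis,
        divfree=divfree,
        regions_full=regions_full,
    )
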
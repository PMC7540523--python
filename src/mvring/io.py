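"""Volume, geometry and tabular I/O plus run configuration.

Velocity input is NIfTI: either three scalar volumes per frame (suffixes
``_vx``/``_vy``/``_vz``) or one 5D volume (x, y, z, frame, component).
Masks are per-frame NIfTI volumes binarized at 0.5.  Results are exported
as per-frame region masks (NIfTI), core polylines (JSON), and one parameter
CSV row per frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import BoundingBox, Grid, MaskSeries, VelocitySeries, VortexCore, VortexParams, VortexRegion

__all__ = [
    "RunConfig",
    "load_velocity_series",
    "load_mask_series",
    "bounding_box",
    "export_results",
    "load_regions",
    "PARAM_COLUMNS",
]

PARAM_COLUMNS = [
    "frame",
    "present",
    "vol_mL",
    "vort_max_s1",
    "vort_mean_s1",
    "ekin_abs_mJ",
    "ekin_rel_Jm3",
    "alpha_deg",
    "ci",
]


@dataclass
class RunConfig:
    """Run configuration (YAML-loadable).

    spacing in mm, frame_duration in ms, velocity units "m/s" or "cm/s",
    optional LV long-axis direction, solver/filter/tracer tunables and the
    random seed used by any stochastic component.
    """

    spacing: tuple[float, float, float] = (1.8, 2.5, 4.0)
    frame_duration: float = 33.3
    velocity_units: str = "m/s"
    long_axis: tuple[float, float, float] | None = None
    bbox_margin: int = 2
    hodge_tol: float = 1e-6
    hodge_max_iter: int | None = None
    spatial_sigma: float = 1.0
    median_size: int = 3
    temporal_sigma: float = 1.0
    window_factor: float = 0.5
    d_floor: float = 1.0
    min_voxels: int = 5
    trace: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.spacing = tuple(float(s) for s in cfg.spacing)
        if cfg.long_axis is not None:
            cfg.long_axis = tuple(float(s) for s in cfg.long_axis)
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["spacing"] = list(self.spacing)
        if self.long_axis is not None:
            data["long_axis"] = list(self.long_axis)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def _read_volume(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64)


def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag([*grid.spacing, 1.0])
    aff[:3, 3] = grid.origin
    return aff


def load_velocity_series(velocity_paths: Sequence, config: RunConfig) -> VelocitySeries:
    """Load per-frame velocity volumes and convert to SI m/s.

    ``velocity_paths`` is either a list of per-frame path triplets
    ``(vx, vy, vz)`` / component-suffixed file names, or a single path to a
    5D volume of shape (nx, ny, nz, N, 3).
    """
    paths = list(velocity_paths)
    frames = []
    if len(paths) == 1 and not isinstance(paths[0], (tuple, list)):
        data = _read_volume(paths[0])
        if data.ndim != 5 or data.shape[-1] != 3:
            raise ValueError(f"expected 5D (x,y,z,frame,component) volume, got {data.shape}")
        frames = [data[..., f, :] for f in range(data.shape[3])]
    else:
        for f, entry in enumerate(paths):
            if isinstance(entry, (tuple, list)):
                comps = [_read_volume(p) for p in entry]
            else:
                base = str(entry)
                comps = [_read_volume(base.replace("_vx", f"_v{ax}")) for ax in "xyz"]
            if any(c.shape != comps[0].shape for c in comps):
                raise ValueError(f"component shapes disagree in frame {f}")
            frames.append(np.stack(comps, axis=-1))
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        for f, fr in enumerate(frames):
            if fr.shape != frames[0].shape:
                raise ValueError(
                    f"frame {f} has shape {fr.shape[:3]}, expected {frames[0].shape[:3]}"
                )
    arr = np.stack(frames, axis=0)
    if not np.all(np.isfinite(arr)):
        raise ValueError("velocity input contains non-finite voxels")
    units = config.velocity_units.lower()
    if units == "cm/s":
        arr = arr / 100.0
    elif units != "m/s":
        raise ValueError(f"unsupported velocity unit {config.velocity_units!r}")
    grid = Grid(
        shape=arr.shape[1:4],
        spacing=config.spacing,
        frame_duration=config.frame_duration,
        n_frames=arr.shape[0],
    )
    return VelocitySeries(grid=grid, frames=arr, units_in=config.velocity_units)


def load_mask_series(mask_paths: Sequence, grid: Grid) -> MaskSeries:
    """Load per-frame masks, binarize at 0.5 and validate against the grid."""
    import warnings

    frames = []
    for f, path in enumerate(mask_paths):
        data = _read_volume(path)
        if data.shape != grid.shape:
            raise ValueError(f"mask frame {f} shape {data.shape} != grid shape {grid.shape}")
        frames.append(data > 0.5)
    arr = np.stack(frames, axis=0)
    if not np.any(arr):
        raise ValueError("all mask frames are empty")
    for f in range(arr.shape[0]):
        if not np.any(arr[f]):
            warnings.warn(f"mask frame {f} is empty")
    return MaskSeries(grid=grid, frames=arr, provenance="reference")


def bounding_box(masks: MaskSeries, margin: int = 2) -> BoundingBox:
    """Smallest axis-aligned box containing the union of all mask frames,
    expanded by ``margin`` voxels per axis and clipped to the grid."""
    union = masks.union()
    if not np.any(union):
        raise ValueError("cannot compute bounding box of all-empty masks")
    idx = np.argwhere(union)
    lower = np.maximum(idx.min(axis=0) - margin, 0)
    upper = np.minimum(idx.max(axis=0) + 1 + margin, masks.grid.shape)
    return BoundingBox(lower=tuple(int(v) for v in lower), upper=tuple(int(v) for v in upper))


def _params_frame(params: list[VortexParams], frames_present: set[int], n_frames: int) -> pd.DataFrame:
    by_frame = {p.frame: p for p in params}
    rows = []
    for f in range(n_frames):
        p = by_frame.get(f)
        rows.append(
            {
                "frame": f,
                "present": int(f in frames_present),
                "vol_mL": p.vol if p else np.nan,
                "vort_max_s1": p.vort_max if p else np.nan,
                "vort_mean_s1": p.vort_mean if p else np.nan,
                "ekin_abs_mJ": p.ekin_abs if p else np.nan,
                "ekin_rel_Jm3": p.ekin_rel if p else np.nan,
                "alpha_deg": p.alpha if p else np.nan,
                "ci": p.ci if p else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=PARAM_COLUMNS)


def export_results(
    cores: dict[int, VortexCore],
    regions: dict[int, VortexRegion],
    params: list[VortexParams],
    out_dir,
    grid: Grid,
    n_frames: int | None = None,
) -> dict[str, Path]:
    """Write region masks (per-frame NIfTI), core polylines (JSON) and the
    parameter CSV.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = n_frames if n_frames is not None else grid.n_frames
    written: dict[str, Path] = {}
    aff = _affine(grid)
    for frame, region in regions.items():
        vol = np.zeros(grid.shape, dtype=np.uint8)
        if region.n_voxels:
            vol[tuple(region.voxels.T)] = 1
        p = out / f"region_frame{frame:03d}.nii.gz"
        nib.save(nib.Nifti1Image(vol, aff), str(p))
        written[f"region_{frame}"] = p
    core_records = []
    for frame in sorted(cores):
        c = cores[frame]
        core_records.append(
            {
                "frame": frame,
                "shape": c.shape,
                "closed": bool(c.closed),
                "is_mv_ring": bool(c.is_mv_ring),
                "major_axis_mm": float(c.major_axis),
                "minor_axis_mm": float(c.minor_axis),
                "points_mm": np.asarray(c.points).tolist(),
            }
        )
    cores_path = out / "cores.json"
    cores_path.write_text(json.dumps(core_records, indent=1))
    written["cores"] = cores_path
    present = {f for f, c in cores.items() if c.is_mv_ring}
    csv_path = out / "params.csv"
    _params_frame(params, present, n).to_csv(csv_path, index=False)
    written["params"] = csv_path
    return written


def load_regions(out_dir, grid: Grid) -> dict[int, VortexRegion]:
    """Reload exported region masks (round-trip of :func:`export_results`)."""
    out = Path(out_dir)
    regions = {}
    for p in sorted(out.glob("region_frame*.nii.gz")):
        frame = int(p.stem.split("frame")[1].split(".")[0])
        vol = _read_volume(p) > 0.5
        regions[frame] = VortexRegion(voxels=np.argwhere(vol), frame=frame)
    return regions
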
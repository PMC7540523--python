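"""Vortex core-line tracing, shape classification and temporal tracking.

The core line is grown from the maximum-Q point of a vortex candidate by a
predictor-corrector scheme: the predictor elongates the line along the local
(trilinearly interpolated) vorticity direction; the corrector moves the
predictor point to the maximum of interpolated Q on the plane perpendicular
to the vorticity at the predictor, found by a contracting pattern search.
Tracing stops when the line closes on its start point (torus), gets stuck,
leaves the Q > 0 region, or exceeds the step budget; an open forward line is
complemented by a backward trace which may close the ring by fusing with the
forward line.  Open results are classified as U- or bracket-shaped by their
in-plane turning angle.

Temporal tracking seeds the mitral-valve ring at the two peak frames of the
max-Q curve and propagates membership frame by frame, requiring a small
centroid displacement and a small relative change of the fitted major axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .types import Grid, QSeries, VortexCandidate, VortexCore

__all__ = [
    "TraceConfig",
    "trace_core",
    "classify_shape",
    "turning_angle",
    "ellipsoid_axes",
    "track_cores",
]


@dataclass
class TraceConfig:
    """Tunables of the predictor-corrector tracer and the temporal tracker.

    All lengths in mm.  Defaults are expressed relative to the voxel spacing
    through :meth:`for_grid`.
    """

    step: float = 1.0
    pattern_mesh0: float = 2.0
    pattern_mesh_min: float = 0.2
    pattern_radius: float = 8.0
    close_tol: float = 1.0
    stuck_tol: float = 0.1
    max_steps: int = 500
    min_loop_steps: int = 6
    u_turn_deg: float = 150.0
    bracket_gap: float = 8.0
    track_dist: float = 10.0
    track_axis_change: float = 0.5

    def __post_init__(self) -> None:
        if self.max_steps < self.min_loop_steps or self.min_loop_steps < 3:
            raise ValueError("require max_steps >= min_loop_steps >= 3")
        for name in ("step", "pattern_mesh0", "pattern_mesh_min", "pattern_radius",
                     "close_tol", "stuck_tol", "bracket_gap", "track_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_grid(cls, grid: Grid, **overrides) -> "TraceConfig":
        h_min = float(min(grid.spacing))
        h_max = float(max(grid.spacing))
        defaults = dict(
            step=0.5 * h_min,
            pattern_mesh0=1.0 * h_min,
            pattern_mesh_min=0.1 * h_min,
            pattern_radius=2.0 * h_max,
            close_tol=0.5 * h_min,
            stuck_tol=0.05 * h_min,
            bracket_gap=2.0 * h_max,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _interpolator(volume: np.ndarray, grid: Grid, fill: float = 0.0):
    axes = grid.axes_mm()
    return RegularGridInterpolator(
        axes, volume, method="linear", bounds_error=False, fill_value=fill
    )


class _Fields:
    """Trilinear interpolators for Q and vorticity on one frame."""

    def __init__(self, q_frame: np.ndarray, vorticity_frame: np.ndarray, grid: Grid):
        self.q = _interpolator(q_frame, grid)
        self.w = _interpolator(vorticity_frame, grid)

    def q_at(self, p: np.ndarray) -> float:
        return float(np.asarray(self.q(p)).ravel()[0])

    def unit_vorticity(self, p: np.ndarray) -> np.ndarray | None:
        w = np.asarray(self.w(p), dtype=float).reshape(3)
        nrm = np.linalg.norm(w)
        if nrm < 1e-12:
            return None
        return w / nrm


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ normal) * normal
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(normal, e1)


def _pattern_search(fields: _Fields, predictor: np.ndarray, normal: np.ndarray,
                    cfg: TraceConfig) -> tuple[np.ndarray, float]:
    """Maximize interpolated Q on the plane through ``predictor`` with the
    given normal, by compass search with mesh contraction (factor 0.5)."""
    e1, e2 = _plane_basis(normal)
    best = predictor.copy()
    best_q = fields.q_at(predictor)
    mesh = cfg.pattern_mesh0
    while mesh >= cfg.pattern_mesh_min:
        moved = False
        for d in (e1, -e1, e2, -e2):
            cand = best + mesh * d
            if np.linalg.norm(cand - predictor) > cfg.pattern_radius:
                continue
            q = fields.q_at(cand)
            if q > best_q:
                best, best_q = cand, q
                moved = True
        if not moved:
            mesh *= 0.5
    return best, best_q


def _trace_one_direction(
    fields: _Fields, seed: np.ndarray, sign: float, cfg: TraceConfig,
    fuse_with: np.ndarray | None = None,
) -> tuple[list[np.ndarray], str]:
    """Grow one core line from the seed.  Returns (points, stop_reason) with
    stop_reason in {closed, fused, stuck, q_nonpos, max_steps}."""
    points: list[np.ndarray] = [seed.copy()]
    w0 = fields.unit_vorticity(seed)
    if w0 is None:
        return points, "stuck"
    prev_dir = sign * w0
    current = seed.copy()
    for _ in range(cfg.max_steps):
        w = fields.unit_vorticity(current)
        if w is None:
            return points, "stuck"
        if w @ prev_dir < 0:  # keep a consistent orientation along the line
            w = -w
        predictor = current + cfg.step * w
        corrector, q_corr = _pattern_search(fields, predictor, w, cfg)
        if q_corr <= 0.0:
            return points, "q_nonpos"
        if len(points) >= cfg.min_loop_steps:
            # arriving back at the start point, or revisiting an earlier part
            # of the line, closes the ring; the pre-loop tail is trimmed
            revisit = np.linalg.norm(
                np.asarray(points[: len(points) - cfg.min_loop_steps + 1]) - corrector,
                axis=1,
            )
            j = int(np.argmin(revisit))
            if revisit[j] < cfg.close_tol:
                del points[:j]
                return points, "closed"
        if fuse_with is not None and len(points) >= 2:
            d = np.linalg.norm(fuse_with - corrector, axis=1)
            if np.min(d) < cfg.close_tol:
                return points, "fused"
        disp = np.linalg.norm(corrector - current)
        if disp < cfg.stuck_tol:
            return points, "stuck"
        if len(points) >= 2:
            dists = np.linalg.norm(np.asarray(points[:-1]) - corrector, axis=1)
            if np.min(dists) < cfg.stuck_tol:
                return points, "stuck"
        step_dir = corrector - current
        nrm = np.linalg.norm(step_dir)
        prev_dir = step_dir / nrm if nrm > 0 else w
        points.append(corrector.copy())
        current = corrector
    return points, "max_steps"


def trace_core(
    q_frame: np.ndarray,
    vorticity_frame: np.ndarray,
    seed_point: np.ndarray,
    cfg: TraceConfig,
    grid: Grid,
    frame: int = -1,
) -> VortexCore:
    """Trace the vortex core polyline through a seed (mm position).

    Forward first; if the forward line does not close, a backward trace
    (negated vorticity) is appended, allowed to close by fusing with the
    forward line.  The returned core is classified as torus when closed;
    open lines carry shape "none" until :func:`classify_shape`.
    """
    seed = np.asarray(seed_point, dtype=float)
    fields = _Fields(q_frame, vorticity_frame, grid)
    if fields.q_at(seed) <= 0:
        raise ValueError("seed outside vortex (interpolated Q <= 0)")
    fwd, reason = _trace_one_direction(fields, seed, +1.0, cfg)
    if reason == "closed":
        core = VortexCore(points=np.asarray(fwd), closed=True, shape="torus", frame=frame)
    else:
        bwd, breason = _trace_one_direction(
            fields, seed, -1.0, cfg, fuse_with=np.asarray(fwd)
        )
        pts = np.asarray(list(reversed(bwd[1:])) + fwd)
        closed = breason in ("closed", "fused")
        core = VortexCore(
            points=pts, closed=closed, shape="torus" if closed else "none", frame=frame
        )
    _fit_axes(core)
    return core


def turning_angle(points: np.ndarray) -> float:
    """Total turning angle (degrees) of a polyline, measured as the absolute
    cumulative signed turning of its projection onto its best-fit plane."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        return 0.0
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[:2].T  # coordinates in the two principal directions
    seg = np.diff(proj, axis=0)
    keep = np.linalg.norm(seg, axis=1) > 1e-12
    seg = seg[keep]
    if seg.shape[0] < 2:
        return 0.0
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    turns = np.diff(ang)
    turns = (turns + np.pi) % (2 * np.pi) - np.pi
    return float(np.degrees(abs(np.sum(turns))))


def classify_shape(
    lines: list[VortexCore], cfg: TraceConfig
) -> tuple[str, VortexCore | None]:
    """Classify traced line(s): torus (closed), U (open, turning >= u_turn),
    bracket (two open lines whose endpoints pair up within bracket_gap and
    whose combined turning reaches u_turn), else none.

    Returns the label and, for a bracket, the combined core.
    """
    if not lines:
        return "none", None
    for ln in lines:
        if ln.closed:
            ln.shape = "torus"
            return "torus", ln
    for ln in lines:
        if ln.n_points >= 3 and turning_angle(ln.points) >= cfg.u_turn_deg:
            ln.shape = "U"
            return "U", ln
    if len(lines) == 2 and all(ln.n_points >= 2 for ln in lines):
        a, b = lines[0].points, lines[1].points
        straight = np.linalg.norm(a[0] - b[0]) <= cfg.bracket_gap and \
            np.linalg.norm(a[-1] - b[-1]) <= cfg.bracket_gap
        crossed = np.linalg.norm(a[0] - b[-1]) <= cfg.bracket_gap and \
            np.linalg.norm(a[-1] - b[0]) <= cfg.bracket_gap
        if straight or crossed:
            total = turning_angle(a) + turning_angle(b)
            if total >= cfg.u_turn_deg:
                b_ordered = b[::-1] if straight else b
                combined = VortexCore(
                    points=np.vstack([a, b_ordered]),
                    closed=False,
                    shape="bracket",
                    frame=lines[0].frame,
                )
                _fit_axes(combined)
                return "bracket", combined
    return "none", None


def ellipsoid_axes(points: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Major and minor axis lengths of an ellipsoid fitted to core points.

    Principal component analysis of the point coordinates; the length along
    each principal direction is twice the maximum absolute projection of the
    centered points.  Raises for fewer than 3 points or collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("ellipsoid fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    lengths = sorted(
        (2.0 * float(np.max(np.abs(centered @ vt[k]))) for k in range(min(3, vt.shape[0]))),
        reverse=True,
    )
    major, minor = lengths[0], lengths[1] if len(lengths) > 1 else 0.0
    if minor <= 1e-9 * max(major, 1.0):
        raise ValueError("core points are collinear")
    return major, minor, centroid


def _fit_axes(core: VortexCore) -> None:
    try:
        major, minor, centroid = ellipsoid_axes(core.points)
    except ValueError:
        core.major_axis = float(
            np.linalg.norm(core.points.max(axis=0) - core.points.min(axis=0))
        ) if core.n_points else 0.0
        core.minor_axis = 0.0
        return
    core.major_axis = major
    core.minor_axis = minor
    core.centroid = centroid


def _trace_frame_candidates(
    frame: int,
    candidates: list[VortexCandidate],
    q_frame: np.ndarray,
    vorticity_frame: np.ndarray,
    cfg: TraceConfig,
    grid: Grid,
) -> list[VortexCore]:
    cores = []
    for cand in candidates:
        vox = cand.voxels
        qvals = q_frame[tuple(vox.T)]
        seed = grid.positions(vox[int(np.argmax(qvals))])[0]
        try:
            core = trace_core(q_frame, vorticity_frame, seed, cfg, grid, frame=frame)
        except ValueError:
            continue
        if core.n_points >= 3:
            cores.append(core)
    return cores


def _resolve_frame_core(
    cores: list[VortexCore], cfg: TraceConfig, prev_centroid: np.ndarray | None
) -> VortexCore | None:
    """Apply the shape and two-core rules to the traced candidates of one frame."""
    if not cores:
        return None
    shaped = [c for c in cores if c.closed]
    for c in cores:
        if not c.closed and c.n_points >= 3 and turning_angle(c.points) >= cfg.u_turn_deg:
            c.shape = "U"
            shaped.append(c)
    pool = shaped if shaped else cores
    if len(cores) == 2 and not shaped:
        label, combined = classify_shape(cores, cfg)
        if label == "bracket" and combined is not None:
            return combined
    if len(pool) >= 2 and prev_centroid is not None:
        pool = sorted(pool, key=lambda c: np.linalg.norm(c.centroid - prev_centroid))
    return pool[0]


def track_cores(
    candidates_per_frame: dict[int, list[VortexCandidate]],
    q_series: QSeries,
    vorticity_frames: np.ndarray,
    cfg: TraceConfig,
    grid: Grid,
) -> dict[int, VortexCore]:
    """Trace cores over the vortex-frame window and flag MV-ring membership.

    The two peak frames of the max-Q curve seed the ring (membership there
    requires a recognizable shape).  Iteration then proceeds frame by frame:
    from the E peak backward to the window start and forward up to the
    minimum of the max-Q curve between the peaks; from the A peak forward to
    the window end and backward down to that minimum.  Membership propagates
    only while the core stays close to the previous frame's ring (centroid
    displacement <= track_dist) and keeps a similar size (relative major-axis
    change <= track_axis_change).
    """
    window = list(q_series.vortex_frames)
    e_peak, a_peak = q_series.peak_frames
    cores: dict[int, VortexCore] = {}

    def trace_at(frame: int, prev_centroid) -> VortexCore | None:
        cands = candidates_per_frame.get(frame, [])
        traced = _trace_frame_candidates(
            frame, cands, q_series.q_frames[frame], vorticity_frames[frame], cfg, grid
        )
        return _resolve_frame_core(traced, cfg, prev_centroid)

    def seed_peak(frame: int) -> VortexCore | None:
        core = trace_at(frame, None)
        if core is None:
            return None
        if core.shape == "none":
            label, combined = classify_shape([core], cfg)
            if label != "none" and combined is not None:
                core = combined
            core.shape = label if label != "none" else "none"
        core.is_mv_ring = core.shape != "none"
        cores[frame] = core
        return core

    def propagate(frames: list[int], prev: VortexCore | None) -> None:
        for f in frames:
            if prev is None:
                break
            core = trace_at(f, prev.centroid if prev is not None else None)
            if core is None:
                cores.pop(f, None)
                prev = None
                continue
            dist = float(np.linalg.norm(core.centroid - prev.centroid))
            axis_ok = (
                prev.major_axis > 0
                and abs(core.major_axis - prev.major_axis) / prev.major_axis
                <= cfg.track_axis_change
            )
            core.is_mv_ring = bool(prev.is_mv_ring and dist <= cfg.track_dist and axis_ok)
            cores[f] = core
            prev = core if core.is_mv_ring else None

    if not window:
        return cores
    pos_in_window = {f: i for i, f in enumerate(window)}
    if e_peak not in pos_in_window or a_peak not in pos_in_window:
        return cores

    # minimum of the max-Q curve between the two peaks (within the window)
    ie, ia = pos_in_window[e_peak], pos_in_window[a_peak]
    lo, hi = min(ie, ia), max(ie, ia)
    between = window[lo : hi + 1]
    min_frame = min(between, key=lambda f: q_series.max_curve[f]) if between else e_peak
    imin = pos_in_window[min_frame]

    e_core = seed_peak(e_peak)
    propagate([window[i] for i in range(ie - 1, -1, -1)], e_core)
    propagate([window[i] for i in range(ie + 1, imin + 1)], e_core)

    if a_peak != e_peak:
        a_core = seed_peak(a_peak)
        propagate([window[i] for i in range(ia + 1, len(window))], a_core)
        propagate([window[i] for i in range(ia - 1, imin, -1)], a_core)
    return cores
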
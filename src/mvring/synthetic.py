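"""Ground-truthed 4D vortex-ring flow phantoms.

The generator emulates the diastolic intraventricular flow pattern that the
extraction pipeline targets: a toroidal vortex ring forming below the mitral
valve inside an ellipsoidal left-ventricle, with biphasic (E/A-wave-like)
amplitude modulation over the cardiac cycle, additive rotation-free (gradient)
contamination and Gaussian velocity noise.

The base field is the Biot-Savart velocity of a circular vortex filament,
discretized as a polygon and regularized with a Gaussian (Lamb-Oseen-like)
core of radius ``a``; the regularization factor depends only on the distance
to each segment, which keeps the field analytically divergence-free.  The
velocity gradient of every segment contribution is available in closed form,
so the phantom also provides analytic Q and vorticity truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import Grid, MaskSeries, VelocitySeries

__all__ = [
    "RingSpec",
    "PhantomTruth",
    "ring_velocity_field",
    "ring_velocity_gradient",
    "analytic_q",
    "ellipsoid_lv_mask",
    "biphasic_phantom",
    "default_phantom",
]

RHO_BLOOD = 1060.0  # kg/m^3


@dataclass
class RingSpec:
    """Geometry and strength of a circular vortex filament.

    center (mm), unit normal, ring radius R (mm), core radius a (mm),
    circulation gamma (m^2/s), and a per-frame amplitude curve in [0, 1]
    that modulates the circulation over the cardiac cycle.
    """

    center: np.ndarray
    normal: np.ndarray
    radius: float = 16.0
    core_radius: float = 4.0
    circulation: float = 0.02
    amplitude_curve: np.ndarray = field(default_factory=lambda: np.ones(1))
    n_segments: int = 64

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(self.normal)
        if nrm == 0:
            raise ValueError("ring normal must be non-zero")
        self.normal = self.normal / nrm
        if not (self.radius > self.core_radius > 0):
            raise ValueError("require R > a > 0")
        self.amplitude_curve = np.asarray(self.amplitude_curve, dtype=float)
        if self.n_segments < 64:
            raise ValueError("ring discretization needs >= 64 segments")

    def filament_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment midpoints (mm) and segment vectors (mm) of the polygon."""
        n = self.n_segments
        # orthonormal in-plane basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(self.normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ self.normal) * self.normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(self.normal, e1)
        theta = 2 * np.pi * np.arange(n + 1) / n
        verts = (
            self.center
            + self.radius * np.outer(np.cos(theta), e1)
            + self.radius * np.outer(np.sin(theta), e2)
        )
        mid = 0.5 * (verts[:-1] + verts[1:])
        seg = np.diff(verts, axis=0)
        return mid, seg


@dataclass
class PhantomTruth:
    """Analytic ground truth recorded before contamination and noise.

    ``core_circles`` maps frame -> (center mm, normal, radius mm) for frames
    with non-zero amplitude; ``region_masks`` holds the analytic {Q > 0}
    voxel masks; ``present`` flags frames with amplitude > 0.
    """

    core_circles: dict[int, tuple[np.ndarray, np.ndarray, float]]
    region_masks: np.ndarray  # (N, nx, ny, nz) bool
    present: np.ndarray  # (N,) bool
    long_axis: np.ndarray  # unit 3-vector
    amplitude_curve: np.ndarray
    base_velocity: np.ndarray  # (nx, ny, nz, 3) at amplitude 1, m/s
    base_vorticity: np.ndarray  # analytic curl at amplitude 1, s^-1
    base_q: np.ndarray  # analytic Q at amplitude 1, s^-2

    def core_circle_points(self, frame: int, n: int = 256) -> np.ndarray:
        center, normal, radius = self.core_circles[frame]
        ref = np.array([1.0, 0.0, 0.0])
        if abs(normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ normal) * normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        th = 2 * np.pi * np.arange(n) / n
        return center + radius * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2))


def _biot_savart(
    points_mm: np.ndarray,
    spec: RingSpec,
    want_gradient: bool = False,
    chunk: int = 20000,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Velocity (m/s) and optionally its spatial gradient (s^-1) at points.

    Each polygon segment contributes ``u_i = c (L_i x d) g(|d|)`` with
    ``d = x - m_i`` and the 3D-Gaussian smoothing kernel
    ``g(s) = q(s / sigma) / s^3``, ``q(rho) = erf(rho/sqrt(2)) -
    rho sqrt(2/pi) exp(-rho^2/2)`` and ``sigma = a / sqrt(2)``.  Near the
    filament this reproduces a Lamb-Oseen core of radius ``a`` (peak
    vorticity Gamma / (pi a^2)); the gradient follows by direct
    differentiation.  Lengths are converted mm -> m so the field is in m/s
    and the gradient in s^-1.
    """
    from scipy.special import erf

    mids, segs = spec.filament_points()
    mids_m = mids * 1e-3
    segs_m = segs * 1e-3
    sigma = spec.core_radius * 1e-3 / np.sqrt(2.0)
    c = spec.circulation / (4 * np.pi)
    sq2pi = np.sqrt(2.0 / np.pi)
    pts_m = np.atleast_2d(points_mm) * 1e-3
    npts = pts_m.shape[0]
    vel = np.zeros((npts, 3))
    grad = np.zeros((npts, 3, 3)) if want_gradient else None
    eye = np.eye(3)
    for start in range(0, npts, chunk):
        p = pts_m[start : start + chunk]  # (P, 3)
        d = p[:, None, :] - mids_m[None, :, :]  # (P, S, 3)
        s2 = np.einsum("psk,psk->ps", d, d)
        s = np.sqrt(s2)
        np.maximum(s, 1e-12, out=s)
        rho = s / sigma
        ex = np.exp(-0.5 * rho**2)
        q = erf(rho / np.sqrt(2.0)) - rho * sq2pi * ex
        g = q / s**3
        lxd = np.cross(np.broadcast_to(segs_m, d.shape), d)  # (P, S, 3)
        vel[start : start + chunk] = c * np.einsum("psk,ps->pk", lxd, g)
        if want_gradient:
            # q'(rho) = sqrt(2/pi) rho^2 exp(-rho^2/2)
            dq = sq2pi * rho**2 * ex
            # g'(s) = q'(rho)/(sigma s^3) - 3 q/s^4
            dg_ds = dq / (sigma * s**3) - 3.0 * q / s**4
            # du_k/dx_j = c * [ (L x e_j)_k g + (L x d)_k g'(s) d_j / s ]
            lxe = np.cross(segs_m[:, None, :], eye[None, :, :])  # (S, 3j, 3k)
            term1 = np.einsum("sjk,ps->pkj", lxe, g)
            coeff = dg_ds / s  # carries the 1/s of the radial direction d_j/s
            term2 = np.einsum("psk,ps,psj->pkj", lxd, coeff, d)
            grad[start : start + chunk] = c * (term1 + term2)
    return vel, grad


def ring_velocity_field(spec: RingSpec, grid: Grid, frame: int = 0) -> np.ndarray:
    """Velocity volume (m/s) of the ring at one cardiac frame's amplitude."""
    amp = float(spec.amplitude_curve[frame])
    if amp == 0.0:
        return np.zeros((*grid.shape, 3))
    base = ring_base_field(spec, grid)
    return amp * base


def ring_base_field(spec: RingSpec, grid: Grid) -> np.ndarray:
    """Unit-amplitude ring velocity sampled at all voxel centers."""
    pts = _grid_points(grid)
    vel, _ = _biot_savart(pts, spec)
    return vel.reshape(*grid.shape, 3)


def ring_velocity_gradient(spec: RingSpec, grid: Grid) -> np.ndarray:
    """Analytic unit-amplitude velocity-gradient tensor volume (s^-1).

    Entry ``[..., k, j]`` is du_k/dx_j.
    """
    pts = _grid_points(grid)
    _, grad = _biot_savart(pts, spec, want_gradient=True)
    return grad.reshape(*grid.shape, 3, 3)


def analytic_q(gradient: np.ndarray) -> np.ndarray:
    """Q field from an analytic velocity-gradient tensor volume."""
    s_t = 0.5 * (gradient + np.swapaxes(gradient, -1, -2))
    o_t = 0.5 * (gradient - np.swapaxes(gradient, -1, -2))
    return 0.5 * (
        np.sum(o_t**2, axis=(-2, -1)) - np.sum(s_t**2, axis=(-2, -1))
    )


def analytic_vorticity(gradient: np.ndarray) -> np.ndarray:
    """Vorticity (curl) vectors from the analytic gradient tensor."""
    return np.stack(
        [
            gradient[..., 2, 1] - gradient[..., 1, 2],
            gradient[..., 0, 2] - gradient[..., 2, 0],
            gradient[..., 1, 0] - gradient[..., 0, 1],
        ],
        axis=-1,
    )


def _grid_points(grid: Grid) -> np.ndarray:
    ax = grid.axes_mm()
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def ellipsoid_lv_mask(
    grid: Grid,
    center_mm,
    semi_axes_mm,
    n_frames: int | None = None,
) -> MaskSeries:
    """Per-frame identical ellipsoidal LV mask (voxel centers inside)."""
    center = np.asarray(center_mm, dtype=float)
    semi = np.asarray(semi_axes_mm, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    if np.any(semi < np.asarray(grid.spacing)):
        raise ValueError("degenerate ellipsoid: semi-axis below voxel spacing")
    lo = center - semi
    hi = center + semi
    ax = grid.axes_mm()
    gmin = np.array([a[0] for a in ax])
    gmax = np.array([a[-1] for a in ax])
    if np.any(lo < gmin - 0.5 * grid.spacing_mm) or np.any(hi > gmax + 0.5 * grid.spacing_mm):
        raise ValueError("ellipsoid extends outside the grid")
    pts = _grid_points(grid)
    inside = np.sum(((pts - center) / semi) ** 2, axis=1) <= 1.0
    vol = inside.reshape(grid.shape)
    n = n_frames if n_frames is not None else grid.n_frames
    frames = np.broadcast_to(vol, (n, *grid.shape)).copy()
    g = Grid(grid.shape, grid.spacing, grid.origin, grid.frame_duration, n)
    return MaskSeries(grid=g, frames=frames, provenance="synthetic")


def _window_amplitudes(n_frames: int, window: tuple[int, int], scale: float) -> np.ndarray:
    """Smooth half-sine ramp over an inclusive frame window, zero outside."""
    first, last = window
    amp = np.zeros(n_frames)
    length = last - first + 1
    k = np.arange(1, length + 1)
    amp[first : last + 1] = scale * np.sin(np.pi * k / (length + 1))
    return amp


def _smooth_random_potential(shape, rng: np.random.Generator, sigma_vox: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    phi = rng.standard_normal(shape)
    return gaussian_filter(phi, sigma=sigma_vox, mode="nearest")


def biphasic_phantom(
    spec: RingSpec,
    grid: Grid,
    ea_timing: tuple[tuple[int, int], tuple[int, int]] = ((3, 8), (14, 19)),
    a_scale: float = 0.7,
    noise_sd: float = 0.01,
    grad_amp: float = 0.05,
    seed: int = 0,
    lv_center=None,
    lv_semi_axes=(26.0, 26.0, 40.0),
) -> tuple[VelocitySeries, MaskSeries, PhantomTruth]:
    """Biphasic (E/A) vortex-ring phantom with contamination and noise.

    Parameters
    ----------
    ea_timing : inclusive (first, last) frame windows of the E and A waves;
        they must be disjoint with a >= 2-frame diastasis gap.
    a_scale : circulation of the A ring relative to the E ring.
    noise_sd : Gaussian velocity noise standard deviation in m/s.
    grad_amp : peak magnitude (m/s) of the additive rotation-free
        contamination, built as the gradient of a smooth random scalar so
        that the true divergence-free part stays exactly the clean field.
    """
    (e0, e1), (a0, a1) = ea_timing
    n = grid.n_frames
    if not (0 <= e0 <= e1 < n and 0 <= a0 <= a1 < n):
        raise ValueError("E/A windows out of range")
    if not (e1 < a0 - 2 or a1 < e0 - 2):
        raise ValueError("E and A windows must be disjoint with a >= 2-frame diastasis gap")
    amp = _window_amplitudes(n, (e0, e1), 1.0) + _window_amplitudes(n, (a0, a1), a_scale)
    spec.amplitude_curve = amp

    base = ring_base_field(spec, grid)
    grad_tensor = ring_velocity_gradient(spec, grid)
    base_q = analytic_q(grad_tensor)
    base_vort = analytic_vorticity(grad_tensor)

    rng = np.random.default_rng(seed)
    frames = np.zeros((n, *grid.shape, 3))
    region_masks = np.zeros((n, *grid.shape), dtype=bool)
    core_circles: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    for f in range(n):
        v = amp[f] * base
        if amp[f] > 0:
            region_masks[f] = base_q > 0  # Q scales with amp^2 > 0
            core_circles[f] = (spec.center.copy(), spec.normal.copy(), spec.radius)
        if grad_amp > 0:
            phi = _smooth_random_potential(grid.shape, rng, sigma_vox=4.0)
            g = np.stack(np.gradient(phi, *grid.spacing_m, edge_order=2), axis=-1)
            peak = np.max(np.linalg.norm(g, axis=-1))
            if peak > 0:
                v = v + (grad_amp / peak) * g
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.shape)
        frames[f] = v

    if lv_center is None:
        lv_center = np.asarray(spec.center) - spec.normal * 16.0
    masks = ellipsoid_lv_mask(grid, lv_center, lv_semi_axes, n_frames=n)
    velocity = VelocitySeries(grid=grid, frames=frames, units_in="m/s")
    truth = PhantomTruth(
        core_circles=core_circles,
        region_masks=region_masks,
        present=amp > 0,
        long_axis=spec.normal.copy(),
        amplitude_curve=amp,
        base_velocity=base,
        base_vorticity=base_vort,
        base_q=base_q,
    )
    return velocity, masks, truth


def default_phantom(
    seed: int = 0,
    noise_sd: float = 0.01,
    grad_amp: float = 0.05,
    shape: tuple[int, int, int] = (64, 64, 40),
    spacing: tuple[float, float, float] = (1.8, 2.5, 4.0),
    n_frames: int = 30,
) -> tuple[VelocitySeries, MaskSeries, PhantomTruth]:
    """Study-scale phantom: 64 x 64 x 40 voxels at 1.8 x 2.5 x 4 mm^3,
    30 frames, R = 16 mm, a = 4 mm ring just below the LV base.
    """
    grid = Grid(shape=shape, spacing=spacing, n_frames=n_frames)
    fov_center = np.array(
        [grid.origin[i] + (shape[i] - 1) * spacing[i] / 2 for i in range(3)]
    )
    lv_center = fov_center
    ring_center = lv_center + np.array([0.0, 0.0, 16.0])  # toward the base
    spec = RingSpec(
        center=ring_center,
        normal=np.array([0.0, 0.0, 1.0]),
        radius=16.0,
        core_radius=4.0,
        circulation=0.02,
        amplitude_curve=np.zeros(n_frames),
    )
    return biphasic_phantom(
        spec,
        grid,
        noise_sd=noise_sd,
        grad_amp=grad_amp,
        seed=seed,
        lv_center=lv_center,
        lv_semi_axes=(26.0, 26.0, 40.0),
    )
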
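"""Helmholtz-Hodge decomposition: divergence-free part of the velocity field.

A smooth vector field splits uniquely into a rotation-free, a divergence-free
and a harmonic part.  Only the divergence-free part ``r`` carries rotational
information, so it is represented as the curl of a vector potential,
``r = curl(Psi)``, which turns the decomposition into the curl-curl Poisson
problem ``curl(curl(Psi)) = curl(v)`` with ``Psi = 0`` clamped on the
bounding-box boundary (this makes ``r`` tangential to the box faces).  The
discrete curl-curl operator is rank-deficient — discrete gradients lie in its
null space — so the system is solved by a minimum-norm least-squares Krylov
method (LSMR started from zero).

All finite differences are second order: central in the interior, one-sided
at box faces (``numpy.gradient`` with ``edge_order=2`` and matching sparse
matrices share the same stencils, so array and operator paths agree exactly).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsmr

from .types import BoundingBox, Grid, HodgeSolution, VelocitySeries

__all__ = [
    "discrete_curl",
    "discrete_divergence",
    "curl_matrix",
    "solve_vector_potential",
    "divergence_free_part",
]


def _gradients(component: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hx, hy, hz = spacing
    return np.gradient(component, hx, hy, hz, edge_order=2)


def discrete_curl(field: np.ndarray, spacing) -> np.ndarray:
    """Curl of a vector volume (..., 3) by second-order finite differences.

    ``spacing`` must be in the length unit consistent with the field values
    (pass spacing in meters for velocities in m/s to obtain s^-1).
    """
    fx, fy, fz = field[..., 0], field[..., 1], field[..., 2]
    _, dfx_dy, dfx_dz = _gradients(fx, spacing)
    dfy_dx, _, dfy_dz = _gradients(fy, spacing)
    dfz_dx, dfz_dy, _ = _gradients(fz, spacing)
    return np.stack(
        [dfz_dy - dfy_dz, dfx_dz - dfz_dx, dfy_dx - dfx_dy], axis=-1
    )


def discrete_divergence(field: np.ndarray, spacing) -> np.ndarray:
    """Divergence of a vector volume (..., 3), same stencils as the curl."""
    dfx_dx, _, _ = _gradients(field[..., 0], spacing)
    _, dfy_dy, _ = _gradients(field[..., 1], spacing)
    _, _, dfz_dz = _gradients(field[..., 2], spacing)
    return dfx_dx + dfy_dy + dfz_dz


def _diff_matrix_1d(n: int, h: float) -> sp.csr_matrix:
    """1D second-order first-derivative matrix matching numpy.gradient(edge_order=2)."""
    d = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        d[i, i - 1] = -0.5
        d[i, i + 1] = 0.5
    d[0, 0], d[0, 1], d[0, 2] = -1.5, 2.0, -0.5
    d[n - 1, n - 3], d[n - 1, n - 2], d[n - 1, n - 1] = 0.5, -2.0, 1.5
    return (d / h).tocsr()


def _partial_matrices(shape, spacing) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
    nx, ny, nz = shape
    dx = _diff_matrix_1d(nx, spacing[0])
    dy = _diff_matrix_1d(ny, spacing[1])
    dz = _diff_matrix_1d(nz, spacing[2])
    ix, iy, iz = sp.identity(nx), sp.identity(ny), sp.identity(nz)
    px = sp.kron(dx, sp.kron(iy, iz), format="csr")
    py = sp.kron(ix, sp.kron(dy, iz), format="csr")
    pz = sp.kron(ix, sp.kron(iy, dz), format="csr")
    return px, py, pz


def curl_matrix(shape, spacing) -> sp.csr_matrix:
    """Sparse matrix of the discrete curl on flattened (C-order) vector volumes.

    Acts on component-stacked vectors ``[Fx; Fy; Fz]`` of length 3 * nvox and
    reproduces :func:`discrete_curl` exactly.
    """
    px, py, pz = _partial_matrices(shape, spacing)
    z = sp.csr_matrix(px.shape)
    return sp.bmat(
        [
            [z, -pz, py],
            [pz, z, -px],
            [-py, px, z],
        ],
        format="csr",
    )


def boundary_shell_mask(shape) -> np.ndarray:
    """Boolean volume marking the one-voxel-thick boundary shell."""
    m = np.zeros(shape, dtype=bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


class CurlCurlOperator:
    """Pre-assembled curl-curl least-squares system for one box geometry.

    Assembling the sparse operator dominates setup cost, so the pipeline
    builds it once per bounding box and reuses it for every cardiac frame.
    """

    def __init__(self, shape, spacing):
        self.shape = tuple(shape)
        self.spacing = tuple(spacing)
        self.nvox = int(np.prod(self.shape))
        self.curl = curl_matrix(self.shape, self.spacing)
        shell = boundary_shell_mask(self.shape).ravel()
        free_scalar = np.flatnonzero(~shell)
        # unknowns: all three Psi components at interior voxels
        self.free_cols = np.concatenate(
            [free_scalar + c * self.nvox for c in range(3)]
        )
        self.A = (self.curl @ self.curl)[:, self.free_cols].tocsr()

    def solve(self, field: np.ndarray, tol: float = 1e-8, max_iter: int | None = None) -> HodgeSolution:
        """Minimum-norm least-squares solve of curl(curl(Psi)) = curl(field)."""
        if field.shape != (*self.shape, 3):
            raise ValueError(f"field shape {field.shape} != {(*self.shape, 3)}")
        b = self.curl @ field.reshape(-1, 3).T.ravel()
        if max_iter is None:
            max_iter = min(10 * self.A.shape[1], 100_000)
        bnorm = float(np.linalg.norm(b))
        if bnorm == 0.0:
            psi = np.zeros((*self.shape, 3))
            return HodgeSolution(psi=psi, r=np.zeros_like(psi), residual=0.0)
        x, istop, itn, normr, *_ = lsmr(self.A, b, atol=tol, btol=tol, maxiter=max_iter)[:4]
        residual = float(normr) / bnorm
        if istop == 7:
            raise RuntimeError(
                f"curl-curl solver did not converge within {max_iter} iterations "
                f"(achieved relative residual {residual:.3e})"
            )
        psi_flat = np.zeros(3 * self.nvox)
        psi_flat[self.free_cols] = x
        psi = psi_flat.reshape(3, *self.shape).transpose(1, 2, 3, 0)
        r = discrete_curl(psi, self.spacing)
        return HodgeSolution(psi=psi, r=r, residual=residual)


def solve_vector_potential(
    field: np.ndarray,
    spacing,
    tol: float = 1e-8,
    max_iter: int | None = None,
    operator: CurlCurlOperator | None = None,
) -> HodgeSolution:
    """Solve for the vector potential of one vector volume on its box.

    Parameters
    ----------
    field : (nx, ny, nz, 3) vector volume already restricted to the box.
    spacing : per-axis grid spacing (same length unit as positions implied
        by the field's derivative unit; meters for SI velocity input).
    tol : relative residual tolerance of the least-squares solve.
    """
    shape = field.shape[:3]
    if any(s < 3 for s in shape):
        raise ValueError("box interior must be at least 3 voxels per axis")
    if operator is None:
        operator = CurlCurlOperator(shape, spacing)
    return operator.solve(field, tol=tol, max_iter=max_iter)


def divergence_free_part(
    series: VelocitySeries,
    box: BoundingBox,
    tol: float = 1e-6,
    max_iter: int | None = None,
) -> tuple[VelocitySeries, list[HodgeSolution]]:
    """Divergence-free projection of every frame, restricted to the box.

    Returns a :class:`VelocitySeries` on the box subgrid whose frames are the
    divergence-free fields ``r = curl(Psi)``, plus the per-frame solutions.
    """
    subgrid = box.subgrid(series.grid)
    spacing_m = series.grid.spacing_m
    operator = CurlCurlOperator(box.shape, spacing_m)
    out = np.zeros((series.n_frames, *box.shape, 3))
    solutions: list[HodgeSolution] = []
    sl = box.slices
    for f in range(series.n_frames):
        sol = operator.solve(series.frames[f][sl], tol=tol, max_iter=max_iter)
        out[f] = sol.r
        solutions.append(sol)
    return VelocitySeries(grid=subgrid, frames=out), solutions
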
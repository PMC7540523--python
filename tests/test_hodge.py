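"""Finite-difference operators and the curl-curl vector-potential solve."""

import numpy as np
import pytest

from mvring.hodge import (
    CurlCurlOperator,
    boundary_shell_mask,
    curl_matrix,
    discrete_curl,
    discrete_divergence,
    divergence_free_part,
    solve_vector_potential,
)
from mvring.io import bounding_box
from mvring.types import BoundingBox, Grid, MaskSeries, VelocitySeries


def coords(shape, spacing):
    ax = [np.arange(n) * h for n, h in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


class TestDifferentialOperators:
    def test_uniform_field_has_zero_curl_and_divergence(self):
        f = np.ones((6, 7, 8, 3)) * np.array([1.0, -2.0, 0.5])
        sp = (1.8e-3, 2.5e-3, 4e-3)
        assert np.allclose(discrete_curl(f, sp), 0.0)
        assert np.allclose(discrete_divergence(f, sp), 0.0)

    def test_rigid_rotation_curl_is_twice_omega(self):
        # v = omega x x with omega = (0, 0, 1) -> curl = (0, 0, 2), div = 0
        sp = (1e-3, 1e-3, 1e-3)
        x, y, z = coords((8, 8, 8), sp)
        v = np.stack([-y, x, np.zeros_like(x)], axis=-1)
        curl = discrete_curl(v, sp)
        assert np.allclose(curl[..., 2], 2.0, atol=1e-9)
        assert np.allclose(curl[..., :2], 0.0, atol=1e-9)
        assert np.allclose(discrete_divergence(v, sp), 0.0, atol=1e-9)

    def test_linear_field_divergence_is_three(self):
        sp = (2e-3, 3e-3, 4e-3)
        x, y, z = coords((7, 7, 7), sp)
        v = np.stack([x, y, z], axis=-1)
        assert np.allclose(discrete_divergence(v, sp), 3.0, atol=1e-9)

    def test_curl_of_discrete_gradient_vanishes(self):
        # the 1D difference operators act on different axes and commute, so
        # curl(grad(phi)) is exactly zero (up to float roundoff)
        rng = np.random.default_rng(0)
        sp = (1.8e-3, 2.5e-3, 4e-3)
        phi = rng.standard_normal((9, 8, 7))
        g = np.stack(np.gradient(phi, *sp, edge_order=2), axis=-1)
        curl = discrete_curl(g, sp)
        assert np.abs(curl).max() <= 1e-6 * np.abs(g).max() / min(sp)

    def test_quadratic_gradient_field_curl_free(self):
        sp = (1e-3, 1e-3, 1e-3)
        x, y, z = coords((8, 8, 8), sp)
        v = np.stack([2 * x, 2 * y, np.zeros_like(x)], axis=-1)  # grad(x^2+y^2)
        assert np.allclose(discrete_curl(v, sp), 0.0, atol=1e-9)

    def test_sparse_curl_matrix_matches_array_curl(self):
        rng = np.random.default_rng(1)
        shape, sp = (7, 6, 5), (1.8e-3, 2.5e-3, 4e-3)
        f = rng.standard_normal((*shape, 3))
        c_arr = discrete_curl(f, sp)
        C = curl_matrix(shape, sp)
        c_mat = (C @ f.reshape(-1, 3).T.ravel()).reshape(3, *shape).transpose(1, 2, 3, 0)
        assert np.allclose(c_arr, c_mat, atol=1e-10 * np.abs(c_arr).max())


def _compact_potential(shape, spacing):
    """Smooth vector potential vanishing near the box faces."""
    x, y, z = coords(shape, spacing)
    L = [(n - 1) * h for n, h in zip(shape, spacing)]
    bump = (
        np.sin(np.pi * x / L[0]) * np.sin(np.pi * y / L[1]) * np.sin(np.pi * z / L[2])
    ) ** 2
    return np.stack([bump, 0.5 * bump, -0.3 * bump], axis=-1)


class TestVectorPotentialSolve:
    def test_reconstructs_curl_type_field(self):
        shape, sp = (24, 24, 24), (2e-3, 2e-3, 2e-3)
        field = discrete_curl(_compact_potential(shape, sp), sp)
        sol = solve_vector_potential(field, sp, tol=1e-8)
        err = np.linalg.norm(sol.r - field) / np.linalg.norm(field)
        assert err <= 1e-3

    def test_rejects_gradient_field(self):
        shape, sp = (24, 24, 24), (2e-3, 2e-3, 2e-3)
        x, y, z = coords(shape, sp)
        L = [(n - 1) * h for n, h in zip(shape, sp)]
        phi = np.sin(np.pi * x / L[0]) ** 2 * np.sin(np.pi * y / L[1]) ** 2 * np.sin(
            np.pi * z / L[2]
        ) ** 2
        # analytic gradient of the scalar, sampled on the grid
        gx = (2 * np.pi / L[0] * np.sin(np.pi * x / L[0]) * np.cos(np.pi * x / L[0])
              * np.sin(np.pi * y / L[1]) ** 2 * np.sin(np.pi * z / L[2]) ** 2)
        gy = (2 * np.pi / L[1] * np.sin(np.pi * y / L[1]) * np.cos(np.pi * y / L[1])
              * np.sin(np.pi * x / L[0]) ** 2 * np.sin(np.pi * z / L[2]) ** 2)
        gz = (2 * np.pi / L[2] * np.sin(np.pi * z / L[2]) * np.cos(np.pi * z / L[2])
              * np.sin(np.pi * x / L[0]) ** 2 * np.sin(np.pi * y / L[1]) ** 2)
        grad = np.stack([gx, gy, gz], axis=-1)
        sol = solve_vector_potential(grad, sp, tol=1e-8)
        assert np.linalg.norm(sol.r) <= 1e-2 * np.linalg.norm(grad)

    def test_matches_dense_minimum_norm_oracle_on_small_box(self):
        rng = np.random.default_rng(2)
        shape, sp = (5, 5, 5), (1e-3, 1e-3, 1e-3)
        op = CurlCurlOperator(shape, sp)
        field = rng.standard_normal((*shape, 3))
        sol = op.solve(field, tol=1e-12)
        # dense pseudo-inverse (minimum-norm least squares) oracle
        b = op.curl @ field.reshape(-1, 3).T.ravel()
        x = np.linalg.pinv(op.A.toarray()) @ b
        psi = np.zeros(3 * op.nvox)
        psi[op.free_cols] = x
        r_oracle = discrete_curl(psi.reshape(3, *shape).transpose(1, 2, 3, 0), sp)
        err = np.linalg.norm(sol.r - r_oracle) / max(np.linalg.norm(r_oracle), 1e-30)
        assert err <= 1e-8

    def test_tangency_on_box_faces(self):
        rng = np.random.default_rng(3)
        shape, sp = (10, 9, 8), (2e-3, 2e-3, 2e-3)
        sol = solve_vector_potential(rng.standard_normal((*shape, 3)), sp, tol=1e-8)
        scale = np.abs(sol.r).max()
        assert np.abs(sol.r[[0, -1], :, :, 0]).max() <= 1e-8 * scale
        assert np.abs(sol.r[:, [0, -1], :, 1]).max() <= 1e-8 * scale
        assert np.abs(sol.r[:, :, [0, -1], 2]).max() <= 1e-8 * scale

    def test_interior_divergence_small(self):
        shape, sp = (16, 16, 16), (2e-3, 2e-3, 2e-3)
        field = discrete_curl(_compact_potential(shape, sp), sp)
        sol = solve_vector_potential(field, sp, tol=1e-10)
        div = discrete_divergence(sol.r, sp)
        bound = 1e-6 * np.abs(sol.r).max() / min(sp)
        assert np.abs(div[2:-2, 2:-2, 2:-2]).max() <= bound

    def test_projection_is_linear(self):
        rng = np.random.default_rng(4)
        shape, sp = (8, 8, 8), (2e-3, 2e-3, 2e-3)
        op = CurlCurlOperator(shape, sp)
        u = rng.standard_normal((*shape, 3))
        v = rng.standard_normal((*shape, 3))
        a, b = 2.0, -0.5
        r_combo = op.solve(a * u + b * v, tol=1e-12).r
        r_parts = a * op.solve(u, tol=1e-12).r + b * op.solve(v, tol=1e-12).r
        assert np.linalg.norm(r_combo - r_parts) <= 1e-6 * np.linalg.norm(r_parts)

    def test_zero_field_maps_to_zero(self):
        sol = solve_vector_potential(np.zeros((5, 5, 5, 3)), (1e-3, 1e-3, 1e-3))
        assert np.all(sol.r == 0) and sol.residual == 0.0


class TestDivergenceFreePart:
    def test_idempotent_projection(self):
        shape, sp_mm = (14, 14, 14), (2.0, 2.0, 2.0)
        grid = Grid(shape=shape, spacing=sp_mm, n_frames=1)
        field = discrete_curl(_compact_potential(shape, grid.spacing_m), grid.spacing_m)
        series = VelocitySeries(grid=grid, frames=field[None])
        box = BoundingBox(lower=(0, 0, 0), upper=shape)
        once, _ = divergence_free_part(series, box, tol=1e-10)
        twice, _ = divergence_free_part(once, box, tol=1e-10)
        delta = np.linalg.norm(twice.frames - once.frames)
        assert delta <= 1e-3 * np.linalg.norm(once.frames)

    def test_removes_gradient_contamination_from_ring_field(self):
        # truth oracle: the divergence-free part of ring field + gradient
        # contamination is the clean ring field.  The box must be generous
        # relative to the ring: the tangential boundary condition alters the
        # through-flow of a ring whose far field the box crops.
        from mvring.synthetic import RingSpec, ring_base_field, _smooth_random_potential

        rng_grid = Grid(shape=(48, 48, 48), spacing=(2.5, 2.5, 2.5), n_frames=1)
        center = np.full(3, 47 * 2.5 / 2)
        spec = RingSpec(
            center=center, normal=np.array([0.0, 0.0, 1.0]), radius=7.0,
            core_radius=3.0, circulation=0.015, amplitude_curve=np.ones(1),
        )
        clean = ring_base_field(spec, rng_grid)
        phi = _smooth_random_potential(rng_grid.shape, np.random.default_rng(0), 4.0)
        g = np.stack(np.gradient(phi, *rng_grid.spacing_m, edge_order=2), axis=-1)
        g *= 0.05 / np.max(np.linalg.norm(g, axis=-1))
        noisy = VelocitySeries(grid=rng_grid, frames=(clean + g)[None])
        box = BoundingBox(lower=(0, 0, 0), upper=rng_grid.shape)
        proj, _ = divergence_free_part(noisy, box, tol=1e-8)
        inner = tuple(slice(3, s - 3) for s in rng_grid.shape)
        err = np.linalg.norm(proj.frames[0][inner] - clean[inner])
        assert err <= 0.05 * np.linalg.norm(clean[inner])
        # the gradient part itself is rejected at solver precision
        clean_series = VelocitySeries(grid=rng_grid, frames=clean[None])
        proj_clean, _ = divergence_free_part(clean_series, box, tol=1e-8)
        delta = np.linalg.norm(proj.frames[0] - proj_clean.frames[0])
        assert delta <= 1e-6 * np.linalg.norm(proj_clean.frames[0])
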
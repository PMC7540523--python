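"""Q fields, smoothing, thresholds, vortex-frame window and candidates."""

import numpy as np
import pytest

from mvring.qcrit import (
    apply_masks,
    candidate_factor,
    first_principal_component,
    frame_thresholds,
    q_field,
    select_candidates,
    smooth_q_series,
    threshold_regions,
    velocity_gradient_tensor,
    vortex_frame_window,
)
from mvring.types import Grid, MaskSeries, VortexCandidate


def full_masks(shape, n_frames=1):
    g = Grid(shape=shape, spacing=(1, 1, 1), n_frames=n_frames)
    return MaskSeries(grid=g, frames=np.ones((n_frames, *shape), dtype=bool))


def coords(shape, spacing):
    ax = [np.arange(n) * h for n, h in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


class TestGradientTensor:
    def test_uniform_field_zero_tensor(self):
        f = np.ones((6, 6, 6, 3))
        g = velocity_gradient_tensor(f, (1e-3, 1e-3, 1e-3))
        assert np.allclose(g, 0.0)

    def test_simple_shear_single_entry(self):
        sp = (1e-3, 1e-3, 1e-3)
        x, y, z = coords((7, 7, 7), sp)
        gamma = 3.0
        v = np.stack([gamma * y, np.zeros_like(y), np.zeros_like(y)], axis=-1)
        g = velocity_gradient_tensor(v, sp)
        expected = np.zeros((3, 3))
        expected[0, 1] = gamma
        assert np.allclose(g - expected, 0.0, atol=1e-9)

    def test_rigid_rotation_antisymmetric(self):
        sp = (1e-3, 1e-3, 1e-3)
        x, y, z = coords((7, 7, 7), sp)
        w = 2.0
        v = np.stack([-w * y, w * x, np.zeros_like(x)], axis=-1)
        g = velocity_gradient_tensor(v, sp)
        assert np.allclose(g[..., 0, 1], -w, atol=1e-9)
        assert np.allclose(g[..., 1, 0], w, atol=1e-9)


class TestQField:
    def test_rigid_rotation_q_equals_omega_squared(self):
        sp = (1e-3, 1e-3, 1e-3)
        x, y, z = coords((8, 8, 8), sp)
        w = 1.7
        v = np.stack([-w * y, w * x, np.zeros_like(x)], axis=-1)
        q = q_field(v, sp)
        assert np.allclose(q, w**2, rtol=1e-10)

    def test_pure_shear_q_zero(self):
        sp = (1e-3, 1e-3, 1e-3)
        x, y, z = coords((8, 8, 8), sp)
        v = np.stack([2.5 * y, np.zeros_like(y), np.zeros_like(y)], axis=-1)
        assert np.allclose(q_field(v, sp), 0.0, atol=1e-9)

    def test_uniform_field_q_zero(self):
        v = np.ones((6, 6, 6, 3))
        assert np.allclose(q_field(v, (1e-3, 1e-3, 1e-3)), 0.0)

    def test_galilean_invariance(self):
        rng = np.random.default_rng(0)
        sp = (1.8e-3, 2.5e-3, 4e-3)
        v = rng.standard_normal((8, 8, 8, 3))
        q0 = q_field(v, sp)
        q1 = q_field(v + np.array([0.3, -1.2, 0.7]), sp)
        # identical up to float roundoff of the shifted velocities
        assert np.abs(q1 - q0).max() <= 1e-9 * np.abs(q0).max()


class TestSmoothing:
    def test_constant_field_unchanged(self):
        q = np.full((4, 8, 8, 8), 3.5)
        out = smooth_q_series(q)
        assert np.allclose(out, 3.5)

    def test_median_removes_single_voxel_impulse(self):
        q = np.zeros((1, 9, 9, 9))
        q[0, 4, 4, 4] = 100.0
        out = smooth_q_series(q, spatial_sigma=0.0, median_size=3, temporal_sigma=0.0)
        assert np.all(out == 0.0)

    def test_short_lived_structures_attenuated_more(self):
        # a Q blob present in 1 of 30 frames is attenuated >= 2x more than
        # one present in 5 consecutive frames
        def peak_after(frames_present):
            q = np.zeros((30, 5, 5, 5))
            for f in frames_present:
                q[f, 2, 2, 2] = 1.0
            out = smooth_q_series(q, spatial_sigma=0.0, median_size=1, temporal_sigma=1.0)
            return out[:, 2, 2, 2].max()

        single = peak_after([15])
        sustained = peak_after([13, 14, 15, 16, 17])
        assert sustained / single >= 2.0


class TestMaskingAndThresholds:
    def test_full_mask_identity(self):
        rng = np.random.default_rng(1)
        q = rng.standard_normal((2, 6, 6, 6))
        masks = full_masks((6, 6, 6), 2)
        assert np.array_equal(apply_masks(q, masks), q)

    def test_empty_mask_frame_zeroes_q(self):
        q = np.ones((1, 6, 6, 6))
        g = Grid(shape=(6, 6, 6), spacing=(1, 1, 1), n_frames=1)
        masks = MaskSeries(grid=g, frames=np.zeros((1, 6, 6, 6), dtype=bool))
        assert np.all(apply_masks(q, masks) == 0.0)

    def test_masked_voxel_not_reported_as_maximum(self):
        q = np.zeros((1, 6, 6, 6))
        q[0, 0, 0, 0] = 100.0  # outside mask
        q[0, 3, 3, 3] = 5.0
        g = Grid(shape=(6, 6, 6), spacing=(1, 1, 1), n_frames=1)
        frames = np.zeros((1, 6, 6, 6), dtype=bool)
        frames[0, 2:5, 2:5, 2:5] = True
        masks = MaskSeries(grid=g, frames=frames)
        qm = apply_masks(q, masks)
        thr, max_curve, locs = frame_thresholds(qm, masks)
        assert tuple(locs[0]) == (3, 3, 3)
        assert max_curve[0] == 5.0

    def test_two_frame_worked_example(self):
        # frame 1: 10 at p1, 4 at p2; frame 2: 3 at p1, 8 at p2
        # -> thr_1 = (10+4)/2 = 7, thr_2 = (3+8)/2 = 5.5
        q = np.zeros((2, 5, 5, 5))
        p1, p2 = (1, 1, 1), (3, 3, 3)
        q[0][p1], q[0][p2] = 10.0, 4.0
        q[1][p1], q[1][p2] = 3.0, 8.0
        masks = full_masks((5, 5, 5), 2)
        thr, max_curve, locs = frame_thresholds(q, masks)
        assert thr[0] == pytest.approx(7.0)
        assert thr[1] == pytest.approx(5.5)
        assert max_curve.tolist() == [10.0, 8.0]

    def test_single_frame_threshold_is_frame_maximum(self):
        q = np.zeros((1, 5, 5, 5))
        q[0, 2, 2, 2] = 9.0
        masks = full_masks((5, 5, 5), 1)
        thr, max_curve, _ = frame_thresholds(q, masks)
        assert thr[0] == max_curve[0] == 9.0

    def test_identical_frames_threshold_equals_maximum(self):
        rng = np.random.default_rng(2)
        base = np.abs(rng.standard_normal((5, 5, 5)))
        q = np.stack([base] * 4)
        masks = full_masks((5, 5, 5), 4)
        thr, max_curve, _ = frame_thresholds(q, masks)
        assert np.allclose(thr, max_curve)

    def test_threshold_never_exceeds_frame_maximum(self):
        rng = np.random.default_rng(3)
        q = np.abs(rng.standard_normal((6, 6, 6, 6)))
        masks = full_masks((6, 6, 6), 6)
        thr, max_curve, _ = frame_thresholds(q, masks)
        assert np.all(thr <= max_curve + 1e-12)


class TestVortexFrameWindow:
    def test_biphasic_curve_spans_both_waves(self):
        n = 30
        curve = np.zeros(n)
        curve[3:9] = [5, 8, 10, 10, 8, 5]
        curve[14:20] = [4, 6, 8, 8, 6, 4]
        thr = 0.4 * curve  # plausible threshold curve
        window, peaks = vortex_frame_window(curve, thr)
        assert set(range(3, 20)).issubset(window)
        assert 3 <= peaks[0] <= 8 and 14 <= peaks[1] <= 19
        assert window.index(peaks[0]) < window.index(peaks[1])

    def test_constant_positive_curve_selects_all_frames(self):
        curve = np.full(10, 4.0)
        window, peaks = vortex_frame_window(curve, np.full(10, 4.0))
        assert window == list(range(10))
        assert peaks[0] == peaks[1]

    def test_single_peak_duplicated(self):
        curve = np.zeros(12)
        curve[5] = 10.0
        curve[4] = curve[6] = 6.0
        window, peaks = vortex_frame_window(curve, curve * 0.3)
        assert peaks == (5, 5)
        assert 5 in window

    def test_flat_zero_curve_raises(self):
        with pytest.raises(ValueError):
            vortex_frame_window(np.zeros(10), np.zeros(10))


class TestCandidates:
    def test_all_below_threshold_empty(self):
        q = np.full((5, 5, 5), 0.5)
        assert threshold_regions(q, 1.0) == []

    def test_two_separated_blobs(self):
        q = np.zeros((12, 12, 12))
        q[1:3, 1:3, 1:3] = 2.0  # 8 voxels
        q[8:11, 8:11, 8:11] = 3.0  # 27 voxels
        regions = threshold_regions(q, 1.0, min_voxels=5)
        sizes = sorted(r.n_voxels for r in regions)
        assert sizes == [8, 27]

    def test_single_blob_exact_voxels(self):
        q = np.zeros((8, 8, 8))
        q[2:5, 2:5, 2:5] = 2.0
        regions = threshold_regions(q, 1.0, min_voxels=1)
        assert len(regions) == 1
        assert set(map(tuple, regions[0].voxels)) == {
            (i, j, k) for i in range(2, 5) for j in range(2, 5) for k in range(2, 5)
        }

    def test_components_are_disjoint(self):
        rng = np.random.default_rng(5)
        q = rng.standard_normal((10, 10, 10))
        regions = threshold_regions(q, 1.0, min_voxels=1)
        seen = set()
        for r in regions:
            vox = set(map(tuple, r.voxels))
            assert not (vox & seen)
            seen |= vox


class TestPrincipalComponent:
    def grid(self, shape):
        return Grid(shape=shape, spacing=(1, 1, 1), n_frames=1)

    def test_static_blob_supported_on_blob(self):
        shape = (8, 8, 8)
        base = np.zeros(shape)
        base[2:5, 2:5, 2:5] = 1.0
        q = np.stack([a * base for a in (1.0, 2.0, 3.0)])
        thr = np.zeros(3)
        pc = first_principal_component(q, thr, [0, 1, 2], self.grid(shape))
        blob = base > 0
        assert np.abs(pc.w1[~blob]).max() <= 1e-9
        loc = tuple(int(v) for v in pc.w1_max_location)
        assert blob[loc]

    def test_sign_fixed_at_q_maximum(self):
        shape = (6, 6, 6)
        base = np.zeros(shape)
        base[2:4, 2:4, 2:4] = 1.0
        q = np.stack([a * base for a in (1.0, 3.0)])
        pc = first_principal_component(q, np.zeros(2), [0, 1], self.grid(shape))
        gmax = np.unravel_index(np.argmax(q.max(axis=0)), shape)
        assert pc.w1[gmax] >= 0

    def test_higher_variance_blob_dominates(self):
        shape = (12, 6, 6)
        a = np.zeros(shape); a[1:3, 2:4, 2:4] = 1.0
        b = np.zeros(shape); b[9:11, 2:4, 2:4] = 1.0
        # blob b varies 5x more than blob a, anti-correlated
        q = np.stack([a * 1.0 + b * 5.0, a * 2.0 + b * 0.0])
        pc = first_principal_component(q, np.zeros(2), [0, 1], self.grid(shape))
        wa = np.abs(pc.w1[a > 0]).max()
        wb = np.abs(pc.w1[b > 0]).max()
        assert wb > wa


class TestCandidateFactor:
    def make_pc(self, shape, w1, loc_mm):
        from mvring.qcrit import PCFields

        return PCFields(w1=w1, explained_variance_ratio=1.0, w1_max_location=np.asarray(loc_mm))

    def test_worked_example(self):
        # w1 values {1, 2, 3} over the region, d_max = 2 mm -> f_c = 3.0 / mm
        g = Grid(shape=(5, 5, 5), spacing=(1, 1, 1), n_frames=1)
        w1 = np.zeros((5, 5, 5))
        vox = np.array([[1, 1, 1], [2, 1, 1], [3, 1, 1]])
        w1[tuple(vox.T)] = [1.0, 2.0, 3.0]
        pc = self.make_pc((5, 5, 5), w1, [1.0, 1.0, 1.0])
        cand = candidate_factor(VortexCandidate(voxels=vox), pc, [1.0, 0, 0], g)
        assert cand.d_max == pytest.approx(2.0)
        assert cand.f_c == pytest.approx(3.0)

    def test_doubling_dmax_halves_factor(self):
        g = Grid(shape=(9, 5, 5), spacing=(1, 1, 1), n_frames=1)
        w1 = np.ones((9, 5, 5))
        near = VortexCandidate(voxels=np.array([[0, 1, 1], [2, 1, 1]]))
        far = VortexCandidate(voxels=np.array([[0, 1, 1], [4, 1, 1]]))
        pc = self.make_pc((9, 5, 5), w1, [0.0, 1.0, 1.0])
        c1 = candidate_factor(near, pc, [1.0, 0, 0], g)
        c2 = candidate_factor(far, pc, [1.0, 0, 0], g)
        assert c2.f_c == pytest.approx(c1.f_c / 2.0)

    def test_zero_w1_gives_zero_factor(self):
        g = Grid(shape=(5, 5, 5), spacing=(1, 1, 1), n_frames=1)
        pc = self.make_pc((5, 5, 5), np.zeros((5, 5, 5)), [0.0, 0.0, 0.0])
        cand = candidate_factor(
            VortexCandidate(voxels=np.array([[3, 3, 3]])), pc, [0, 0, 1.0], g
        )
        assert cand.f_c == 0.0


class TestSelectCandidates:
    def make(self, f_c, d_max):
        c = VortexCandidate(voxels=np.array([[0, 0, 0]]))
        c.f_c, c.d_max = f_c, d_max
        return c

    def test_distant_region_excluded(self):
        # f_c {5, 3, 1}, d_max {10, 12, 25} -> third excluded (25 >= 2 x 10)
        cands = [self.make(5, 10), self.make(3, 12), self.make(1, 25)]
        sel = select_candidates(cands)
        assert [c.f_c for c in sel] == [5, 3]

    def test_single_region_always_selected(self):
        sel = select_candidates([self.make(0.1, 99.0)])
        assert len(sel) == 1

    def test_empty_input_empty_output(self):
        assert select_candidates([]) == []
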
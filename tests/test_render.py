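"""Point-cloud reconstruction, hole filling, layering and DRC rendering."""

import numpy as np
import pytest

import lfm3d as L
from conftest import random_layered_scene, zbuffer_render_oracle

FIT = L.CalibrationFit(slope=1.0, intercept=0.0, r_squared=1.0, n_points=2)


def _metric(arr):
    return L.MetricDepthMap(depth_mm=np.asarray(arr, dtype=float), provenance=FIT)


class TestUpsample:
    def test_identity_resolution(self):
        rng = np.random.default_rng(0)
        m = _metric(rng.random((6, 6)))
        out = L.upsample_depth(m, (6, 6))
        np.testing.assert_array_equal(out.depth_mm, m.depth_mm)

    def test_constant_map_any_size(self):
        out = L.upsample_depth(_metric(np.full((4, 4), 2.2)), (17, 13))
        np.testing.assert_allclose(out.depth_mm, 2.2, atol=1e-9)

    def test_linear_ramp_reproduced(self):
        # bicubic reproduces affine data; compare away from the borders,
        # where the spline's edge extension decays
        n = 32
        ramp = np.tile(np.arange(float(n)), (n, 1))
        out = L.upsample_depth(_metric(ramp), (2 * n, 2 * n))
        cols = (np.arange(2 * n) + 0.5) / 2 - 0.5
        expected = np.tile(cols, (2 * n, 1))
        interior = np.s_[24:-24, 24:-24]
        np.testing.assert_allclose(out.depth_mm[interior], expected[interior], atol=1e-6)

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError):
            L.upsample_depth(_metric(np.zeros((8, 8))), (4, 8))

    def test_range_preserved(self):
        rng = np.random.default_rng(1)
        m = _metric(rng.random((10, 10)))
        out = L.upsample_depth(m, (40, 40))
        assert out.depth_mm.min() >= m.depth_mm.min()
        assert out.depth_mm.max() <= m.depth_mm.max()


class TestFillHoles:
    def test_no_holes_is_identity(self):
        rng = np.random.default_rng(2)
        m = _metric(rng.random((9, 9)))
        out = L.fill_holes(m, np.zeros((9, 9), bool))
        np.testing.assert_array_equal(out.depth_mm, m.depth_mm)

    def test_plane_hole_filled_exactly(self):
        yy, xx = np.mgrid[0:12, 0:12]
        plane = 0.3 * xx + 0.7 * yy + 1.0
        holes = np.zeros((12, 12), bool)
        holes[4:8, 3:9] = True
        broken = plane.copy()
        broken[holes] = -99.0
        out = L.fill_holes(_metric(broken), holes)
        np.testing.assert_allclose(out.depth_mm, plane, atol=1e-10)

    def test_quadratic_hole_beats_constant_fill(self):
        yy, xx = np.mgrid[0:15, 0:15] / 14.0
        surf = xx**2 + yy**2
        holes = np.zeros((15, 15), bool)
        holes[5:10, 5:10] = True
        broken = surf.copy()
        broken[holes] = 0.0
        out = L.fill_holes(_metric(broken), holes)
        err_coons = np.abs(out.depth_mm[holes] - surf[holes]).max()
        const_fill = surf[~holes & (np.abs(xx * 14 - 7) <= 3) & (np.abs(yy * 14 - 7) <= 3)].mean()
        err_const = np.abs(const_fill - surf[holes]).max()
        assert err_coons < err_const

    def test_border_hole_warns_and_fills(self):
        d = np.ones((8, 8))
        holes = np.zeros((8, 8), bool)
        holes[0, 2:5] = True
        broken = d.copy()
        broken[holes] = 0.0
        with pytest.warns(UserWarning):
            out = L.fill_holes(_metric(broken), holes)
        np.testing.assert_allclose(out.depth_mm, 1.0)

    def test_nonhole_pixels_untouched(self):
        rng = np.random.default_rng(3)
        d = rng.random((10, 10))
        holes = np.zeros((10, 10), bool)
        holes[4:6, 4:7] = True
        out = L.fill_holes(_metric(d), holes)
        np.testing.assert_array_equal(out.depth_mm[~holes], d[~holes])


class TestPointCloud:
    def test_count_conservation(self):
        rng = np.random.default_rng(4)
        pc = L.build_point_cloud(_metric(rng.random((10, 10))), rng.random((10, 10, 3)), 0.1)
        assert len(pc) == 100

    def test_stride_subsampling(self):
        rng = np.random.default_rng(5)
        pc = L.build_point_cloud(
            _metric(rng.random((10, 10))), rng.random((10, 10, 3)), 0.1, stride=2
        )
        assert len(pc) == 25
        assert pc.lateral_scale == pytest.approx(0.2)

    def test_flat_depth_constant_z(self):
        rng = np.random.default_rng(6)
        pc = L.build_point_cloud(_metric(np.full((5, 5), 1.5)), rng.random((5, 5, 3)), 1.0)
        assert np.all(pc.points[:, 2] == 1.5)

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.build_point_cloud(_metric(np.zeros((5, 5))), np.zeros((6, 5, 3)), 1.0)

    def test_ply_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        pc = L.build_point_cloud(_metric(rng.random((6, 6))), rng.random((6, 6, 3)), 0.5)
        for binary in (True, False):
            path = tmp_path / f"cloud_{binary}.ply"
            L.save_point_cloud(pc, path, binary=binary)
            back = L.load_point_cloud(path, lateral_scale=0.5)
            np.testing.assert_allclose(back.points, pc.points, atol=1e-6)
            np.testing.assert_allclose(back.colors, pc.colors, atol=1 / 255)


class TestLayering:
    def _cloud(self, zs, seed=8):
        rng = np.random.default_rng(seed)
        n = len(zs)
        pts = np.column_stack([np.arange(n) * 0.1, np.zeros(n), zs])
        return L.PointCloud(points=pts, colors=rng.random((n, 3)), lateral_scale=0.1)

    def test_single_layer(self):
        sc = L.layer_scene(self._cloud([1.0, 2.0, 3.0]), 1)
        assert sc.n_layers == 1
        assert sc.masks.sum() == 3

    def test_two_values_partition_perfectly(self):
        sc = L.layer_scene(self._cloud([1.0, 1.0, 5.0, 5.0]), 2)
        assert sc.masks[0].sum() == 2
        assert sc.masks[1].sum() == 2

    def test_degenerate_range_collapses(self):
        sc = L.layer_scene(self._cloud([2.0, 2.0, 2.0]), 5)
        assert sc.n_layers == 1

    def test_every_cell_single_layer(self):
        rng = np.random.default_rng(9)
        pc = L.PointCloud(
            points=rng.random((200, 3)), colors=rng.random((200, 3)), lateral_scale=0.2
        )
        sc = L.layer_scene(pc, 7)
        assert sc.masks.sum(axis=0).max() <= 1

    def test_default_layer_count_rule(self):
        assert L.default_layer_count(3.0, 0.05, 1.0) == 60
        assert L.default_layer_count(100.0, 0.01, 0.5, cap=128) == 128
        assert L.default_layer_count(0.0, 0.05, 1.0) == 1


class TestInteraction:
    def _cloud(self, seed=10, n=50):
        rng = np.random.default_rng(seed)
        return L.PointCloud(points=rng.random((n, 3)), colors=rng.random((n, 3)),
                            lateral_scale=0.1)

    def test_identity(self):
        pc = self._cloud()
        out = L.apply_interaction(pc)
        np.testing.assert_allclose(out.points, pc.points, atol=1e-12)

    def test_zoom_scales_pairwise_distances(self):
        pc = self._cloud()
        out = L.apply_interaction(pc, zoom=2.0)
        d0 = np.linalg.norm(pc.points[0] - pc.points[1])
        d1 = np.linalg.norm(out.points[0] - out.points[1])
        assert d1 == pytest.approx(2 * d0)
        assert len(out) == len(pc)

    def test_full_turn_is_identity(self):
        pc = self._cloud()
        out = L.apply_interaction(pc, rotation_deg=(0.0, 360.0, 0.0))
        np.testing.assert_allclose(out.points, pc.points, atol=1e-9)

    def test_rotation_preserves_distances(self):
        pc = self._cloud()
        out = L.apply_interaction(pc, rotation_deg=(20.0, -35.0, 10.0))
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(out.points), pdist(pc.points), atol=1e-9)


class TestDrcRendering:
    def test_empty_scene_uniform_background(self, small_display):
        scene = L.LayeredScene(
            z_planes=np.array([7.0]), masks=np.zeros((1, 10, 10), bool),
            colors=np.zeros((1, 10, 10, 3)), cell_size_mm=0.3, origin_xy=(-1.5, -1.5),
        )
        eia = L.render_eia_drc(scene, small_display, (11, 11), background=(0.2, 0.3, 0.4))
        assert np.allclose(eia.raster, [0.2, 0.3, 0.4])

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_zbuffer_oracle(self, small_display, seed):
        scene = random_layered_scene(seed)
        eia = L.render_eia_drc(scene, small_display, (11, 11))
        oracle = zbuffer_render_oracle(scene, small_display, (11, 11))
        np.testing.assert_array_equal(eia.raster, oracle)

    def test_ray_count_equals_raster_pixels(self, small_display):
        scene = random_layered_scene(1)
        eia = L.render_eia_drc(scene, small_display, (9, 9))
        assert eia.rays_cast == eia.raster.shape[0] * eia.raster.shape[1]

    def test_occlusion_monotonicity(self, small_display):
        # adding a nearer opaque layer never changes pixels already struck
        # by a yet-nearer layer
        scene = random_layered_scene(2, n_layers=2)
        eia_before = L.render_eia_drc(scene, small_display, (9, 9))
        rng = np.random.default_rng(3)
        # insert a new layer between the two existing ones
        mid_mask = (rng.random(scene.masks.shape[1:]) < 0.3) & ~scene.masks.any(axis=0)
        z_new = 0.5 * (scene.z_planes[0] + scene.z_planes[1])
        scene2 = L.LayeredScene(
            z_planes=np.array([scene.z_planes[0], z_new, scene.z_planes[1]]),
            masks=np.stack([scene.masks[0], mid_mask, scene.masks[1]]),
            colors=np.stack([scene.colors[0], rng.random(scene.colors.shape[1:]) * mid_mask[..., None], scene.colors[1]]),
            cell_size_mm=scene.cell_size_mm, origin_xy=scene.origin_xy,
        )
        eia_after = L.render_eia_drc(scene2, small_display, (9, 9))
        # pixels struck by the nearest layer in the original render are unchanged
        oracle_near_only = L.render_eia_drc(
            L.LayeredScene(
                z_planes=scene.z_planes[:1], masks=scene.masks[:1],
                colors=scene.colors[:1], cell_size_mm=scene.cell_size_mm,
                origin_xy=scene.origin_xy,
            ),
            small_display, (9, 9), background=(-1.0, -1.0, -1.0),
        )
        struck = oracle_near_only.raster[:, :, 0] >= 0
        np.testing.assert_array_equal(eia_after.raster[struck], eia_before.raster[struck])

    def test_nonpositive_layer_depth_rejected(self, small_display):
        scene = L.LayeredScene(
            z_planes=np.array([-1.0]), masks=np.ones((1, 4, 4), bool),
            colors=np.zeros((1, 4, 4, 3)), cell_size_mm=0.3, origin_xy=(0.0, 0.0),
        )
        with pytest.raises(ValueError):
            L.render_eia_drc(scene, small_display, (5, 5))


class TestPreviewViews:
    def _plane_scene(self, small_display, seed=11, hw=24):
        rng = np.random.default_rng(seed)
        z = small_display.conjugate_plane_mm
        masks = np.ones((1, hw, hw), bool)
        colors = rng.random((1, hw, hw, 3))
        cell = 0.2
        # grid centered on the optical axis (cell (hw-1)/2 at x = 0)
        return L.LayeredScene(
            z_planes=np.array([z]), masks=masks, colors=colors,
            cell_size_mm=cell,
            origin_xy=(-cell * (hw - 1) / 2, -cell * (hw - 1) / 2),
        )

    def test_empty_scene_views_are_background(self, small_display):
        scene = L.LayeredScene(
            z_planes=np.array([7.0]), masks=np.zeros((1, 6, 6), bool),
            colors=np.zeros((1, 6, 6, 3)), cell_size_mm=0.3, origin_xy=(-0.9, -0.9),
        )
        eia = L.render_eia_drc(scene, small_display, (11, 11))
        views = L.preview_views(eia, small_display, [0.0, 3.0])
        assert all(np.all(v == 0) for v in views)

    def test_symmetric_scene_views_mirror(self, small_display):
        scene = self._plane_scene(small_display)
        # mirror the scene colors laterally to make it symmetric
        sym_colors = 0.5 * (scene.colors + scene.colors[:, :, ::-1])
        scene = L.LayeredScene(
            z_planes=scene.z_planes, masks=scene.masks, colors=sym_colors,
            cell_size_mm=scene.cell_size_mm, origin_xy=scene.origin_xy,
        )
        eia = L.render_eia_drc(scene, small_display, (11, 11))
        plus, minus = L.preview_views(eia, small_display, [2.0, -2.0])
        np.testing.assert_allclose(plus, minus[:, ::-1], atol=1e-12)

    def test_angle_outside_acceptance_warns(self, small_display):
        scene = self._plane_scene(small_display)
        eia = L.render_eia_drc(scene, small_display, (11, 11))
        with pytest.warns(UserWarning):
            L.preview_views(eia, small_display, [45.0])

    def test_zero_degree_view_samples_central_pixels(self, small_display):
        scene = self._plane_scene(small_display)
        eia = L.render_eia_drc(scene, small_display, (11, 11))
        (v0,) = L.preview_views(eia, small_display, [0.0])
        np.testing.assert_array_equal(v0, eia.raster[5::11, 5::11])
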
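"""Seed selection against brute force, closed-form TIN metrics, the
acceptance rule's threshold behavior, and the filter's invariants
(monotone growth, idempotence, translation invariance)."""

import numpy as np
import pytest

import vinepest as vp
from vinepest.ground_filter import Tin, _batch_metrics


def flat_cloud(rng, n=2000, extent=30.0, z=5.0, jitter=0.0):
    xyz = np.column_stack(
        [
            rng.uniform(0, extent, n),
            rng.uniform(0, extent, n),
            np.full(n, z) + (rng.normal(0, jitter, n) if jitter else 0.0),
        ]
    )
    return vp.PointCloud(xyz)


class TestSeedTin:
    def test_four_cells_on_a_plane_give_four_vertices_two_triangles(self):
        # one point per 6 m cell, corners of a square
        pts = [[1, 1, 0], [7, 1, 0], [1, 7, 0], [7, 7, 0]]
        tin = vp.build_seed_tin(vp.PointCloud(pts), cell_size=6.0)
        assert len(tin.vertices) == 4
        assert len(tin.triangles) == 2

    def test_lowest_point_in_cell_wins(self):
        pts = [[1, 1, 5.0], [1.5, 1.5, 1.0], [7, 1, 0], [1, 7, 0], [7, 7, 0]]
        tin = vp.build_seed_tin(vp.PointCloud(pts), cell_size=6.0)
        cell0 = tin.vertices[
            (tin.vertices[:, 0] < 6) & (tin.vertices[:, 1] < 6)
        ]
        assert cell0.shape == (1, 3)
        assert cell0[0, 2] == 1.0

    def test_seeds_match_per_cell_argmin_brute_force(self, rng):
        cloud = flat_cloud(rng, n=1000, extent=30.0, jitter=2.0)
        tin = vp.build_seed_tin(cloud, cell_size=6.0)
        xyz = cloud.xyz
        mins = xyz[:, :2].min(axis=0)
        ij = np.floor((xyz[:, :2] - mins) / 6.0).astype(int)
        for cell in {tuple(t) for t in ij}:
            in_cell = (ij == cell).all(axis=1)
            zmin = xyz[in_cell, 2].min()
            # that point must be a TIN vertex
            winner = xyz[in_cell][xyz[in_cell, 2].argmin()]
            assert any(
                np.allclose(winner, v) for v in tin.vertices
            ), f"cell {cell} argmin z={zmin} not among seeds"

    def test_collinear_seeds_cannot_triangulate(self):
        pts = [[x, 0.0, 0.0] for x in (1, 7, 13, 19)]
        with pytest.raises(ValueError, match="triangulate|collinear"):
            vp.build_seed_tin(vp.PointCloud(pts), cell_size=6.0)


class TestTinMetrics:
    def facet(self):
        """Horizontal equilateral triangle, vertex-to-centroid distance 1."""
        r = 1.0
        angles = np.deg2rad([90, 210, 330])
        verts = np.column_stack(
            [r * np.cos(angles), r * np.sin(angles), np.zeros(3)]
        )
        return Tin.from_points(verts)

    def test_point_on_facet_is_zero_zero(self):
        tin = self.facet()
        m = vp.point_to_tin_metrics([0.0, 0.0, 0.0], tin)
        assert m.distance == pytest.approx(0.0, abs=1e-12)
        assert m.angle == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("h", [0.1, 0.5, 1.0, 3.0])
    def test_point_above_centroid_closed_form(self, h):
        # distance = h, angle = atan(h / r) with r = 1
        tin = self.facet()
        m = vp.point_to_tin_metrics([0.0, 0.0, h], tin)
        assert m.distance == pytest.approx(h, rel=1e-12)
        assert m.angle == pytest.approx(np.degrees(np.arctan(h)), rel=1e-9)
        assert not m.extrapolated

    def test_point_below_is_symmetric(self):
        tin = self.facet()
        up = vp.point_to_tin_metrics([0.0, 0.0, 0.7], tin)
        down = vp.point_to_tin_metrics([0.0, 0.0, -0.7], tin)
        assert up.distance == pytest.approx(down.distance)
        assert up.angle == pytest.approx(down.angle)

    def test_outside_hull_is_flagged_extrapolated(self):
        tin = self.facet()
        m = vp.point_to_tin_metrics([50.0, 50.0, 0.0], tin)
        assert m.extrapolated

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_point_matches_vector_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        verts = np.column_stack(
            [rng.uniform(0, 10, 3), rng.uniform(0, 10, 3), rng.uniform(0, 2, 3)]
        )
        tin = Tin.from_points(verts)
        # query above the triangle centroid so the facet is unambiguous
        centroid = verts.mean(axis=0)
        p = centroid + np.array([0.0, 0.0, rng.uniform(0.2, 3.0)])
        m = vp.point_to_tin_metrics(p, tin)
        # independent computation: plane from 3 points, plumb-line
        # residual |z - plane(x, y)|, explicit segment-to-plane angles
        v0, v1, v2 = verts
        normal = np.cross(v1 - v0, v2 - v0)
        normal /= np.linalg.norm(normal)
        exp_dist = abs(np.dot(normal, p - v0)) / abs(normal[2])
        exp_angle = max(
            np.degrees(
                np.arcsin(
                    abs(np.dot(normal, p - v))
                    / np.linalg.norm(p - v)
                )
            )
            for v in verts
        )
        assert m.distance == pytest.approx(exp_dist, rel=1e-9)
        assert m.angle == pytest.approx(exp_angle, rel=1e-9)


class TestClassifyGround:
    def test_flat_plane_is_fully_ground(self, rng):
        cloud = flat_cloud(rng, n=10_000, extent=40.0)
        out = vp.classify_ground(cloud, vp.GroundFilterParams())
        assert (out.classification == vp.CLASS_GROUND).all()

    def test_outlier_above_plane_is_vegetation(self, rng):
        cloud = flat_cloud(rng, n=5000, extent=40.0)
        xyz = np.vstack([cloud.xyz, [[20.0, 20.0, 5.0 + 1.5]]])
        out = vp.classify_ground(vp.PointCloud(xyz), vp.GroundFilterParams())
        assert out.classification[-1] == vp.CLASS_MEDIUM_VEGETATION
        assert (out.classification[:-1] == vp.CLASS_GROUND).all()

    def test_empty_and_degenerate_clouds_error(self):
        with pytest.raises(ValueError):
            vp.classify_ground(
                vp.PointCloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]]),
                vp.GroundFilterParams(cell_size=0.5),
            )

    def test_loose_thresholds_accept_everything(self, small_scene):
        params = vp.GroundFilterParams(max_angle=89.9, max_distance=1e9)
        out = vp.classify_ground(
            vp.PointCloud(small_scene.cloud.xyz), params
        )
        noise = out.classification == vp.CLASS_NOISE
        assert (out.classification[~noise] == vp.CLASS_GROUND).all()

    def test_zero_distance_keeps_only_seeds_ground(self, rng):
        cloud = flat_cloud(rng, n=3000, extent=40.0, jitter=0.05)
        params = vp.GroundFilterParams(max_distance=0.0)
        out = vp.classify_ground(cloud, params)
        n_ground = int((out.classification == vp.CLASS_GROUND).sum())
        tin = vp.build_seed_tin(cloud, params.cell_size)
        assert n_ground == len(tin.vertices)

    def test_translation_invariance(self, rng):
        """Labels survive a constant coordinate shift.  Exact equality
        is impossible in floating point (shifted coordinates round
        differently, flipping cell/triangle ties), so near-threshold
        points may flip; agreement must still be essentially total."""
        cloud = flat_cloud(rng, n=3000, extent=30.0, jitter=0.3)
        params = vp.GroundFilterParams()
        a = vp.classify_ground(cloud, params).classification
        shifted = vp.PointCloud(cloud.xyz + np.array([123.4, -987.6, 55.5]))
        b = vp.classify_ground(shifted, params).classification
        assert (a == b).mean() >= 0.995

    def test_idempotent_on_ground_subset(self, small_scene):
        params = vp.GroundFilterParams()
        first = vp.classify_ground(vp.PointCloud(small_scene.cloud.xyz), params)
        ground_only = first.subset(first.classification == vp.CLASS_GROUND)
        second = vp.classify_ground(vp.PointCloud(ground_only.xyz), params)
        assert (second.classification == vp.CLASS_GROUND).all()

    def test_low_outliers_are_noise(self, rng):
        cloud = flat_cloud(rng, n=4000, extent=40.0, jitter=0.01)
        xyz = np.vstack([cloud.xyz, [[10.0, 10.0, 5.0 - 2.5]]])
        out = vp.classify_ground(vp.PointCloud(xyz), vp.GroundFilterParams())
        assert out.classification[-1] == vp.CLASS_NOISE

    def test_synthetic_scene_truth_recovery(self, small_scene):
        out = vp.classify_ground(
            vp.PointCloud(small_scene.cloud.xyz), vp.GroundFilterParams()
        )
        truth = small_scene.cloud.classification
        ground_rec = (
            (out.classification == vp.CLASS_GROUND) & (truth == vp.CLASS_GROUND)
        ).sum() / (truth == vp.CLASS_GROUND).sum()
        veg_rec = (
            (out.classification == vp.CLASS_MEDIUM_VEGETATION)
            & (truth == vp.CLASS_MEDIUM_VEGETATION)
        ).sum() / (truth == vp.CLASS_MEDIUM_VEGETATION).sum()
        assert ground_rec >= 0.99
        assert veg_rec >= 0.95


class TestMonotonicity:
    def test_ground_set_grows_monotonically_across_iterations(self, rng):
        """Capping the iteration count earlier always yields a subset of
        the later ground set (the deterministic trajectory only adds)."""
        cloud = flat_cloud(rng, n=4000, extent=40.0, jitter=0.4)
        previous = None
        for cap in (1, 2, 3, 50):
            params = vp.GroundFilterParams(max_iterations=cap)
            ground = (
                vp.classify_ground(cloud, params).classification
                == vp.CLASS_GROUND
            )
            if previous is not None:
                assert (previous & ~ground).sum() == 0, (
                    f"ground set shrank between caps {cap}"
                )
            previous = ground
        tin = vp.build_seed_tin(cloud, 6.0)
        first = vp.classify_ground(
            cloud, vp.GroundFilterParams(max_iterations=1)
        )
        assert (first.classification == vp.CLASS_GROUND).sum() >= len(tin.vertices)
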
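"""Color conversion anchors against the sRGB/D65 formulas, k-means
behavior on chroma, training-set bookkeeping, ANN separability and
determinism, and pointwise classification."""

import numpy as np
import pytest

import vinepest as vp
from vinepest.laic import AFFECTED, OTHER, cluster_mean_rgb
from vinepest.geomatic_io import MASK_NODATA


def reference_rgb_to_lab(rgb):
    """Independent implementation of sRGB (D65) -> L*a*b* from the
    published formulas: inverse companding, the RGB->XYZ matrix, and
    the f(t) cube-root transfer."""
    rgb = np.asarray(rgb, dtype=float) / 255.0
    lin = np.where(rgb > 0.04045, ((rgb + 0.055) / 1.055) ** 2.4, rgb / 12.92)
    m = np.array(
        [
            [0.4124, 0.3576, 0.1805],
            [0.2126, 0.7152, 0.0722],
            [0.0193, 0.1192, 0.9505],
        ]
    )
    xyz = m @ lin
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    L = 116 * f[1] - 16
    a = 500 * (f[0] - f[1])
    b = 200 * (f[1] - f[2])
    return L, a, b


class TestRgbToLab:
    def test_white_anchor(self):
        lab = vp.rgb_to_lab(np.array([[[255, 255, 255]]], dtype=np.uint8))
        assert lab.L[0, 0] == pytest.approx(100.0, abs=0.01)
        assert abs(lab.a[0, 0]) < 0.01
        assert abs(lab.b[0, 0]) < 0.01

    def test_black_anchor(self):
        lab = vp.rgb_to_lab(np.array([[[0, 0, 0]]], dtype=np.uint8))
        assert abs(lab.L[0, 0]) < 0.01
        assert abs(lab.a[0, 0]) < 0.01
        assert abs(lab.b[0, 0]) < 0.01

    def test_mid_gray_is_neutral_and_matches_formulas(self):
        lab = vp.rgb_to_lab(np.array([[[119, 119, 119]]], dtype=np.uint8))
        assert abs(lab.a[0, 0]) < 0.01
        assert abs(lab.b[0, 0]) < 0.01
        L_ref, _, _ = reference_rgb_to_lab([119, 119, 119])
        assert lab.L[0, 0] == pytest.approx(L_ref, abs=0.05)

    @pytest.mark.parametrize(
        "rgb", [(60, 110, 50), (130, 80, 45), (140, 110, 80), (10, 200, 240)]
    )
    def test_arbitrary_colors_match_independent_formulas(self, rgb):
        lab = vp.rgb_to_lab(np.array([[rgb]], dtype=np.uint8))
        L, a, b = reference_rgb_to_lab(rgb)
        assert lab.L[0, 0] == pytest.approx(L, abs=0.1)
        assert lab.a[0, 0] == pytest.approx(a, abs=0.1)
        assert lab.b[0, 0] == pytest.approx(b, abs=0.1)

    def test_spatial_shuffle_invariance(self, rng):
        img = rng.integers(0, 256, (10, 10, 3), dtype=np.uint8)
        lab = vp.rgb_to_lab(img).lab
        perm = rng.permutation(100)
        shuffled = img.reshape(100, 3)[perm].reshape(10, 10, 3)
        lab_shuffled = vp.rgb_to_lab(shuffled).lab
        np.testing.assert_allclose(
            lab.reshape(100, 3)[perm], lab_shuffled.reshape(100, 3), atol=1e-12
        )

    def test_lab_roundtrip_within_one_8bit_unit(self, rng):
        from skimage.color import lab2rgb

        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        lab = vp.rgb_to_lab(img)
        back = np.clip(np.round(lab2rgb(lab.lab) * 255.0), 0, 255)
        assert np.abs(back - img).max() <= 1.0

    def test_nodata_propagates(self, unit_grid, rng):
        data = rng.integers(0, 256, unit_grid.shape + (3,), dtype=np.uint8)
        valid = rng.random(unit_grid.shape) > 0.3
        lab = vp.rgb_to_lab(vp.GeoRaster(unit_grid, data, valid=valid))
        np.testing.assert_array_equal(lab.valid, valid)

    def test_single_band_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="RGB"):
            vp.rgb_to_lab(vp.GeoRaster(unit_grid, np.zeros(unit_grid.shape)))


class TestClusterAb:
    def _bicolor_patch(self, n_each=100):
        img = np.zeros((2, n_each, 3), dtype=np.uint8)
        img[0] = (60, 110, 50)
        img[1] = (140, 110, 80)
        return img

    def test_bicolor_patch_separates_perfectly(self):
        lab = vp.rgb_to_lab(self._bicolor_patch())
        model, assignment = vp.cluster_ab(lab, k=2, seed=0)
        assert len(np.unique(assignment[0])) == 1
        assert len(np.unique(assignment[1])) == 1
        assert assignment[0, 0] != assignment[1, 0]
        # centroids sit exactly on the two population (a, b) values
        ab0 = np.array([lab.a[0, 0], lab.b[0, 0]])
        ab1 = np.array([lab.a[1, 0], lab.b[1, 0]])
        got = model.centroids[np.argsort(model.centroids[:, 0])]
        want = np.array(sorted([list(ab0), list(ab1)]))
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_duplication_invariance(self):
        patch = self._bicolor_patch()
        lab1 = vp.rgb_to_lab(patch)
        lab2 = vp.rgb_to_lab(np.concatenate([patch, patch], axis=1))
        m1, _ = vp.cluster_ab(lab1, k=2, seed=0)
        m2, _ = vp.cluster_ab(lab2, k=2, seed=0)
        np.testing.assert_allclose(
            np.sort(m1.centroids, axis=0), np.sort(m2.centroids, axis=0), atol=1e-6
        )

    def test_assignments_are_nearest_centroid(self, rng):
        img = rng.integers(0, 256, (20, 10, 3), dtype=np.uint8)
        lab = vp.rgb_to_lab(img)
        model, assignment = vp.cluster_ab(lab, k=4, seed=1)
        ab = np.stack([lab.a, lab.b], axis=-1).reshape(-1, 2)
        np.testing.assert_array_equal(
            model.assign(ab), assignment.reshape(-1)
        )

    def test_objective_beats_random_assignments(self, rng):
        """k-means inertia must be no worse than 50 random partitions
        of the same pixels (brute-force comparison)."""
        img = rng.integers(0, 256, (10, 20, 3), dtype=np.uint8)
        lab = vp.rgb_to_lab(img)
        model, _ = vp.cluster_ab(lab, k=3, seed=0)
        ab = np.stack([lab.a, lab.b], axis=-1).reshape(-1, 2)
        for _ in range(50):
            labels = rng.integers(0, 3, len(ab))
            inertia = 0.0
            for c in range(3):
                members = ab[labels == c]
                if len(members):
                    inertia += ((members - members.mean(axis=0)) ** 2).sum()
            assert model.inertia <= inertia + 1e-9

    def test_k_bounds_enforced(self):
        lab = vp.rgb_to_lab(self._bicolor_patch())
        for bad_k in (1, 11):
            with pytest.raises(ValueError, match="k must be"):
                vp.cluster_ab(lab, k=bad_k)

    def test_too_few_distinct_chroma_values(self):
        img = np.full((5, 5, 3), 90, dtype=np.uint8)
        with pytest.raises(ValueError, match="distinct"):
            vp.cluster_ab(vp.rgb_to_lab(img), k=3)

    def test_deterministic_given_seed(self, rng):
        img = rng.integers(0, 256, (30, 30, 3), dtype=np.uint8)
        lab = vp.rgb_to_lab(img)
        m1, a1 = vp.cluster_ab(lab, k=5, seed=9)
        m2, a2 = vp.cluster_ab(lab, k=5, seed=9)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_allclose(m1.centroids, m2.centroids)


class TestTrainingSet:
    def _setup(self):
        assignment = np.array([0] * 60 + [1] * 40)
        rgb = np.zeros((100, 3), dtype=np.uint8)
        rgb[:60] = (130, 80, 45)
        rgb[60:] = (60, 110, 50)
        return assignment, rgb

    def test_fraction_of_positives_matches_cluster_split(self):
        assignment, rgb = self._setup()
        x, y = vp.make_training_set(
            assignment, {0: AFFECTED, 1: OTHER}, rgb
        )
        assert len(y) == 100
        assert y.sum() == 60

    def test_label_swap_complements_targets(self):
        assignment, rgb = self._setup()
        _, y1 = vp.make_training_set(assignment, {0: AFFECTED, 1: OTHER}, rgb)
        _, y2 = vp.make_training_set(assignment, {0: OTHER, 1: AFFECTED}, rgb)
        np.testing.assert_array_equal(y1, 1 - y2)

    def test_all_other_is_an_error(self):
        assignment, rgb = self._setup()
        with pytest.raises(ValueError, match="nothing to learn"):
            vp.make_training_set(assignment, {0: OTHER, 1: OTHER}, rgb)

    def test_uncovered_cluster_is_an_error(self):
        assignment, rgb = self._setup()
        with pytest.raises(ValueError, match="cover"):
            vp.make_training_set(assignment, {0: AFFECTED}, rgb)

    def test_reference_color_labeling_picks_the_right_cluster(self):
        assignment, rgb = self._setup()
        labeling = vp.label_clusters_by_reference(
            assignment, rgb, k=2, affected_rgb=(130, 80, 45)
        )
        assert labeling == {0: AFFECTED, 1: OTHER}
        means = cluster_mean_rgb(assignment, rgb, 2)
        np.testing.assert_allclose(means[0], (130, 80, 45))


class TestAnn:
    def _blobs(self, rng, n=500, d=60):
        brown = rng.normal((130, 80, 45), 8, (n, 3))
        green = rng.normal((60, 110, 50), 8, (n, 3))
        x = np.clip(np.vstack([brown, green]), 0, 255)
        y = np.concatenate([np.ones(n), np.zeros(n)]).astype(np.uint8)
        return x, y

    def test_separable_blobs_reach_99pct_training_accuracy(self, rng):
        x, y = self._blobs(rng)
        clf = vp.train_ann(x, y, vp.AnnConfig(seed=0))
        assert (clf.predict(x) == y).mean() >= 0.99

    def test_conflicting_labels_reduce_to_majority(self):
        x = np.full((100, 3), 90.0)
        y = np.array([1] * 70 + [0] * 30, dtype=np.uint8)
        clf = vp.train_ann(x, y, vp.AnnConfig(seed=0))
        acc = (clf.predict(x) == y).mean()
        assert acc == pytest.approx(0.7, abs=0.02)

    def test_single_class_is_an_error(self):
        x = np.zeros((10, 3))
        with pytest.raises(ValueError, match="both classes"):
            vp.train_ann(x, np.ones(10, dtype=np.uint8))

    def test_same_seed_identical_weights_and_predictions(self, rng):
        x, y = self._blobs(rng, n=200)
        c1 = vp.train_ann(x, y, vp.AnnConfig(seed=3))
        c2 = vp.train_ann(x, y, vp.AnnConfig(seed=3))
        for w1, w2 in zip(c1.mlp.coefs_, c2.mlp.coefs_):
            np.testing.assert_array_equal(w1, w2)
        probe = rng.uniform(0, 255, (50, 3))
        np.testing.assert_array_equal(c1.score(probe), c2.score(probe))

    def test_model_roundtrip_through_json(self, rng, tmp_path):
        x, y = self._blobs(rng, n=200)
        clf = vp.train_ann(x, y, vp.AnnConfig(seed=2))
        path = tmp_path / "model.json"
        vp.save_classifier(clf, path)
        back = vp.load_classifier(path)
        probe = rng.uniform(0, 255, (100, 3))
        np.testing.assert_allclose(back.score(probe), clf.score(probe), atol=1e-12)


class TestClassifyRaster:
    def _clf(self, rng):
        x = np.vstack(
            [
                rng.normal((130, 80, 45), 8, (300, 3)),
                rng.normal((60, 110, 50), 8, (300, 3)),
            ]
        )
        y = np.concatenate([np.ones(300), np.zeros(300)]).astype(np.uint8)
        return vp.train_ann(np.clip(x, 0, 255), y, vp.AnnConfig(seed=0))

    def test_all_nodata_in_all_nodata_out(self, unit_grid, rng):
        clf = self._clf(rng)
        ortho = vp.GeoRaster(
            unit_grid,
            np.zeros(unit_grid.shape + (3,), dtype=np.uint8),
            valid=np.zeros(unit_grid.shape, dtype=bool),
        )
        out = vp.classify_raster(ortho, clf)
        assert (out.data == MASK_NODATA).all()

    def test_training_positive_color_classifies_as_one(self, unit_grid, rng):
        clf = self._clf(rng)
        ortho = vp.GeoRaster(
            unit_grid,
            np.full(unit_grid.shape + (3,), (130, 80, 45), dtype=np.uint8),
        )
        out = vp.classify_raster(ortho, clf)
        assert (out.data == 1).all()

    def test_masking_commutes_with_classification(self, unit_grid, rng):
        """Classifying the vegetation-masked image equals masking the
        classified image: the classifier is strictly per-pixel."""
        clf = self._clf(rng)
        data = rng.integers(0, 256, unit_grid.shape + (3,), dtype=np.uint8)
        keep = rng.random(unit_grid.shape) > 0.5
        mask = vp.VegetationMask(
            vp.GeoRaster(unit_grid, keep.astype(np.uint8), nodata=255), 0.0
        )
        ortho = vp.GeoRaster(unit_grid, data)
        a = vp.classify_raster(vp.apply_mask(ortho, mask), clf)
        b = vp.classify_raster(ortho, clf)
        np.testing.assert_array_equal(a.data[keep], b.data[keep])
        assert (a.data[~keep] == MASK_NODATA).all()

    def test_classification_is_pointwise_under_cropping(self, unit_grid, rng):
        clf = self._clf(rng)
        data = rng.integers(0, 256, unit_grid.shape + (3,), dtype=np.uint8)
        full = vp.classify_raster(vp.GeoRaster(unit_grid, data), clf)
        sub_grid = vp.GridSpec(
            unit_grid.origin_x, unit_grid.origin_y, unit_grid.pixel_size, 16, 16
        )
        sub = vp.classify_raster(
            vp.GeoRaster(sub_grid, data[:16, :16]), clf
        )
        np.testing.assert_array_equal(sub.data, full.data[:16, :16])
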
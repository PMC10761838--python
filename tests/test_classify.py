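import numpy as np
import pytest

from specdiv import classify as clf
from specdiv import spectral as sp
from specdiv.synthgen import Crown, NONFOREST


def _crown(x_m=40.0, y_m=40.0, diameter_m=16.0, species=0, species_id="SP001"):
    return Crown(species, species_id, x_m, y_m, diameter_m, 10.0, 0.3)


class TestExtractTrainingSpectra:
    def test_pixel_count_matches_footprint(self):
        feats = np.random.default_rng(0).random((20, 20, 3))
        mask = np.ones((20, 20), bool)
        crown = _crown(40.0, 40.0, 12.0)
        rr, cc = clf.crown_footprint_pixels(crown, (20, 20))
        ts = clf.extract_training_spectra(feats, mask, [crown])
        assert len(ts.labels) == rr.size
        assert set(ts.labels) == {"SP001"}

    def test_masked_crown_skipped(self):
        feats = np.zeros((20, 20, 3))
        mask = np.zeros((20, 20), bool)
        mask[15:, 15:] = True
        with pytest.raises(ValueError):
            clf.extract_training_spectra(feats, mask, [_crown(20.0, 20.0, 10.0)])

    def test_mean_spectrum_matches_signature(self, landscape, scene):
        pool, _ = landscape
        cube = scene.cube
        bands = sp.select_classification_bands(sp.select_usable_bands(cube), cube)
        stack = np.moveaxis(cube.reflectance[bands.indices], 0, -1).astype(float)
        normed = sp.brightness_normalize(stack.reshape(-1, len(bands))).reshape(stack.shape)
        mask = sp.compute_ndvi_mask(cube, 0.4)
        ts = clf.extract_training_spectra(normed, mask, scene.crowns, truth_map=scene.truth_map)
        for sp_idx in scene.species_indices:
            sp_id = pool.species_ids[sp_idx]
            sel = ts.labels == sp_id
            if sel.sum() < 20:
                continue
            mean_spec = ts.samples[sel].mean(axis=0)
            sig = pool.signatures[sp_idx][bands.indices]
            sig = sig / np.linalg.norm(sig)
            cos = mean_spec @ sig / np.linalg.norm(mean_spec)
            assert cos > 0.99


class TestSplit:
    def _ts(self, n=100, d=4, label="A"):
        rng = np.random.default_rng(1)
        return clf.TrainingSet(
            samples=rng.random((n, d)),
            labels=np.full(n, label, dtype=object),
            crown_ids=np.arange(n),
        )

    def test_75_25_split(self):
        ts = clf.split_train_test(self._ts(100), 0.75, seed=0)
        assert (ts.split == "train").sum() == 75
        assert (ts.split == "test").sum() == 25

    def test_deterministic(self):
        a = clf.split_train_test(self._ts(), 0.75, seed=5)
        b = clf.split_train_test(self._ts(), 0.75, seed=5)
        np.testing.assert_array_equal(a.split, b.split)

    def test_partition_covers_all(self):
        ts = clf.split_train_test(self._ts(97), 0.75, seed=2)
        assert np.all((ts.split == "train") | (ts.split == "test"))

    def test_singleton_class_raises(self):
        ts = self._ts(1)
        with pytest.raises(ValueError, match="A"):
            clf.split_train_test(ts, 0.75, seed=0)


class TestSMOTE:
    def test_minority_oversampled_to_majority(self, rng):
        x = np.vstack([rng.random((100, 3)), rng.random((10, 3)) + 5])
        y = np.array(["A"] * 100 + ["B"] * 10)
        xb, yb = clf.smote_balance(x, y, seed=0)
        assert (yb == "A").sum() == (yb == "B").sum() == 100
        assert (xb[yb == "A"] == x[:100]).all()  # majority untouched

    def test_synthetic_on_segments_between_originals(self, rng):
        xo = rng.random((10, 2)) + 5
        x = np.vstack([rng.random((50, 2)), xo])
        y = np.array(["A"] * 50 + ["B"] * 10)
        xb, yb = clf.smote_balance(x, y, seed=1)
        synth = xb[len(x):][yb[len(x):] == "B"]
        for p in synth:
            dmin = np.inf
            for i in range(10):
                for j in range(10):
                    if i == j:
                        continue
                    a, b = xo[i], xo[j]
                    t = np.clip((p - a) @ (b - a) / ((b - a) @ (b - a)), 0, 1)
                    dmin = min(dmin, np.linalg.norm(a + t * (b - a) - p))
            assert dmin < 1e-9

    def test_no_new_labels(self, rng):
        x = np.vstack([rng.random((30, 2)), rng.random((5, 2))])
        y = np.array(["A"] * 30 + ["B"] * 5)
        _, yb = clf.smote_balance(x, y, seed=0)
        assert set(yb) == {"A", "B"}

    def test_balanced_input_unchanged(self, rng):
        x = rng.random((20, 2))
        y = np.array(["A"] * 10 + ["B"] * 10)
        xb, yb = clf.smote_balance(x, y, seed=0)
        np.testing.assert_array_equal(xb, x)
        np.testing.assert_array_equal(yb, y)


class TestRandomForest:
    def _separable(self, rng, n=60):
        x = np.vstack([rng.random((n, 2)) + off for off in (0, 10, 20)])
        y = np.repeat(["A", "B", "C"], n)
        return x, y

    def test_separable_toy_zero_oob_error(self, rng):
        x, y = self._separable(rng)
        forest = clf.train_rf(x, y, ntree_grid=[100], seed=0)
        assert forest.oob_error == 0.0

    def test_seeded_determinism(self, rng):
        x, y = self._separable(rng)
        a = clf.train_rf(x, y, ntree_grid=[50], seed=3)
        b = clf.train_rf(x, y, ntree_grid=[50], seed=3)
        assert (a.mtry, a.ntree) == (b.mtry, b.ntree)
        grid = rng.random((30, 2)) * 25
        np.testing.assert_array_equal(a.predict(grid), b.predict(grid))

    def test_empty_grid_raises(self, rng):
        x, y = self._separable(rng)
        with pytest.raises(ValueError):
            clf.train_rf(x, y, mtry_grid=[], ntree_grid=[100])

    def test_subsample_per_class_caps(self, rng):
        x = rng.random((120, 2))
        y = np.array(["A"] * 100 + ["B"] * 20)
        xs, ys = clf.subsample_per_class(x, y, 50, seed=0)
        assert (ys == "A").sum() == 50 and (ys == "B").sum() == 20


class TestPredictMap:
    def _forest(self, rng):
        x = np.vstack([rng.random((50, 2)), rng.random((50, 2)) + 10])
        y = np.repeat(["A", "B"], 50)
        return clf.train_rf(x, y, ntree_grid=[50], seed=0)

    def test_fully_masked_map_empty(self, rng):
        forest = self._forest(rng)
        cmap = clf.predict_map(forest, np.zeros((5, 5, 2)), np.zeros((5, 5), bool))
        assert (cmap.labels == NONFOREST).all()

    def test_feature_dim_mismatch_raises(self, rng):
        forest = self._forest(rng)
        with pytest.raises(ValueError):
            clf.predict_map(forest, np.zeros((5, 5, 3)), np.ones((5, 5), bool))

    def test_single_class_dominates_pure_scene(self, rng):
        forest = self._forest(rng)
        feats = rng.random((10, 10, 2))  # all near class A's cloud
        cmap = clf.predict_map(forest, feats, np.ones((10, 10), bool))
        labels = [cmap.legend[c] for c in cmap.labels[cmap.mask]]
        assert labels.count("A") >= 0.99 * len(labels)

    def test_area_histogram_16m2_per_pixel(self, rng):
        forest = self._forest(rng)
        feats = np.zeros((10, 10, 2))
        feats[:, 5:, :] = 10.5
        cmap = clf.predict_map(forest, feats, np.ones((10, 10), bool))
        area = cmap.area_km2()
        np.testing.assert_allclose(area.sum(), 100 * 16 / 1e6)


class TestAccuracy:
    def test_perfect_agreement(self):
        rep = clf.assess_accuracy(np.repeat([0, 1], 50), np.repeat([0, 1], 50))
        assert rep.overall_accuracy == 100.0
        assert rep.kappa == 1.0

    def test_hand_confusion_40_10(self):
        ref = np.repeat([0, 1], 50)
        pred = np.concatenate([[0] * 40 + [1] * 10, [0] * 10 + [1] * 40])
        rep = clf.assess_accuracy(ref, pred)
        np.testing.assert_allclose(rep.overall_accuracy, 80.0)
        np.testing.assert_allclose(rep.kappa, 0.6)
        np.testing.assert_allclose(rep.producers_accuracy.to_numpy(), [80.0, 80.0])
        np.testing.assert_allclose(rep.users_accuracy.to_numpy(), [80.0, 80.0])

    def test_one_sided_predictions_chance_kappa(self):
        ref = np.repeat([0, 1], 50)
        rep = clf.assess_accuracy(ref, np.zeros(100, dtype=int))
        np.testing.assert_allclose(rep.kappa, 0.0, atol=1e-12)

    def test_scalars_recomputable_from_matrix(self, rng):
        ref = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        rep = clf.assess_accuracy(ref, pred)
        rep2 = clf.ConfusionReport.from_matrix(rep.matrix)
        assert rep2.overall_accuracy == rep.overall_accuracy
        assert rep2.kappa == rep.kappa

    def test_matrix_marginals(self, rng):
        ref = rng.integers(0, 3, 90)
        pred = rng.integers(0, 3, 90)
        rep = clf.assess_accuracy(ref, pred)
        assert rep.matrix.to_numpy().sum() == 90
        for c in rep.matrix.index:
            assert rep.matrix.loc[c].sum() == (ref == c).sum()
            assert rep.matrix[c].sum() == (pred == c).sum()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            clf.assess_accuracy(np.array([]), np.array([]))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            clf.assess_accuracy(np.array([1]), np.array([1, 2]))
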
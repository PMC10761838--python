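import numpy as np
import pytest
from scipy.stats import spearmanr

from specdiv import synthgen as sg
from specdiv.spectral import SpectralCube


class TestSpeciesPool:
    def test_pa_specific_count_emulates_target(self):
        pool = sg.generate_species_pool(53, 4, 0.51, seed=7)
        assert pool.n_pa_specific() == 27

    def test_single_ubiquitous_species(self):
        pool = sg.generate_species_pool(1, 1, 0.0, seed=123)
        assert pool.n_species == 1
        assert pool.n_pa_specific() == 0
        assert pool.membership.all()

    def test_seeded_determinism(self):
        a = sg.generate_species_pool(20, 4, 0.5, seed=1)
        b = sg.generate_species_pool(20, 4, 0.5, seed=1)
        np.testing.assert_array_equal(a.membership, b.membership)
        np.testing.assert_array_equal(a.signatures, b.signatures)
        np.testing.assert_array_equal(a.niche_coefficients, b.niche_coefficients)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sg.generate_species_pool(0, 1, 0.5, seed=0)
        with pytest.raises(ValueError):
            sg.generate_species_pool(3, 4, 0.5, seed=0)
        with pytest.raises(ValueError):
            sg.generate_species_pool(10, 2, 1.2, seed=0)

    def test_every_species_in_at_least_one_pa(self):
        pool = sg.generate_species_pool(30, 4, 0.6, seed=3)
        assert (pool.membership.sum(axis=1) >= 1).all()

    def test_signatures_in_unit_interval_on_cube_grid(self):
        pool = sg.generate_species_pool(8, 2, 0.25, seed=9)
        assert pool.signatures.shape == (8, len(pool.wavelengths))
        assert pool.signatures.min() >= 0 and pool.signatures.max() <= 1

    def test_evergreen_niche_positive_on_rainfall(self):
        pool = sg.generate_species_pool(40, 4, 0.3, seed=5)
        ever = pool.phenology == 1
        assert (pool.niche_coefficients[ever, 0] > 0).all()
        assert (pool.niche_coefficients[~ever, 0] < 0).all()

    def test_dbh_samples_within_bounds(self, rng):
        pool = sg.generate_species_pool(5, 1, 0.0, seed=2)
        d = pool.sample_dbh(0, 1000, rng)
        assert d.min() >= 0.02 and d.max() <= sg.DBH_MAX_M


class TestClimateGrids:
    def test_rainfall_means_strictly_increasing(self):
        grids = sg.generate_climate_grids(4, seed=0)
        means = grids.pa_rainfall_means()
        assert np.all(np.diff(means) > 0)

    def test_zero_noise_equals_pa_means(self):
        grids = sg.generate_climate_grids(4, noise_sd=0.0, seed=0)
        for name in sg.CLIMATE_COVARIATES:
            g = grids.covariates[name]
            for p in range(4):
                vals = g[grids.pa_index == p]
                assert np.allclose(vals, vals[0])

    def test_seeded_determinism(self):
        a = sg.generate_climate_grids(4, seed=11)
        b = sg.generate_climate_grids(4, seed=11)
        for name in sg.CLIMATE_COVARIATES:
            np.testing.assert_array_equal(a.covariates[name], b.covariates[name])

    def test_degenerate_extent_raises(self):
        with pytest.raises(ValueError):
            sg.generate_climate_grids(4, cells_per_pa=(0, 3))

    def test_soil_binary(self):
        grids = sg.generate_climate_grids(4, seed=0)
        assert set(np.unique(grids.soil)) <= {0, 1}

    def test_rasters_share_extent(self):
        grids = sg.generate_climate_grids(3, cells_per_pa=(2, 5), seed=0)
        shp = grids.elevation.shape
        assert all(g.shape == shp for g in grids.covariates.values())
        assert grids.soil.shape == shp == grids.pa_index.shape


class TestScene:
    def test_noise_free_single_species_exact_signature(self):
        pool = sg.generate_species_pool(1, 1, 0.0, seed=1)
        grids = sg.generate_climate_grids(1, cells_per_pa=(1, 1), seed=1)
        scene = sg.generate_scene(
            pool, grids, 0, size=(64, 64), noise_sd=0.0, brightness_range=(1.0, 1.0), seed=1
        )
        forest = scene.truth_map == 0
        assert forest.any()
        spectra = np.moveaxis(scene.cube.reflectance, 0, -1)[forest]
        assert np.max(np.abs(spectra - pool.signatures[0])) < 1e-6

    def test_truth_map_determinism(self, landscape):
        pool, grids = landscape
        a = sg.generate_scene(pool, grids, 1, size=(128, 128), seed=77)
        b = sg.generate_scene(pool, grids, 1, size=(128, 128), seed=77)
        np.testing.assert_array_equal(a.truth_map, b.truth_map)

    def test_crown_frequencies_track_niche_model(self, scene):
        realized = np.bincount(
            [c.species for c in scene.crowns], minlength=int(scene.species_indices.max()) + 1
        )[scene.species_indices]
        expected = scene.expected_species_frequencies()
        rho = spearmanr(realized, expected).statistic
        assert rho >= 0.8

    def test_truth_labels_subset_of_local_species(self, scene):
        labels = np.unique(scene.truth_map)
        labels = labels[labels != sg.NONFOREST]
        assert set(labels) <= set(scene.species_indices)

    def test_reflectance_in_unit_interval(self, scene):
        assert scene.cube.reflectance.min() >= 0.0
        assert scene.cube.reflectance.max() <= 1.0

    def test_scene_smaller_than_crown_raises(self, landscape):
        pool, grids = landscape
        with pytest.raises(ValueError):
            sg.generate_scene(pool, grids, 0, size=(1, 1), seed=0)

    def test_evergreen_share_increases_with_rainfall(self):
        pool = sg.generate_species_pool(16, 4, 0.25, seed=21)
        grids = sg.generate_climate_grids(4, cells_per_pa=(2, 2), seed=22)
        shares = []
        for p in range(4):
            sc = sg.generate_scene(pool, grids, p, size=(96, 96), seed=23 + p)
            sp_ids = np.array([c.species for c in sc.crowns])
            shares.append(pool.phenology[sp_ids].mean())
        slope = np.polyfit(grids.pa_rainfall_means(), shares, 1)[0]
        assert slope > 0

    def test_disc_rasterization_area(self):
        arr = np.full((100, 100), sg.NONFOREST, dtype=np.int32)
        n = sg._paint_disc(arr, 200.0, 200.0, 40.0, np.int32(1))
        expected_px = np.pi * (40.0 / sg.PIXEL_SIZE_M) ** 2
        assert abs(n - expected_px) < 4 * np.pi * (40.0 / sg.PIXEL_SIZE_M)  # boundary band
        assert (arr == 1).sum() == n


class TestFieldSurvey:
    def test_records_match_registry(self, scene, survey):
        # every quadrat's records equal the registry crowns inside its
        # footprint with DBH above the recording limit
        for q in survey.quadrats:
            half = q.size_m / 2
            expected = [
                c for c in scene.crowns
                if (q.center_x_m - half <= c.x_m < q.center_x_m + half)
                and (q.center_y_m - half <= c.y_m < q.center_y_m + half)
                and c.dbh_m > sg.DBH_MIN_M
            ]
            assert len(q.records) == len(expected)

    def test_small_dbh_excluded(self, scene):
        # saplings (DBH 0.035 m) blanket the scene; recordable trees are
        # sparser, so quadrats hit both kinds
        crowns = []
        for x in range(10, 990, 5):
            for y in range(10, 990, 5):
                dbh = 0.5 if (x + y) % 20 == 0 else 0.035
                crowns.append(sg.Crown(0, "SP001", float(x), float(y), 6.0, 10.0, dbh_m=dbh))
        sc = sg.SyntheticScene(
            cube=scene.cube,
            truth_map=scene.truth_map,
            crowns=crowns,
            pa=scene.pa,
            pa_id=scene.pa_id,
            species_indices=scene.species_indices,
            cell_origin=scene.cell_origin,
            cell_species_probs=scene.cell_species_probs,
        )
        sv = sg.generate_field_survey(sc, 30, seed=0)
        records = [r for q in sv.quadrats for r in q.records]
        assert records, "expected some recordable trees"
        assert all(r.dbh_m > sg.DBH_MIN_M for r in records)
        # saplings outnumber recordable trees 3:1 in the scene but never appear
        assert all(r.dbh_m == 0.5 for r in records)

    def test_determinism(self, scene):
        a = sg.generate_field_survey(scene, 10, seed=9)
        b = sg.generate_field_survey(scene, 10, seed=9)
        assert [(q.center_x_m, q.center_y_m) for q in a.quadrats] == [
            (q.center_x_m, q.center_y_m) for q in b.quadrats
        ]
        assert [len(q.records) for q in a.quadrats] == [len(q.records) for q in b.quadrats]

    def test_invalid_count_raises(self, scene):
        with pytest.raises(ValueError):
            sg.generate_field_survey(scene, 0, seed=0)


def test_cube_type_invariants(scene):
    cube = scene.cube
    assert isinstance(cube, SpectralCube)
    assert cube.n_bands == len(cube.wavelengths)
    assert not np.isnan(cube.reflectance).any()
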
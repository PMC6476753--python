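import numpy as np
import pytest

from landres import (ConfigurationError, GenerationError, SyntheticConfig,
                     bray_curtis_matrix, distance_matrix, generate_elevation,
                     generate_landuse, generate_world, mantel_test,
                     place_individuals, read_ascii_grid, read_genepop,
                     write_bundle)
from landres.genotypes import attach_locations, read_locations_csv
from landres.rasters import LANDUSE_CODES
from landres.synthetic import (DEFAULT_LANDUSE_PROPORTIONS,
                               dissimilarity_response)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        props = dict(DEFAULT_LANDUSE_PROPORTIONS)
        props["forest"] += 0.05
        with pytest.raises(ConfigurationError, match="sum to 1"):
            SyntheticConfig(landuse_proportions=props)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(grid_rows=1)

    def test_negative_beta_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(beta=-1)

    def test_default_proportions_emulate_skewed_shares(self):
        assert DEFAULT_LANDUSE_PROPORTIONS["forest"] == pytest.approx(0.646, abs=5e-3)
        assert sum(DEFAULT_LANDUSE_PROPORTIONS.values()) == pytest.approx(1.0, abs=1e-12)


class TestElevation:
    def test_zero_amplitude_gives_constant_raster(self):
        cfg = SyntheticConfig(grid_rows=10, grid_cols=10, hill_amplitude=0.0,
                              elevation_noise_sd=0.0, seed=1)
        elev = generate_elevation(cfg)
        np.testing.assert_allclose(elev.values, cfg.elevation_base)

    def test_determinism(self):
        cfg = SyntheticConfig(seed=5)
        np.testing.assert_array_equal(generate_elevation(cfg).values,
                                      generate_elevation(cfg).values)

    def test_bounds_from_generator_formula(self):
        cfg = SyntheticConfig(grid_rows=50, grid_cols=50, seed=3)
        elev = generate_elevation(cfg)
        assert (elev.values >= cfg.elevation_base).all()
        assert (elev.values <= cfg.elevation_base
                + cfg.n_hills * cfg.hill_amplitude).all()
        assert (elev.values > 0).all()


class TestLanduse:
    def test_degenerate_all_forest(self):
        props = {k: 0.0 for k in DEFAULT_LANDUSE_PROPORTIONS}
        props["forest"] = 1.0
        cfg = SyntheticConfig(landuse_proportions=props, seed=2)
        lu = generate_landuse(cfg)
        assert (lu.values == LANDUSE_CODES["forest"]).all()

    def test_realized_fractions_track_requested(self):
        cfg = SyntheticConfig(grid_rows=60, grid_cols=60, seed=4)
        lu = generate_landuse(cfg)
        codes, counts = np.unique(lu.values, return_counts=True)
        realized = dict(zip(codes, counts / counts.sum()))
        for name, wanted in DEFAULT_LANDUSE_PROPORTIONS.items():
            got = realized.get(LANDUSE_CODES[name], 0.0)
            assert abs(got - wanted) <= 0.03, name

    def test_determinism(self):
        cfg = SyntheticConfig(seed=6)
        np.testing.assert_array_equal(generate_landuse(cfg).values,
                                      generate_landuse(cfg).values)

    def test_spatial_aggregation(self):
        # patches, not salt-and-pepper: most rook neighbours share a class
        cfg = SyntheticConfig(grid_rows=40, grid_cols=40, seed=8)
        v = generate_landuse(cfg).values
        same = (v[:, 1:] == v[:, :-1]).mean()
        assert same > 0.8


class TestPlacement:
    def test_all_placements_in_habitat(self):
        cfg = SyntheticConfig(grid_rows=30, grid_cols=30, n_individuals=40,
                              seed=9)
        lu = generate_landuse(cfg)
        table = place_individuals(cfg, lu)
        habitat = {LANDUSE_CODES[c] for c in cfg.habitat_classes}
        for loc in table.location:
            assert int(lu.values[loc]) in habitat

    def test_pigeonhole_error(self):
        props = {k: 0.0 for k in DEFAULT_LANDUSE_PROPORTIONS}
        props["forest"] = 1.0
        cfg = SyntheticConfig(grid_rows=2, grid_cols=2, n_individuals=5,
                              landuse_proportions=props, distinct_cells=True,
                              seed=1)
        with pytest.raises(GenerationError, match="habitat cells"):
            place_individuals(cfg, generate_landuse(cfg))

    def test_sex_ratio_zero_gives_single_sex(self):
        cfg = SyntheticConfig(grid_rows=20, grid_cols=20, n_individuals=15,
                              sex_ratio=0.0, seed=2)
        table = place_individuals(cfg, generate_landuse(cfg))
        assert set(table.sex) == {"F"}


class TestGenotypeSimulation:
    def test_full_chain_determinism(self, small_world_config):
        _, _, t1, _ = generate_world(small_world_config)
        _, _, t2, _ = generate_world(small_world_config)
        np.testing.assert_array_equal(t1.calls, t2.calls)
        assert t1.sex == t2.sex and t1.location == t2.location

    def test_perfect_correlation_limit(self):
        # everyone in the same cell with zero latent noise: the latent field
        # is perfectly shared, so all individuals are identical at every
        # locus and all pairwise Bray-Curtis distances are 0
        props = {k: 0.0 for k in DEFAULT_LANDUSE_PROPORTIONS}
        props["forest"] = 1.0
        cfg = SyntheticConfig(grid_rows=2, grid_cols=2, n_individuals=6,
                              n_loci=4, noise_sd=0.0, distinct_cells=False,
                              landuse_proportions=props, seed=11)
        # force colocation by providing a single habitat cell
        lu = generate_landuse(cfg)
        table = place_individuals(cfg, lu)
        table.location = [(0, 0)] * cfg.n_individuals
        from landres import build_network, simulate_genotypes, generate_elevation
        locs = {ind: (0, 0) for ind in table.ids}
        net = build_network(locs, generate_elevation(cfg), lu)
        full = simulate_genotypes(cfg, table, net)
        assert (full.calls == full.calls[0]).all()
        np.testing.assert_allclose(bray_curtis_matrix(full).values, 0.0)

    def test_infinite_noise_limit_decouples_from_space(self):
        cfg = SyntheticConfig(grid_rows=30, grid_cols=30, n_individuals=40,
                              n_loci=10, noise_sd=40.0, seed=12)
        _, _, table, net = generate_world(cfg)
        res = mantel_test(bray_curtis_matrix(table), distance_matrix(net),
                          n_perm=199, seed=1)
        assert abs(res.r) < 0.1

    def test_ibd_contract_at_beta_zero(self):
        # pure isolation-by-distance worlds: genetic distance correlates
        # with Euclidean distance in (at least) 4 of 5 small replicates
        hits = 0
        for seed in range(5):
            cfg = SyntheticConfig(grid_rows=25, grid_cols=25,
                                  n_individuals=30, n_loci=8, seed=seed)
            _, _, table, net = generate_world(cfg)
            res = mantel_test(bray_curtis_matrix(table), distance_matrix(net),
                              n_perm=199, seed=seed)
            hits += res.p <= 0.05
        assert hits >= 4

    def test_response_curve_is_monotone(self):
        rho, phi = dissimilarity_response(8)
        assert phi[0] > phi[-1]
        assert (np.diff(phi) <= 1e-3).all()  # decreasing up to MC noise


class TestBundleIO:
    def test_bundle_round_trip(self, tmp_path, small_world_config):
        paths = write_bundle(small_world_config, tmp_path)
        table = read_genepop(paths["genotypes"])
        table = attach_locations(table, read_locations_csv(paths["locations"]))
        elev = read_ascii_grid(paths["elevation"], kind="elevation")
        lu = read_ascii_grid(paths["landuse"], kind="landuse")
        assert table.n == small_world_config.n_individuals
        assert elev.shape == lu.shape == (25, 25)
        _, _, direct, _ = generate_world(small_world_config)
        np.testing.assert_array_equal(np.sort(table.calls, axis=2),
                                      np.sort(direct.calls, axis=2))
        assert table.sex == direct.sex and table.location == direct.location
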
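"""Ground-truth structure of the synthetic world generator."""

import numpy as np
import pandas as pd
import pytest

from betabreak import (
    MountainBlock,
    WorldConfig,
    aggregate_environment,
    build_regions,
    generate_climate_fields,
    generate_species_ranges,
    generate_world,
    multisite_beta,
    pairwise_beta,
)


def noiseless(**kw):
    kw.setdefault("t_noise_sd", 0.0)
    kw.setdefault("pet_noise_sd", 0.0)
    kw.setdefault("prec_noise_sd", 0.0)
    kw.setdefault("t_dif_noise_sd", 0.0)
    kw.setdefault("elev_noise_sd", 0.0)
    kw.setdefault("mountain_blocks", [])
    return WorldConfig(**kw)


class TestClimateFields:
    def test_tdif_lies_exactly_on_joined_segments(self):
        # glacial-minus-present difference: slopes 0.09 equatorward of the
        # breakpoint, 0.24 poleward, joined at 37
        cfg = noiseless(seed=0)
        env = generate_climate_fields(cfg).set_index(["lat", "lon"])
        tdif = env["t_pres"] - env["t_past"]

        def expected(abs_lat):
            return 2.0 + 0.09 * min(abs_lat, 37) + 0.24 * max(abs_lat - 37, 0)

        for lat in (35, 36, 37, 38):
            got = tdif.loc[(lat, 0)]
            assert got == pytest.approx(expected(lat + 0.5), abs=1e-12)

    def test_all_zero_slopes_give_constant_fields(self):
        cfg = noiseless(
            t_pres_slope=0.0, pet_slope=0.0, prec_slope=0.0,
            t_dif_slope_below=0.0, t_dif_slope_above=0.0, seed=1,
        )
        env = generate_climate_fields(cfg)
        for col in ("t_pres", "t_past", "pet", "prec", "elev"):
            assert env[col].nunique() == 1

    def test_bitwise_determinism(self):
        cfg = WorldConfig(seed=11)
        a = generate_climate_fields(cfg)
        b = generate_climate_fields(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_noise_not_trend(self):
        cfg_a = noiseless(seed=1)
        cfg_b = noiseless(seed=2)
        pd.testing.assert_frame_equal(
            generate_climate_fields(cfg_a), generate_climate_fields(cfg_b)
        )

    def test_glaciation_flag_polewards_only(self):
        env = generate_climate_fields(WorldConfig(seed=0, glaciation_lat=50.0))
        abs_lat = (env["lat"] + 0.5).abs()
        assert (env.loc[abs_lat >= 50, "glaciated"]).all()
        assert (~env.loc[abs_lat < 50, "glaciated"]).all()

    def test_mountain_blocks_inflate_regional_relief(self):
        cfg = noiseless(
            mountain_blocks=[MountainBlock(10, 12, 0, 20, elev_sd=800.0)], seed=3
        )
        env = generate_climate_fields(cfg)
        asg = build_regions(
            cfg.lat_min, cfg.lat_max, cfg.lon_min, cfg.lon_max, band_height_deg=1
        )
        region_env = aggregate_environment(asg, env)
        inside = region_env[
            (region_env["centroid_abs_lat"].between(10, 12))
            & (region_env.index.map(
                lambda r: asg.region_table.loc[r, "centroid_lon"] < 20
            ))
        ]
        outside = region_env[region_env["centroid_abs_lat"] > 20]
        assert inside["a_range"].max() > 100.0
        assert outside["a_range"].max() == pytest.approx(0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="glaciation_lat"):
            WorldConfig(glaciation_lat=80.0, lat_max=62)
        with pytest.raises(ValueError, match="non-finite"):
            WorldConfig(t_pres_slope=float("nan"))
        with pytest.raises(ValueError, match="extent"):
            WorldConfig(lat_min=10, lat_max=10)
        with pytest.raises(ValueError, match="breakpoint"):
            WorldConfig(breakpoint_lat=80, lat_max=62)


class TestSpeciesRanges:
    def test_turnover_world_replaces_species_between_tiles(self):
        # entirely equatorward of the breakpoint: 2x2 tiles, no sharing
        cfg = noiseless(
            lat_min=0, lat_max=10, lon_min=0, lon_max=8, breakpoint_lat=10,
            glaciation_lat=10.0, n_species=40, nested_pool_size=0, seed=4,
        )
        grid = generate_species_ranges(cfg)
        idx = grid.cell_index()
        a = grid.presence[idx[(0, 0)]]
        b = grid.presence[idx[(0, 2)]]  # adjacent tile
        same = grid.presence[idx[(1, 1)]]  # same tile as (0, 0)
        assert pairwise_beta(a, b).beta_sim == 1.0
        assert np.array_equal(a, same)

    def test_pure_nested_world_has_zero_turnover(self):
        # entirely poleward: single-prefix pool, sharp switch -> every range
        # is a poleward truncation of the largest one
        cfg = noiseless(
            lat_min=40, lat_max=50, lon_min=0, lon_max=10, breakpoint_lat=39,
            n_species=20, nested_pool_size=10, nested_prefix_classes=1,
            transition_deg=0.0, seed=5,
        )
        grid = generate_species_ranges(cfg)
        rng = np.random.default_rng(0)
        for _ in range(10):
            rows = rng.choice(grid.n_cells, size=6, replace=False)
            mat = grid.presence[rows]
            mat = mat[mat.any(axis=1)]
            if mat.shape[0] >= 2:
                assert multisite_beta(mat).beta_sim == 0.0

    def test_single_species_world(self):
        cfg = noiseless(
            lat_min=0, lat_max=2, lon_min=0, lon_max=2, breakpoint_lat=2,
            glaciation_lat=2.0, n_species=1, nested_pool_size=0, seed=0,
        )
        grid = generate_species_ranges(cfg)
        assert grid.n_species == 1
        occupied = grid.presence[:, 0] == 1
        mat = grid.presence[occupied]
        assert multisite_beta(mat).beta_sor == 0.0

    def test_determinism_and_seed_sensitivity(self):
        cfg = WorldConfig(seed=7)
        a = generate_species_ranges(cfg)
        b = generate_species_ranges(cfg)
        assert np.array_equal(a.presence, b.presence)
        assert a.species == b.species
        c = generate_species_ranges(WorldConfig(seed=8))
        assert not np.array_equal(a.presence, c.presence)

    def test_group_labels_cover_configured_names(self):
        grid = generate_species_ranges(WorldConfig(seed=0))
        assert set(grid.groups) == {"anura", "caudata", "gymnophiona"}


class TestWorldBundle:
    def test_invariants_and_roundtrip(self, tmp_path):
        from betabreak.io import (
            read_env_table,
            read_occurrence_table,
            write_env_table,
            write_occurrence_table,
        )

        bundle = generate_world(WorldConfig(seed=9))
        occ, env = bundle.occurrence, bundle.cell_env
        assert set(np.unique(occ.presence)) <= {0, 1}
        env_cells = set(zip(env["lat"], env["lon"]))
        occupied = occ.cells[occ.presence.any(axis=1)]
        assert set(map(tuple, occupied)) <= env_cells

        write_occurrence_table(occ, tmp_path / "occ.csv")
        write_env_table(env, tmp_path / "env.csv")
        occ2 = read_occurrence_table(tmp_path / "occ.csv")
        env2 = read_env_table(tmp_path / "env.csv")
        assert sorted(occ2.species) == sorted(occ.species)
        # same presences cell-by-cell (reader drops never-occupied cells)
        idx2 = occ2.cell_index()
        sp2 = {s: j for j, s in enumerate(occ2.species)}
        idx1 = occ.cell_index()
        for cell, i2 in idx2.items():
            row1 = occ.presence[idx1[cell]]
            present1 = {occ.species[j] for j in np.flatnonzero(row1)}
            present2 = {occ2.species[j] for j in np.flatnonzero(occ2.presence[i2])}
            assert present1 == present2
        pd.testing.assert_frame_equal(
            env.reset_index(drop=True), env2.reset_index(drop=True), check_dtype=False
        )
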
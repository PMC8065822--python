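"""Synthetic-data generator: determinism, construction constraints, and
recoverability of the planted structure."""

import numpy as np
import pytest

from endemap.association import BIOCLIM_NAMES
from endemap.geo import project
from endemap.io import clean_occurrences
from endemap.simulate import (
    Assemblage,
    SimulationConfig,
    make_associated_points,
    make_climate,
    make_endemic_assemblage,
    make_landscape,
)


def small_config(**kw):
    defaults = dict(extent_km=(1000.0, 800.0), n_patches=8, n_plant_points=150,
                    n_insect_points=60, climate_cell_km=25.0, seed=11,
                    endemic_assemblages=[Assemblage(3, (200.0, 400.0), 20.0, 8),
                                         Assemblage(3, (800.0, 400.0), 20.0, 8)])
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestMakeLandscape:
    def test_single_patch_is_extent(self):
        layer = make_landscape(small_config(n_patches=1))
        from endemap.geo import unproject

        lon_max, lat_max = unproject(np.array([1000.0]), np.array([800.0]))
        assert layer.patches[0][2].bounds == pytest.approx((0, 0, lon_max[0], lat_max[0]))

    def test_partition_property(self):
        cfg = small_config()
        layer = make_landscape(cfg)
        from shapely.ops import unary_union

        union = unary_union([g for _, _, g in layer.patches])
        total = sum(g.area for _, _, g in layer.patches)
        # patches are disjoint and cover the frame: union area == sum of areas
        assert total == pytest.approx(union.area, rel=1e-6)
        from endemap.geo import unproject
        from shapely.geometry import box

        lon_max, lat_max = unproject(np.array([1000.0]), np.array([800.0]))
        assert union.area == pytest.approx(box(0, 0, lon_max[0], lat_max[0]).area, rel=1e-6)

    def test_determinism_and_seed_sensitivity(self):
        a = make_landscape(small_config(seed=3))
        b = make_landscape(small_config(seed=3))
        c = make_landscape(small_config(seed=4))
        assert all(g1.equals(g2) for (_, _, g1), (_, _, g2) in zip(a.patches, b.patches))
        assert not all(g1.equals(g2) for (_, _, g1), (_, _, g2) in zip(a.patches, c.patches))

    def test_compatible_with_occupancy(self):
        from endemap.specificity import build_occupancy

        cfg = small_config()
        layer = make_landscape(cfg)
        plants, insects = make_associated_points(cfg)
        occ, unassigned, _ = build_occupancy(insects, layer)
        # the mosaic tiles the frame, so (almost) every point lands in a patch
        assert unassigned == 0
        assert len(occ.species_ids) == 5


class TestMakeClimate:
    def test_zero_noise_exact_plane(self):
        layers = make_climate(small_config(climate_noise=0.0))
        r = layers["BIO12"]
        X, Y = r.spec.cell_centres()
        A = np.column_stack([X.ravel(), Y.ravel(), np.ones(X.size)])
        coef, res, *_ = np.linalg.lstsq(A, r.values.ravel(), rcond=None)
        fitted = A @ coef
        ss_res = ((r.values.ravel() - fitted) ** 2).sum()
        ss_tot = ((r.values.ravel() - r.values.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_per_seed(self):
        a = make_climate(small_config(seed=5))
        b = make_climate(small_config(seed=5))
        for name in BIOCLIM_NAMES:
            assert np.array_equal(a[name].values, b[name].values)

    def test_max_temp_dominates_min_everywhere(self):
        layers = make_climate(small_config(climate_noise=2.0))
        assert (layers["BIO5"].values >= layers["BIO6"].values).all()

    def test_all_nineteen_present(self):
        layers = make_climate(small_config())
        assert set(layers) == set(BIOCLIM_NAMES)


class TestMakeAssociatedPoints:
    def test_full_tether_zero_sd_coincides(self):
        cfg = small_config(association_rho=1.0, tether_sd_km=0.0)
        plants, insects = make_associated_points(cfg)
        pk = {(r.location.lon, r.location.lat) for r in plants.records}
        assert all((r.location.lon, r.location.lat) in pk for r in insects.records)

    def test_rho_zero_matches_uniform_nearest_distance(self):
        """With no tethering, the mean insect-to-nearest-plant distance
        matches a direct uniform simulation within Monte-Carlo error."""
        from scipy.spatial import cKDTree

        obs, sim = [], []
        master = np.random.default_rng(404)
        for seed in range(20):
            cfg = small_config(association_rho=0.0, seed=seed)
            plants, insects = make_associated_points(cfg)

            def km(table):
                lon = np.array([r.location.lon for r in table.records])
                lat = np.array([r.location.lat for r in table.records])
                return np.column_stack(project(lon, lat))

            pk, ik = km(plants), km(insects)
            obs.append(cKDTree(pk).query(ik)[0].mean())
            uniform = master.uniform((0, 0), cfg.extent_km, size=(len(ik), 2))
            sim.append(cKDTree(pk).query(uniform)[0].mean())
        assert np.mean(obs) == pytest.approx(np.mean(sim), rel=0.1)

    def test_species_labels_round_robin(self):
        cfg = small_config()
        plants, insects = make_associated_points(cfg)
        assert len(plants.species_set()) == cfg.n_plant_species
        assert len(insects.species_set()) == cfg.n_insect_species

    def test_tables_pass_cleaning_with_zero_drops(self):
        cfg = small_config()
        for t in (*make_associated_points(cfg), make_endemic_assemblage(cfg)):
            _, report = clean_occurrences(t)
            assert report.n_retained == report.n_input


class TestMakeEndemicAssemblage:
    def test_zero_spread_all_points_at_centre(self):
        from endemap.gie import ranges_from_table

        cfg = small_config(endemic_assemblages=[Assemblage(2, (300.0, 300.0), 0.0, 5)])
        table = make_endemic_assemblage(cfg)
        for rng_ in ranges_from_table(table):
            assert rng_.radius_km == pytest.approx(0.0, abs=1e-9)

    def test_radii_bounded_by_twice_spread(self):
        from endemap.gie import classify_ranges, ranges_from_table

        cfg = small_config()
        ranges = ranges_from_table(make_endemic_assemblage(cfg))
        assert all(r.radius_km <= 2 * 20.0 for r in ranges)
        out = classify_ranges(ranges)
        assert len(out[1]) == 6  # every planted species is a class-1 endemic

    def test_two_distant_assemblages_give_two_areas(self):
        from endemap.geo import make_grid
        from endemap.gie import (
            DEFAULT_CLASSES,
            areas_of_endemism,
            classify_ranges,
            gie_surface,
            ranges_from_table,
        )

        cfg = small_config(
            extent_km=(2400.0, 800.0),
            endemic_assemblages=[Assemblage(3, (200.0, 400.0), 20.0, 8),
                                 Assemblage(3, (2200.0, 400.0), 20.0, 8)],
        )
        ranges = ranges_from_table(make_endemic_assemblage(cfg))
        assigned = classify_ranges(ranges)
        grid = make_grid((0, 0, 2400.0, 800.0), 25.0)
        surf = gie_surface(assigned[1], grid, DEFAULT_CLASSES[0])
        out = areas_of_endemism(surf, 2)
        assert len(out.areas) == 2
        species = sorted(tuple(a.species) for a in out.areas)
        assert species[0] == tuple(f"endemic_a1_sp{k}" for k in (1, 2, 3))
        assert species[1] == tuple(f"endemic_a2_sp{k}" for k in (1, 2, 3))
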
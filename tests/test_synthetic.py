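"""Synthetic orchard generator: layout, yields, rasters, point clouds."""

import math

import numpy as np
import pytest

from orchardmetrics.synthetic import (
    CANOPY_REFLECTANCE,
    SOIL_REFLECTANCE,
    OrchardLayout,
    assign_yields,
    density_for_gsd,
    generate_layout,
    render_bands,
    render_cloud,
    simulate_scene,
    yield_signal,
)


class TestLayout:
    def test_reference_field_has_160_trees(self):
        trees = generate_layout(OrchardLayout(), seed=1)
        assert len(trees) == 160
        per_row = [sum(1 for t in trees if t.row_index == i) for i in range(5)]
        assert per_row == [30, 31, 32, 33, 34]

    def test_zero_dead_fraction_means_all_live(self, small_layout):
        trees = generate_layout(small_layout, seed=5)
        assert not any(t.is_dead for t in trees)

    def test_same_seed_reproduces_tree_list(self, small_layout):
        a = generate_layout(small_layout, seed=9)
        b = generate_layout(small_layout, seed=9)
        assert a == b

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_rows=0, trees_per_row=()), "n_rows"),
            (dict(trees_per_row=(5, 5)), "trees_per_row"),
            (dict(row_spacing=0.0), "row_spacing"),
            (dict(dead_fraction=1.0), "dead_fraction"),
            (dict(field_length=50.0), "field_length"),
        ],
    )
    def test_invalid_layout_names_offending_field(self, kwargs, msg):
        base = dict(n_rows=5, trees_per_row=(30, 31, 32, 33, 34))
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            OrchardLayout(**base)

    def test_dead_trees_are_small_and_yieldless(self):
        layout = OrchardLayout(dead_fraction=0.5)
        trees = generate_layout(layout, seed=2)
        dead = [t for t in trees if t.is_dead]
        assert dead, "expected some dead trees at fraction 0.5"
        assert all(t.yield_kg == 0.0 for t in dead)
        assert all(t.canopy_radius <= 0.35 for t in dead)


class TestYields:
    def test_zero_noise_reproduces_signal_exactly(self, small_layout):
        trees = generate_layout(small_layout, seed=4)
        out = assign_yields(trees, noise_sd=0.0, seed=4)
        for t in out:
            assert t.yield_kg == pytest.approx(max(yield_signal(t), 0.0))

    def test_calibrated_noise_hits_target_r2(self):
        """Default calibration puts the sample R^2 between noise-free
        signal and realized yield within +/-0.03 of 0.90 at n=160."""
        trees = generate_layout(OrchardLayout(dead_fraction=0.0), seed=11)
        out = assign_yields(trees, noise_sd=None, seed=11)
        sig = np.array([yield_signal(t) for t in out])
        y = np.array([t.yield_kg for t in out])
        ss_res = np.sum((y - sig) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(0.90, abs=0.03)

    def test_mean_yield_near_80_kg(self):
        trees = generate_layout(OrchardLayout(dead_fraction=0.0), seed=13)
        y = [t.yield_kg for t in trees]
        assert np.mean(y) == pytest.approx(80.0, abs=10.0)

    def test_negative_noise_sd_rejected(self, small_layout):
        trees = generate_layout(small_layout, seed=1)
        with pytest.raises(ValueError):
            assign_yields(trees, noise_sd=-1.0, seed=1)


class TestBands:
    def test_reference_raster_dimensions(self):
        """140 m x 25 m at 2.13 cm/px -> ceil(14000/2.13) x ceil(2500/2.13)."""
        bands = render_bands([], OrchardLayout(), gsd=2.13, noise_sd_reflectance=0.0, seed=0)
        assert bands.shape == (math.ceil(2500 / 2.13), math.ceil(14000 / 2.13))
        assert bands.shape == (1174, 6573)

    def test_no_trees_no_noise_gives_flat_soil(self, small_layout):
        bands = render_bands([], small_layout, gsd=5.0, noise_sd_reflectance=0.0, seed=0)
        for name, val in SOIL_REFLECTANCE.items():
            arr = getattr(bands, name)
            assert np.all(arr == pytest.approx(val, abs=1e-6))

    def test_ng_brighter_over_soil_than_canopy(self, small_scene):
        """Soil NG ~ 0.257 vs canopy NG ~ 0.141 with default reflectances;
        after 0-255 scaling the separation exceeds 5 gray levels."""
        from orchardmetrics.indices import compute_index

        img = compute_index(small_scene.bands, "NG")
        gsd_m = small_scene.bands.gsd_m
        m, n = img.gray.shape
        xs = (np.arange(n) + 0.5) * gsd_m
        ys = small_scene.layout.field_width - (np.arange(m) + 0.5) * gsd_m
        canopy = np.zeros((m, n), dtype=bool)
        for t in small_scene.trees:
            cx, cy = t.center_xy
            d2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
            canopy |= d2 < (0.8 * t.canopy_radius) ** 2
        soil_mean = img.gray[~canopy].mean()
        canopy_mean = img.gray[canopy].mean()
        assert soil_mean > canopy_mean
        assert soil_mean - canopy_mean >= 5.0

    def test_oversized_raster_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            render_bands([], OrchardLayout(), gsd=0.01, seed=0)


class TestCloud:
    def test_density_table_reproduced_and_interpolation_monotone(self):
        assert density_for_gsd(2.13) == pytest.approx(364.77)
        assert density_for_gsd(6.69) == pytest.approx(8.65)
        gsds = np.linspace(2.13, 6.69, 40)
        dens = [density_for_gsd(g) for g in gsds]
        assert np.all(np.diff(dens) < 0)

    def test_canopy_point_count_tracks_density(self, small_layout):
        """Realized canopy points per m^3 within 10% of the mapped density
        for canopies of at least 2 m^3."""
        trees = [t for t in generate_layout(small_layout, seed=21)
                 if t.ellipsoid_volume >= 2.0]
        cloud = render_cloud(trees, small_layout, gsd=2.13, xyz_noise_sd=0.0,
                             seed=21, ground_density=0.0)
        total_volume = sum(t.ellipsoid_volume for t in trees)
        realized = len(cloud) / total_volume
        assert realized == pytest.approx(364.77, rel=0.10)

    def test_dead_tree_gets_only_trunk_points(self, small_layout):
        trees = generate_layout(small_layout, seed=2)
        dead = trees[0].__class__(**{**trees[0].__dict__, "is_dead": True,
                                     "canopy_radius": 0.2})
        cloud = render_cloud([dead], small_layout, gsd=2.13, xyz_noise_sd=0.0,
                             seed=2, ground_density=0.0)
        assert len(cloud) == 5
        assert cloud.points[:, 2].max() <= dead.trunk_height + 1e-9

    def test_noise_free_vertical_extent_matches_truth(self, small_layout):
        """Without jitter or ground returns a single tree's z-range equals
        the canopy depth H - trunk, up to the apex/base sampling gap."""
        t = generate_layout(small_layout, seed=5)[0]
        cloud = render_cloud([t], small_layout, gsd=2.13, xyz_noise_sd=0.0,
                             seed=5, ground_density=0.0, density=5000.0)
        z = cloud.points[:, 2]
        depth = t.canopy_height_total - t.trunk_height
        assert z.max() - z.min() <= depth + 1e-9
        assert z.max() - z.min() == pytest.approx(depth, abs=0.08)

    def test_cloud_inside_raster_extent(self, small_scene):
        ext_x, ext_y = small_scene.bands.extent_xy
        pts = small_scene.cloud.points
        assert pts[:, 0].min() >= 0 and pts[:, 0].max() <= ext_x
        assert pts[:, 1].min() >= 0 and pts[:, 1].max() <= ext_y

    def test_negative_noise_rejected(self, small_layout):
        with pytest.raises(ValueError):
            render_cloud([], small_layout, gsd=2.13, xyz_noise_sd=-0.1, seed=0)


def test_scene_regeneration_is_byte_identical(small_layout):
    a = simulate_scene(small_layout, gsd=4.39, seed=17)
    b = simulate_scene(small_layout, gsd=4.39, seed=17)
    assert a.trees == b.trees
    np.testing.assert_array_equal(a.cloud.points, b.cloud.points)
    for band in ("gre", "red", "reg", "nir"):
        np.testing.assert_array_equal(getattr(a.bands, band), getattr(b.bands, band))
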
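"""RCGP projection profiles, smoothing, boundary detection, 2D<->3D."""

import numpy as np
import pytest

from orchardmetrics.segmentation import (
    GridSegmentation,
    convert_to_3d,
    detect_boundaries,
    project_profile,
    score_detection,
    score_row_bands,
    segment_scene,
    smooth_profile,
)
from orchardmetrics.indices import compute_index
from orchardmetrics.pipeline import segment_bundle

from oracles import brute_force_gaussian_smooth, containment_score_oracle


class TestProjection:
    def test_row_and_column_hand_sums(self):
        gray = np.array([[1, 2], [3, 4]])
        assert project_profile(gray, "row").raw.tolist() == [3, 7]
        assert project_profile(gray, "column").raw.tolist() == [4, 6]

    def test_all_zero_image(self):
        assert np.all(project_profile(np.zeros((4, 5)), "row").raw == 0)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            project_profile(np.empty((0, 0)), "row")

    def test_bad_axis_rejected(self):
        with pytest.raises(ValueError):
            project_profile(np.ones((2, 2)), "diagonal")


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        prof = project_profile(np.full((10, 20), 3), "row")
        sm = smooth_profile(prof, h=2.5)
        np.testing.assert_allclose(sm.smoothed, prof.raw, rtol=1e-12)

    def test_matches_brute_force_convolution(self, rng):
        prof = project_profile(rng.integers(0, 255, (1, 300)).astype(np.int64), "column")
        for h in (1.0, 3.5, 12.0):
            sm = smooth_profile(prof, h)
            np.testing.assert_allclose(
                sm.smoothed, brute_force_gaussian_smooth(prof.raw, h), atol=1e-9
            )

    def test_total_mass_preserved(self, rng):
        prof = project_profile(rng.integers(0, 255, (1, 500)).astype(np.int64), "column")
        sm = smooth_profile(prof, h=25.0)
        assert sm.smoothed.sum() == pytest.approx(prof.raw.sum(), rel=1e-9)

    def test_nonpositive_bandwidth_rejected(self):
        prof = project_profile(np.ones((2, 2)), "row")
        with pytest.raises(ValueError):
            smooth_profile(prof, 0.0)


class TestBoundaries:
    def test_monotone_profile_returns_edges_only(self):
        prof = project_profile(np.ones((1, 100)) * np.arange(100), "column")
        prof = smooth_profile(prof, 2.0)
        bounds = detect_boundaries(prof, expected_spacing_px=20)
        assert bounds.tolist() == [0, 100]

    def test_two_gaussian_bumps_found_at_apexes(self):
        x = np.arange(400, dtype=float)
        raw = np.exp(-0.5 * ((x - 100) / 15) ** 2) + np.exp(-0.5 * ((x - 300) / 15) ** 2)
        prof = project_profile(raw[None] * 1000, "column")
        prof = smooth_profile(prof, 3.0)
        bounds = detect_boundaries(prof, expected_spacing_px=200,
                                   subdivide_wide_cells=False)
        interior = bounds[1:-1]
        assert len(interior) == 2
        assert abs(interior[0] - 100) <= 1 and abs(interior[1] - 300) <= 1

    def test_wide_cell_subdivision_inserts_grid_boundaries(self):
        """A gap of two planting intervals between detected peaks gets one
        inserted boundary at the midpoint."""
        x = np.arange(500, dtype=float)
        raw = np.exp(-0.5 * ((x - 100) / 10) ** 2) + np.exp(-0.5 * ((x - 300) / 10) ** 2)
        prof = smooth_profile(project_profile(raw[None] * 1000, "column"), 3.0)
        bounds = detect_boundaries(prof, expected_spacing_px=100)
        assert 200 in bounds.tolist()

    def test_requires_smoothed_profile(self):
        prof = project_profile(np.ones((2, 3)), "row")
        with pytest.raises(ValueError, match="smoothed"):
            detect_boundaries(prof)

    def test_scale_equivariance(self, small_scene):
        """Multiplying image intensities by a positive constant leaves the
        detected boundaries unchanged (projection and prominence are
        relative)."""
        img = compute_index(small_scene.bands, "NG")
        gray = img.gray.astype(np.int64)
        results = []
        for scale in (1, 7):
            prof = smooth_profile(project_profile(gray * scale, "row"), 20.0)
            rng_ = float(prof.smoothed.max() - prof.smoothed.min())
            results.append(detect_boundaries(prof, min_prominence=0.02 * rng_,
                                             expected_spacing_px=151).tolist())
        assert results[0] == results[1]


class TestConversion:
    def make_seg(self, L, C, m2=1000, n2=2000, m3=25.0, n3=140.0):
        return GridSegmentation(L_2D=np.asarray(L), C_2D=[np.asarray(c) for c in C],
                                m_2D=m2, n_2D=n2, m_3D=m3, n_3D=n3)

    def test_proportional_scaling(self):
        seg = convert_to_3d(self.make_seg([0, 500, 1000], [[0, 1000, 2000]] * 2))
        assert seg.L_3D.tolist() == [0.0, 12.5, 25.0]
        assert seg.C_3D[0].tolist() == [0.0, 70.0, 140.0]

    def test_origin_fixed_point(self):
        seg = convert_to_3d(self.make_seg([0, 10], [[0, 5]]))
        assert seg.L_3D[0] == 0.0 and seg.C_3D[0][0] == 0.0

    def test_round_trip_within_one_pixel(self, rng):
        """3D -> 2D -> 3D reproduces boundaries to within one pixel's
        metre size."""
        m2, m3 = 1174, 25.0
        y3 = np.sort(rng.uniform(0, m3, 20))
        y2 = np.round(y3 * m2 / m3)
        back = y2 * m3 / m2
        assert np.max(np.abs(back - y3)) <= m3 / m2

    def test_zero_dimension_rejected(self):
        seg = self.make_seg([0, 10], [[0, 5]], m2=0)
        with pytest.raises(ValueError):
            convert_to_3d(seg)


class TestSceneSegmentation:
    def test_small_scene_perfectly_gridded(self, small_scene):
        """3 rows x 8 trees, no dead trees: 24 regions, each containing
        exactly one truth centre."""
        seg, regions = segment_bundle(small_scene)
        assert len(regions) == 24
        score = score_detection(regions, small_scene.trees)
        assert score.NC == 24 and score.NE == 0 and score.C == 100.0
        assert score_row_bands(seg, small_scene.trees).C == 100.0

    def test_cell_point_counts_partition_cloud(self, small_scene):
        _, regions = segment_bundle(small_scene)
        total = sum(r.P for r in regions)
        pts = small_scene.cloud.points
        ext_x, ext_y = small_scene.bands.extent_xy
        in_extent = np.sum(
            (pts[:, 0] >= 0) & (pts[:, 0] < ext_x)
            & (pts[:, 1] > 0) & (pts[:, 1] <= ext_y)
        )
        assert total == in_extent

    def test_extent_mismatch_rejected(self, small_scene):
        img = compute_index(small_scene.bands, "NG")
        with pytest.raises(ValueError, match="extent"):
            segment_scene(img, small_scene.cloud, extent_xy=(20.0, 8.0))


class TestScoring:
    def test_counts_to_percentages(self):
        from orchardmetrics.segmentation import DetectionScore

        s = DetectionScore(NC=8, NE=2, N=10)
        assert s.C == 80.0 and s.E == 20.0
        s = DetectionScore(NC=10, NE=0, N=10)
        assert s.C == 100.0 and s.E == 0.0

    def test_matches_containment_oracle(self, rng):
        """Scored C and E equal exhaustive center-in-cell counting on
        randomly perturbed grids."""
        from orchardmetrics.segmentation import TreeRegion
        from orchardmetrics.synthetic import TreeTruth

        for _ in range(10):
            edges_x = np.sort(rng.uniform(0, 100, 8))
            centers = [(rng.uniform(0, 100), rng.uniform(0, 10)) for _ in range(12)]
            windows = [(edges_x[i], edges_x[i + 1], 0.0, 10.0) for i in range(7)]
            regions = [
                TreeRegion(row_index=0, col_index=i, pixel_window=None,
                           metre_window=w, points=np.empty((0, 3)), P=0)
                for i, w in enumerate(windows)
            ]
            trees = [TreeTruth(row_index=0, col_index=i, center_xy=c)
                     for i, c in enumerate(centers)]
            got = score_detection(regions, trees)
            want_c, want_e = containment_score_oracle(windows, centers)
            assert got.C == pytest.approx(want_c)
            assert got.E == pytest.approx(want_e)
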
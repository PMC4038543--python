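import numpy as np
import pytest

import glandnet as gn
from glandnet._haralick import STAT_NAMES
from glandnet.imaging_io import LuminanceImage
from glandnet.qh_comparators import (FAMILY_LENGTHS, MORPH_DESCRIPTORS,
                                     disorder, gland_descriptors, glcm,
                                     voronoi_polygons)
from glandnet.segmentation import GlandSegment, boundary_polygon
from glandnet.synthetic import ellipse_mask_points

from _oracles import (oracle_delaunay_triangles, oracle_density,
                      oracle_haralick, oracle_prim_mst_weight,
                      oracle_voronoi_cells)
from glandnet._haralick import haralick_stats


def segment_from_pixels(px, gid=0):
    arr = np.array(sorted(px), dtype=float)
    return GlandSegment(gland_id=gid, boundary=boundary_polygon(px),
                        pixel_set=px,
                        centroid=(arr[:, 1].mean(), arr[:, 0].mean()),
                        boundary_strength=1.0, seed=(0, 0), scale_px=1.0)


def disk_segment(center_rc, radius, gid=0):
    rr, cc = ellipse_mask_points((center_rc[1], center_rc[0]),
                                 (radius, radius), 0.0, (400, 400))
    return segment_from_pixels(set(zip(rr.tolist(), cc.tolist())), gid)


class TestMorphology:
    def test_identical_circles_have_no_spread(self):
        glands = [disk_segment((50 + 80 * i, 60), 12, i) for i in range(3)]
        vec = gn.morphology_features(glands)
        assert len(vec.values) == 100
        for name in MORPH_DESCRIPTORS:
            assert vec.values[f"morph_{name}_std"] == pytest.approx(0.0, abs=1e-9)
            lo_hi = vec.values[f"morph_{name}_minmax_ratio"]
            assert lo_hi == pytest.approx(1.0, abs=1e-6)

    def test_single_gland_degenerate_aggregates(self):
        g = disk_segment((60, 60), 15)
        vec = gn.morphology_features([g])
        d = gland_descriptors(g)
        for name in MORPH_DESCRIPTORS:
            assert vec.values[f"morph_{name}_mean"] == pytest.approx(d[name])
            assert vec.values[f"morph_{name}_median"] == pytest.approx(d[name])
            assert vec.values[f"morph_{name}_std"] == 0.0

    def test_empty_gland_list_rejected(self):
        with pytest.raises(ValueError):
            gn.morphology_features([])

    def test_hu_moments_match_raw_moment_oracle(self):
        rng = np.random.default_rng(20)
        for trial in range(10):
            theta = float(rng.uniform(0, 180))
            a = float(rng.uniform(10, 25))
            b = float(rng.uniform(5, a))
            rr, cc = ellipse_mask_points((80, 80), (a, b), theta, (160, 160))
            px = set(zip(rr.tolist(), cc.tolist()))
            got = gland_descriptors(segment_from_pixels(px))
            want = _hu_oracle(px)
            for k in range(7):
                assert got[f"hu_moment_{k + 1}"] == pytest.approx(
                    want[k], rel=1e-9, abs=1e-12)


def _hu_oracle(px):
    """Hu's invariant moments from raw coordinate sums over the pixel set."""
    pts = np.array(sorted(px), dtype=float)  # (row, col) == (y, x)
    x = pts[:, 1]
    y = pts[:, 0]
    m00 = len(pts)
    xbar, ybar = x.mean(), y.mean()

    def mu(p, q):
        return ((x - xbar) ** p * (y - ybar) ** q).sum()

    def eta(p, q):
        return mu(p, q) / m00 ** (1 + (p + q) / 2)

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03 = eta(3, 0), eta(0, 3)
    n21, n12 = eta(2, 1), eta(1, 2)
    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11 ** 2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = ((n30 - 3 * n12) * (n30 + n12)
          * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
          + (3 * n21 - n03) * (n21 + n03)
          * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    h6 = ((n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
          + 4 * n11 * (n30 + n12) * (n21 + n03))
    h7 = ((3 * n21 - n03) * (n30 + n12)
          * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
          - (n30 - 3 * n12) * (n21 + n03)
          * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    return [h1, h2, h3, h4, h5, h6, h7]


class TestVoronoi:
    def test_square_lattice_congruent_cells(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        vec = gn.voronoi_features(pts)
        assert len(vec.values) == 12
        for qty in ("area", "perimeter", "chord"):
            assert vec.values[f"voronoi_{qty}_std"] == pytest.approx(0.0, abs=1e-9)
            assert vec.values[f"voronoi_{qty}_minmax_ratio"] == pytest.approx(1.0)
            assert vec.values[f"voronoi_{qty}_disorder"] == pytest.approx(0.0, abs=1e-9)

    def test_disorder_definition_and_range(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            v = rng.uniform(0.1, 10, rng.integers(2, 30))
            d = disorder(v)
            assert 0.0 <= d < 1.0
            assert d == pytest.approx(1 - 1 / (1 + v.std() / v.mean()))

    def test_cells_partition_bounding_box(self):
        rng = np.random.default_rng(22)
        pts = rng.uniform(0, 200, (30, 2))
        polys = voronoi_polygons(pts)
        span = pts.max(axis=0) - pts.min(axis=0)
        assert sum(p.area for p in polys) == pytest.approx(
            span[0] * span[1], abs=1e-6)

    def test_matches_halfplane_oracle(self):
        rng = np.random.default_rng(23)
        for trial in range(5):
            pts = rng.uniform(0, 100, (8, 2))
            window = (*pts.min(axis=0), *pts.max(axis=0))
            cells = oracle_voronoi_cells(pts, window)
            got = sorted(p.area for p in voronoi_polygons(pts))
            want = sorted(c.area for c in cells if not c.is_empty)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gn.voronoi_features(np.array([[0, 0], [1, 1], [2, 0]], float))


class TestDelaunay:
    def test_equilateral_lattice_uniform_sides(self):
        # skewed (parallelogram) lattice: every Delaunay triangle equilateral
        pts = []
        for i in range(4):
            for j in range(4):
                pts.append([j + 0.5 * i, i * np.sqrt(3) / 2])
        vec = gn.delaunay_features(np.array(pts))
        assert len(vec.values) == 8
        assert vec.values["delaunay_side_std"] == pytest.approx(0.0, abs=1e-9)
        assert vec.values["delaunay_side_minmax_ratio"] == pytest.approx(1.0)

    def test_three_points_single_triangle(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        vec = gn.delaunay_features(pts)
        assert vec.values["delaunay_area_mean"] == pytest.approx(6.0)
        assert vec.values["delaunay_area_std"] == 0.0

    def test_triangles_partition_convex_hull(self):
        rng = np.random.default_rng(24)
        pts = rng.uniform(0, 100, (25, 2))
        vec = gn.delaunay_features(pts)
        from scipy.spatial import ConvexHull, Delaunay
        n_tri = len(Delaunay(pts).simplices)
        total = vec.values["delaunay_area_mean"] * n_tri
        assert total == pytest.approx(ConvexHull(pts).volume, abs=1e-6)

    def test_matches_empty_circumcircle_oracle(self):
        rng = np.random.default_rng(25)
        for trial in range(5):
            pts = rng.uniform(0, 100, (12, 2))
            from scipy.spatial import Delaunay
            got = {tuple(sorted(s)) for s in Delaunay(pts).simplices}
            assert got == oracle_delaunay_triangles(pts)

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError):
            gn.delaunay_features(pts)


class TestMST:
    def test_collinear_equal_spacing(self):
        pts = np.column_stack([np.arange(6) * 5.0, np.zeros(6)])
        vec = gn.mst_features(pts)
        assert len(vec.values) == 4
        assert vec.values["mst_edge_mean"] == pytest.approx(5.0)
        assert vec.values["mst_edge_std"] == pytest.approx(0.0, abs=1e-12)
        assert vec.values["mst_edge_minmax_ratio"] == pytest.approx(1.0)

    def test_two_points_single_edge(self):
        vec = gn.mst_features(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert vec.values["mst_edge_mean"] == pytest.approx(5.0)

    def test_total_weight_matches_prim_oracle(self):
        rng = np.random.default_rng(26)
        for trial in range(5):
            pts = rng.uniform(0, 200, (20, 2))
            from glandnet.qh_comparators import mst_edge_lengths
            total = mst_edge_lengths(pts).sum()
            assert total == pytest.approx(oracle_prim_mst_weight(pts),
                                          rel=1e-9)


class TestDensity:
    def test_isolated_glands_zero_counts(self):
        pts = np.column_stack([np.arange(8) * 500.0, np.zeros(8)])
        vec = gn.density_features(pts)
        assert len(vec.values) == 24
        for r in (10, 20, 30, 40, 50):
            assert vec.values[f"density_count_r{r}_mean"] == 0.0

    def test_lattice_interior_counts(self):
        pts = np.array([[i * 10.0, j * 10.0]
                        for i in range(5) for j in range(5)])
        counts, _ = oracle_density(pts, [10.0], [3])
        # interior nodes see exactly their 4 axial neighbours at <= 10 px
        assert max(counts[10.0]) == 4

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(27)
        pts = rng.uniform(0, 150, (40, 2))
        vec = gn.density_features(pts)
        counts, knn = oracle_density(pts, [10.0, 20.0, 30.0, 40.0, 50.0],
                                     [3, 5, 7])
        for r in (10, 20, 30, 40, 50):
            v = np.asarray(counts[float(r)], dtype=float)
            assert vec.values[f"density_count_r{r}_mean"] == pytest.approx(v.mean())
            assert vec.values[f"density_count_r{r}_std"] == pytest.approx(v.std())
            assert vec.values[f"density_count_r{r}_disorder"] == pytest.approx(
                disorder(v))
        for k in (3, 5, 7):
            v = np.asarray(knn[k])
            assert vec.values[f"density_nn{k}_dist_mean"] == pytest.approx(v.mean())

    def test_too_few_centroids_rejected(self):
        with pytest.raises(ValueError):
            gn.density_features(np.zeros((5, 2)))


class TestTexture:
    def test_constant_image_degenerate(self):
        lum = LuminanceImage(values=np.full((20, 20), 50.0))
        vec = gn.intensity_texture_features(lum, np.ones((20, 20), bool))
        assert len(vec.values) == 26
        assert vec.values["texture_entropy_mean"] == pytest.approx(0.0)
        assert vec.values["texture_energy_mean"] == pytest.approx(1.0)
        for name in STAT_NAMES:
            assert vec.values[f"texture_{name}_std"] == pytest.approx(0.0)

    def test_stripes_maximal_contrast_across(self):
        values = np.zeros((16, 16))
        values[:, 1::2] = 100.0  # single-pixel vertical stripes
        levels_mask = np.ones((16, 16), bool)
        lum_levels = np.clip(np.round(values / 100 * 255), 0, 255).astype(np.uint8)
        across = haralick_stats(glcm(lum_levels, levels_mask, (0, 1)))
        along = haralick_stats(glcm(lum_levels, levels_mask, (1, 0)))
        assert across["contrast_average"] == pytest.approx(255.0)
        assert along["contrast_average"] == pytest.approx(0.0)

    def test_matches_summation_oracle_per_offset(self):
        rng = np.random.default_rng(28)
        values = rng.uniform(0, 100, (16, 16))
        mask = rng.random((16, 16)) > 0.2
        levels = np.clip(np.round(values / 100 * 255), 0, 255).astype(np.uint8)
        for off in ((0, 1), (1, 0), (1, 1), (1, -1)):
            counts = glcm(levels, mask, off)
            # oracle co-occurrence by explicit pair loops
            want = np.zeros((256, 256), dtype=int)
            H, W = levels.shape
            for r in range(H):
                for c in range(W):
                    r2, c2 = r + off[0], c + off[1]
                    if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                        want[levels[r, c], levels[r2, c2]] += 1
                        want[levels[r2, c2], levels[r, c]] += 1
            np.testing.assert_array_equal(counts, want)
            got = haralick_stats(counts)
            ref = oracle_haralick(counts)
            for name in STAT_NAMES:
                assert got[name] == pytest.approx(ref[name], rel=1e-9,
                                                 abs=1e-12), name

    def test_empty_mask_rejected(self):
        lum = LuminanceImage(values=np.zeros((8, 8)))
        with pytest.raises(ValueError):
            gn.intensity_texture_features(lum, np.zeros((8, 8), bool))


def test_family_lengths_on_phantom():
    spec = gn.PhantomSpec(image_size_px=(384, 384), n_glands=10,
                          min_spacing_px=70, seed=2)
    img, _ = gn.generate_phantom(spec)
    glands = gn.segment_glands(img)
    from glandnet.pipeline import comparator_features
    feats = comparator_features(img, glands)
    assert len(feats) == sum(FAMILY_LENGTHS.values())


def test_graph_families_rigid_motion_invariant():
    rng = np.random.default_rng(29)
    pts = rng.uniform(0, 200, (15, 2))
    th = 1.1
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = pts @ R.T + np.array([31.0, -7.0])
    for fn in (gn.delaunay_features, gn.mst_features, gn.density_features):
        v1, v2 = fn(pts), fn(moved)
        for name in v1.values:
            assert v1.values[name] == pytest.approx(v2.values[name],
                                                    rel=1e-9, abs=1e-9), name
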
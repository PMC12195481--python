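import math

import numpy as np
import pytest

from smqc.errors import (
    ConfigError,
    EmptyRegionError,
    GeometryError,
    UndefinedCorrelationError,
)
from smqc.peaktable import PeakTable
from smqc.regions import (
    Region,
    RegionSpectrum,
    background_consistency,
    cluster_background_spectra,
    load_regions,
    region_from_polygon,
    region_spectrum,
)


def grid_table(w, h, n_ions=1, seed=0):
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    return PeakTable(coords, 100.0 + np.arange(n_ions), rng.random((w * h, n_ions)))


def brute_force_even_odd(vertices, x, y):
    """Independent even-odd ray-casting point-in-polygon test (boundary counts)."""
    n = len(vertices)
    # on-edge check
    for k in range(n):
        (x1, y1), (x2, y2) = vertices[k], vertices[(k + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
    inside = False
    for k in range(n):
        (x1, y1), (x2, y2) = vertices[k], vertices[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


class TestPolygon:
    def test_square_is_boundary_inclusive(self):
        pt = grid_table(11, 11)
        sq = [(0, 0), (10, 0), (10, 10), (0, 10)]
        reg = region_from_polygon(sq, "t", "tissue", pt)
        assert len(reg.pixels) == 121

    def test_polygon_outside_grid_raises(self):
        pt = grid_table(5, 5)
        with pytest.raises(EmptyRegionError):
            region_from_polygon([(100, 100), (110, 100), (105, 110)], "t", "tissue", pt)

    def test_self_intersecting_polygon_rejected(self):
        pt = grid_table(5, 5)
        bowtie = [(0, 0), (4, 4), (4, 0), (0, 4)]
        with pytest.raises(GeometryError):
            region_from_polygon(bowtie, "t", "tissue", pt)

    def test_l_shape_matches_even_odd_oracle(self):
        pt = grid_table(20, 20)
        ell = [(2, 2), (15, 2), (15, 8), (8, 8), (8, 17), (2, 17)]
        reg = region_from_polygon(ell, "t", "tissue", pt)
        oracle = {
            (x, y)
            for x in range(20)
            for y in range(20)
            if brute_force_even_odd(ell, x, y)
        }
        assert reg.pixels == oracle

    def test_concave_random_polygons_match_oracle(self):
        pt = grid_table(15, 15)
        rng = np.random.default_rng(5)
        for _ in range(5):
            # star-shaped (hence simple) polygon around the grid center
            angles = np.sort(rng.uniform(0, 2 * math.pi, 7))
            radii = rng.uniform(2, 7, 7)
            verts = [(7 + r * math.cos(a), 7 + r * math.sin(a))
                     for a, r in zip(angles, radii)]
            reg = region_from_polygon(verts, "t", "tissue", pt)
            oracle = {
                (x, y)
                for x in range(15)
                for y in range(15)
                if brute_force_even_odd(verts, x, y)
            }
            assert reg.pixels == oracle


class TestRegionSpectrum:
    def test_single_pixel_region_is_that_row(self):
        pt = grid_table(3, 3, n_ions=4, seed=1)
        reg = Region("r", "tissue", frozenset({(1, 1)}))
        sp = region_spectrum(pt, reg)
        row = pt.pixel_index()[(1, 1)]
        np.testing.assert_array_equal(sp.values, pt.intensity[row])

    def test_odd_median(self):
        pt = PeakTable(
            np.array([[0, 0], [1, 0], [2, 0]]), np.array([100.0]),
            np.array([[1.0], [2.0], [10.0]]),
        )
        sp = region_spectrum(pt, Region("r", "tissue", frozenset({(0, 0), (1, 0), (2, 0)})))
        assert sp.values[0] == 2.0

    def test_even_median_is_mean_of_central_pair(self):
        pt = PeakTable(
            np.array([[0, 0], [1, 0], [2, 0], [3, 0]]), np.array([100.0]),
            np.array([[1.0], [1.0], [1.0], [9.0]]),
        )
        reg = Region("r", "tissue", frozenset(map(tuple, pt.coords)))
        assert region_spectrum(pt, reg).values[0] == 1.0

    def test_matches_sort_based_oracle_and_pixel_order_invariant(self, rng):
        pt = grid_table(4, 4, n_ions=5, seed=2)
        pix = [(0, 0), (1, 2), (3, 3), (2, 1), (0, 3), (3, 0), (2, 2)]
        sp = region_spectrum(pt, Region("r", "tissue", frozenset(pix)))
        idx = [pt.pixel_index()[p] for p in pix]
        for j in range(5):
            vals = sorted(pt.intensity[i, j] for i in idx)
            assert sp.values[j] == vals[len(vals) // 2]  # odd n
        # permutation of the pixel set cannot matter (it is a set)
        sp2 = region_spectrum(pt, Region("r", "tissue", frozenset(reversed(pix))))
        np.testing.assert_array_equal(sp.values, sp2.values)


class TestBackgroundConsistency:
    def test_identical_and_scaled_spectra_give_unit_correlation(self):
        v = np.array([1.0, 5.0, 2.0, 8.0])
        cm = background_consistency(
            [RegionSpectrum("a", v), RegionSpectrum("b", v.copy()),
             RegionSpectrum("c", 2.0 * v)]
        )
        np.testing.assert_allclose(cm.matrix, 1.0, atol=1e-12)
        assert cm.consistent

    def test_known_correlation_value(self):
        cm = background_consistency(
            [RegionSpectrum("a", np.array([1.0, 2.0, 3.0])),
             RegionSpectrum("b", np.array([1.0, 2.0, 4.0]))]
        )
        expected = 9.0 / (2.0 * math.sqrt(21.0))
        np.testing.assert_allclose(cm.matrix[0, 1], expected, atol=1e-12)
        assert cm.min_offdiag == pytest.approx(expected)
        assert cm.consistent  # 0.982 > 0.9

    def test_symmetry_and_unit_diagonal(self, rng):
        spectra = [RegionSpectrum(f"r{i}", rng.random(30)) for i in range(4)]
        cm = background_consistency(spectra)
        np.testing.assert_allclose(cm.matrix, cm.matrix.T, atol=1e-15)
        np.testing.assert_array_equal(np.diag(cm.matrix), 1.0)
        assert np.all(np.abs(cm.matrix) <= 1.0)

    def test_zero_variance_spectrum_names_region(self):
        with pytest.raises(UndefinedCorrelationError, match="flat"):
            background_consistency(
                [RegionSpectrum("flat", np.ones(5)),
                 RegionSpectrum("ok", np.arange(5.0))]
            )


class TestClustering:
    def test_identical_pair_merges_first_at_zero(self, rng):
        v = rng.random(20)
        cm = background_consistency(
            [RegionSpectrum("a", v), RegionSpectrum("b", v.copy()),
             RegionSpectrum("c", rng.random(20))]
        )
        Z, _ = cluster_background_spectra(cm)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # a and b (name order)

    def test_merge_heights_match_brute_force_average_linkage(self, rng):
        spectra = [RegionSpectrum(f"r{i}", rng.random(25)) for i in range(5)]
        cm = background_consistency(spectra)
        Z, _ = cluster_background_spectra(cm)

        # independent average-linkage recomputation
        d = 1.0 - cm.matrix
        clusters = {i: [i] for i in range(5)}
        heights = []
        nxt = 5
        while len(clusters) > 1:
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a >= b:
                        continue
                    dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                    if best is None or dist < best[0]:
                        best = (dist, a, b)
            dist, a, b = best
            heights.append(dist)
            clusters[nxt] = clusters.pop(a) + clusters.pop(b)
            nxt += 1
        np.testing.assert_allclose(Z[:, 2], heights, atol=1e-12)

    def test_heights_nondecreasing(self, rng):
        spectra = [RegionSpectrum(f"r{i}", rng.random(15)) for i in range(6)]
        Z, _ = cluster_background_spectra(background_consistency(spectra))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_cut_zero_on_distinct_spectra_gives_singletons(self, rng):
        spectra = [RegionSpectrum(f"r{i}", rng.random(15)) for i in range(4)]
        _, labels = cluster_background_spectra(
            background_consistency(spectra), cut_distance=0.0
        )
        assert len(set(labels.values())) == 4


class TestRegionSet:
    def test_load_regions_schema(self, demo, tmp_path):
        pt, truth = demo
        rs = load_regions(truth.regions, pt)
        assert len(rs.tissue()) == 1 and len(rs.background()) == 3

    def test_overlapping_regions_rejected(self):
        pt = grid_table(5, 5)
        spec = [
            {"name": "a", "role": "tissue", "pixels": [[0, 0], [1, 0]]},
            {"name": "b", "role": "background", "pixels": [[1, 0]]},
        ]
        with pytest.raises(ConfigError):
            load_regions(spec, pt)

    def test_unknown_keys_rejected(self):
        pt = grid_table(5, 5)
        with pytest.raises(ConfigError):
            load_regions([{"name": "a", "role": "tissue", "pix": []}], pt)
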
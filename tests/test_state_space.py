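"""State-space lattice construction and effort rasterization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, box

from lionscr.state_space import (build_state_space, distance_matrix,
                                 rasterize_effort)


S = math.sqrt(0.5)  # lattice spacing for 0.5 km^2 pixels


class TestBuildStateSpace:
    def test_pixel_count_matches_area(self):
        # 36 x 131 lattice-aligned rectangle = 2358 km^2 -> 4716 pixels
        extent = box(0, 0, 36 * S, 131 * S)
        ss = build_state_space(extent, buffer_km=0.0, pixel_area_km2=0.5)
        assert ss.n_pixels == 4716
        assert ss.total_area == pytest.approx(2358.0)
        assert ss.n_habitat == 4716

    def test_lattice_is_regular(self):
        ss = build_state_space(box(0, 0, 4, 3), buffer_km=0.0, pixel_area_km2=0.5)
        xs = np.unique(ss.centroids[:, 0])
        assert np.allclose(np.diff(xs), ss.spacing)
        assert ss.spacing == pytest.approx(S)

    def test_buffer_expands_extent(self):
        small = build_state_space(box(0, 0, 2, 2), buffer_km=0.0, pixel_area_km2=1.0)
        buffered = build_state_space(box(0, 0, 2, 2), buffer_km=3.0, pixel_area_km2=1.0)
        assert buffered.total_area > small.total_area + math.pi * 9 * 0.5

    def test_mask_flags_non_habitat(self):
        mask = box(0, 0, 2, 2)
        ss = build_state_space(box(0, 0, 4, 2), buffer_km=0.0,
                               pixel_area_km2=1.0, habitat_mask=[mask])
        assert ss.n_pixels == 8
        assert ss.n_habitat == 4
        assert ss.habitat_area == pytest.approx(4.0)

    def test_full_mask_is_an_error(self):
        with pytest.raises(ValueError, match="mask"):
            build_state_space(box(0, 0, 2, 2), buffer_km=0.0,
                              pixel_area_km2=1.0, habitat_mask=[box(-1, -1, 3, 3)])

    def test_empty_extent_is_an_error(self):
        with pytest.raises(ValueError, match="empty extent"):
            build_state_space(Point(0, 0).buffer(0), buffer_km=0.0,
                              pixel_area_km2=1.0)

    def test_raster_mask(self):
        # 2x2 raster of 2 km cells over a 4x4 extent; one quadrant masked out
        grid = np.array([[1.0, 1.0], [0.0, 1.0]])   # row 0 is the top
        ss = build_state_space(box(0, 0, 4, 4), buffer_km=0.0,
                               pixel_area_km2=1.0,
                               habitat_mask=(grid, 0.0, 0.0, 2.0))
        assert ss.n_pixels == 16
        assert ss.n_habitat == 12
        bad = ss.centroids[~ss.habitat]
        assert np.all(bad[:, 0] < 2) and np.all(bad[:, 1] < 2)

    def test_habitat_lattice_roundtrip(self):
        ss = build_state_space(box(0, 0, 3, 2), buffer_km=0.0, pixel_area_km2=1.0)
        grid = ss.habitat_lattice()
        ij = ss.habitat_ij()
        for k in range(ss.n_habitat):
            assert grid[ij[k, 1], ij[k, 0]] == k


class TestRasterizeEffort:
    def test_single_cell_segment(self):
        seg = np.array([[0.3, 0.5], [0.3 + 2.0 / math.sqrt(2), 0.5 + 2.0 / math.sqrt(2)]])
        # keep it inside one 3 km cell
        traps, eff = rasterize_effort([(seg, 3)], [], 9.0, n_occasions=5)
        assert traps.n_traps == 1
        assert eff.search_km[0, 2] == pytest.approx(2.0)
        assert eff.search_km.sum() == pytest.approx(2.0)

    def test_two_cell_split(self):
        seg = np.array([[0.6, 0.5], [1.6, 0.5]])
        traps, eff = rasterize_effort([(seg, 1)], [], 1.0, n_occasions=1)
        lengths = dict(zip(map(tuple, traps.cell_ij), eff.search_km[:, 0]))
        assert lengths[(0, 0)] == pytest.approx(0.4)
        assert lengths[(1, 0)] == pytest.approx(0.6)
        assert eff.total_search_km == pytest.approx(1.0)

    def test_duplicate_playbacks_collapse(self):
        pb = [(np.array([0.5, 0.5]), 2), (np.array([0.6, 0.4]), 2)]
        traps, eff = rasterize_effort([], pb, 1.0, n_occasions=3)
        assert traps.n_traps == 1
        assert eff.playback[0, 1] == 1
        assert eff.n_playback_events == 1

    def test_trap_exists_iff_effort(self):
        seg = np.array([[0.1, 0.1], [0.9, 0.1]])
        pb = [(np.array([5.5, 5.5]), 1)]
        traps, eff = rasterize_effort([(seg, 1)], pb, 1.0, n_occasions=1)
        assert traps.n_traps == 2
        assert np.all(eff.active.any(axis=1))

    def test_occasion_out_of_range(self):
        seg = np.array([[0.1, 0.1], [0.9, 0.1]])
        with pytest.raises(ValueError, match="occasion"):
            rasterize_effort([(seg, 7)], [], 1.0, n_occasions=5)

    def test_empty_effort_warns(self, caplog):
        with caplog.at_level("WARNING"):
            traps, eff = rasterize_effort([], [], 1.0, n_occasions=2)
        assert traps.n_traps == 0
        assert "no effort" in caplog.text

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.01, 9.99), st.floats(0.01, 9.99)),
                    min_size=2, max_size=6),
           st.integers(1, 4))
    def test_length_conservation(self, pts, occ):
        """Clipping conserves total track length for arbitrary polylines."""
        verts = np.array(pts)
        true_len = np.sum(np.hypot(*(np.diff(verts, axis=0).T)))
        traps, eff = rasterize_effort([(verts, occ)], [], 1.0, n_occasions=4)
        assert eff.total_search_km == pytest.approx(true_len, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        tracks = [(rng.uniform(0, 5, size=(4, 2)), int(occ))
                  for occ in rng.integers(1, 4, size=6)]
        t1, e1 = rasterize_effort(tracks, [], 1.0, n_occasions=3)
        t2, e2 = rasterize_effort(tracks[::-1], [], 1.0, n_occasions=3)
        assert np.array_equal(t1.cell_ij, t2.cell_ij)
        assert np.allclose(e1.search_km, e2.search_km)


class TestDistanceMatrix:
    def test_three_four_five(self):
        ss = build_state_space(box(0, 0, 1, 1), buffer_km=0.0, pixel_area_km2=1.0)
        seg = np.array([[3.1, 4.1], [3.9, 4.1]])
        traps, _ = rasterize_effort([(seg, 1)], [], 1.0, n_occasions=1)
        d = distance_matrix(ss, traps)
        assert d[0, 0] == pytest.approx(5.0)  # (0.5,0.5) to (3.5,4.5)

    def test_triangle_inequality_sampled(self):
        rng = np.random.default_rng(1)
        ss = build_state_space(box(0, 0, 5, 5), buffer_km=0.0, pixel_area_km2=1.0)
        seg = np.array([[0.2, 0.2], [4.8, 4.8]])
        traps, _ = rasterize_effort([(seg, 1)], [], 1.0, n_occasions=1)
        d = distance_matrix(ss, traps)
        assert np.all(d >= 0)
        # |d(p1,t) - d(p2,t)| <= dist(p1,p2) for sampled pixel pairs
        for _ in range(50):
            p1, p2 = rng.integers(0, ss.n_pixels, size=2)
            t = rng.integers(0, traps.n_traps)
            pp = np.hypot(*(ss.centroids[p1] - ss.centroids[p2]))
            assert abs(d[p1, t] - d[p2, t]) <= pp + 1e-12
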
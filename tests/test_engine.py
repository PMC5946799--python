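"""PIV engine: SAD oracle equivalence, gridding, peaks, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_sad
from spimpiv.engine import (PIVConfig, SimilarityMap, analyze_plane,
                            average_maps, find_peak, make_iw_grid,
                            similarity_map, subpixel_offset, validate_field)
from spimpiv.scenes import SceneConfig, make_tube_dataset


class TestSimilarityMap:
    def test_identical_patches_single_element_zero(self):
        a = np.arange(12.0).reshape(3, 4)
        m = similarity_map(a, a)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == 0.0

    def test_impulse_offset_found(self):
        a = np.zeros((2, 2)); a[0, 0] = 1.0
        b = np.zeros((4, 4)); b[2, 2] = 1.0
        m = similarity_map(a, b)
        pk = find_peak(m, mask_halfwidth=0, ratio_threshold=1.0)
        # origin of the 2x2-in-4x4 map is (-1,-1); impulse at index (2,2)
        assert (pk.dx, pk.dy) == (1, 1)

    def test_matches_brute_force_oracle_exactly(self, rng):
        for _ in range(100):
            a = rng.integers(0, 256, size=(6, 5)).astype(float)
            b = rng.integers(0, 256, size=(11, 9)).astype(float)
            m = similarity_map(a, b)
            np.testing.assert_array_equal(-m.values, brute_force_sad(a, b))

    def test_xcorr_is_plain_product(self, rng):
        a = rng.integers(0, 9, size=(3, 3)).astype(float)
        b = rng.integers(0, 9, size=(5, 5)).astype(float)
        m = similarity_map(a, b, metric="xcorr")
        expected = np.array([[np.sum(a * b[i:i + 3, j:j + 3])
                              for j in range(3)] for i in range(3)])
        np.testing.assert_array_equal(m.values, expected)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity_map(np.zeros((4, 4)), np.zeros((2, 6)))


class TestAverageMaps:
    def _map(self, vals):
        return SimilarityMap(np.asarray(vals, float), (-1, -1))

    def test_identical_maps_average_to_themselves(self):
        m = self._map([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        out = average_maps([m] * 5)
        np.testing.assert_array_equal(out.values, m.values)
        assert out.n_contributing_pairs == 5

    def test_permutation_invariant(self, rng):
        maps = [self._map(rng.normal(size=(3, 3))) for _ in range(6)]
        a = average_maps(maps)
        b = average_maps(maps[::-1])
        np.testing.assert_allclose(a.values, b.values)

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            average_maps([])
        with pytest.raises(ValueError):
            average_maps([self._map(np.zeros((2, 2))),
                          self._map(np.zeros((3, 3)))])

    def test_averaging_improves_peak_to_peak_ratio(self, rng):
        # many noisy maps sharing a true peak: averaged ratio beats the
        # median single-map ratio
        true = np.zeros((9, 9)); true[4, 4] = 3.0
        maps = [self._map(true + rng.normal(0, 1, true.shape))
                for _ in range(250)]
        singles = [find_peak(m, 1, 1.0).ratio for m in maps]
        avg_ratio = find_peak(average_maps(maps), 1, 1.0).ratio
        assert avg_ratio > np.median(singles)


class TestFindPeak:
    def test_single_positive_element_infinite_ratio(self):
        vals = np.zeros((7, 7)); vals[2, 3] = 1.0
        pk = find_peak(SimilarityMap(vals, (-3, -3)), 1, 1.10)
        assert (pk.dx, pk.dy) == (0, -1)
        assert pk.ratio == np.inf and pk.valid

    def test_two_distant_equal_peaks_invalid(self):
        vals = np.zeros((9, 17))
        vals[4, 2] = 5.0
        vals[4, 14] = 5.0      # 12 elements apart, outside the 7x7 mask
        pk = find_peak(SimilarityMap(vals, (-8, -4)), 3, 1.10)
        assert pk.ratio == pytest.approx(1.0)
        assert not pk.valid

    def test_secondary_peak_inside_mask_ignored(self):
        vals = np.zeros((9, 17))
        vals[4, 8] = 5.0
        vals[4, 10] = 4.9      # 2 elements away: masked out
        vals[4, 15] = 0.5      # far third peak, much lower
        pk = find_peak(SimilarityMap(vals, (-8, -4)), 3, 1.10)
        assert pk.valid and pk.ratio == pytest.approx(10.0)

    def test_all_masked_map_invalid(self):
        vals = np.ones((3, 3)); vals[1, 1] = 2.0
        pk = find_peak(SimilarityMap(vals, (-1, -1)), 3, 1.10)
        assert not pk.valid and np.isnan(pk.ratio)

    def test_tie_breaks_to_smallest_displacement(self):
        vals = np.zeros((5, 5))
        vals[1, 3] = vals[3, 1] = 7.0
        pk = find_peak(SimilarityMap(vals, (-2, -2)), 0, 1.0)
        assert (pk.dy, pk.dx) == (-1, 1)   # smallest (dy, dx) lexicographically

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_peak_is_argmax_on_random_maps(self, s):
        rng = np.random.default_rng(s)
        vals = rng.normal(size=(7, 9))
        pk = find_peak(SimilarityMap(vals, (-4, -3)), 1, 1.0)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        assert vals[pk.dy + 3, pk.dx + 4] == vals[i, j]


class TestSubpixel:
    def test_symmetric_neighbors_zero_offset(self):
        vals = np.zeros((5, 5)); vals[2, 2] = 2.0
        vals[2, 1] = vals[2, 3] = 1.0
        vals[1, 2] = vals[3, 2] = 1.0
        sub = subpixel_offset(SimilarityMap(vals, (-2, -2)), (0, 0))
        assert sub.delta_x == 0.0 and sub.delta_y == 0.0

    @pytest.mark.parametrize("offset", [0.3, -0.25, 0.49])
    def test_gaussian_samples_recovered(self, offset):
        x = np.arange(-2.0, 3.0)
        vals = np.exp(-((x[None, :] - offset) ** 2) / 1.3) \
            * np.exp(-(x[:, None] ** 2) / 1.3)
        sub = subpixel_offset(SimilarityMap(vals, (-2, -2)), (0, 0))
        assert sub.delta_x == pytest.approx(offset, abs=1e-6)
        assert sub.delta_y == pytest.approx(0.0, abs=1e-6)

    def test_edge_peak_returns_integer_with_flag(self):
        vals = np.zeros((3, 5)); vals[0, 0] = 1.0
        sub = subpixel_offset(SimilarityMap(vals, (-2, -1)), (-2, -1))
        assert sub.edge and sub.delta_x == 0.0


class TestIWGrid:
    def test_published_tube_geometry(self):
        # 320x120 image, small 32x12, large 128x16, 50% overlap:
        # step (16, 6); small-x from 48 to 240, small-y from 6 to 102
        pc = PIVConfig(small_iw=(32, 12), large_iw=(128, 16), dt=1.0)
        grid = make_iw_grid((120, 320), pc)
        xs = sorted({p.sx0 for p in grid})
        ys = sorted({p.sy0 for p in grid})
        assert xs == list(range(48, 241, 16))
        assert ys == list(range(6, 103, 6))
        for p in grid:
            assert p.lx0 >= 0 and p.lx0 + 128 <= 320
            assert p.ly0 >= 0 and p.ly0 + 16 <= 120
            # concentric: same centre for small and large windows
            assert p.sx0 - p.lx0 == 48 and p.sy0 - p.ly0 == 2

    def test_zero_overlap_tiles_disjointly(self):
        pc = PIVConfig(small_iw=(16, 16), large_iw=(16, 16),
                       overlap_fraction=0.0, dt=1.0)
        grid = make_iw_grid((64, 64), pc)
        assert sorted({p.sx0 for p in grid}) == [0, 16, 32, 48]

    def test_single_large_window_image(self):
        pc = PIVConfig(small_iw=(8, 8), large_iw=(16, 16), dt=1.0)
        grid = make_iw_grid((16, 16), pc)
        assert len(grid) == 1 and grid[0].center == (7.5, 7.5)

    def test_too_small_image_rejected(self):
        pc = PIVConfig(small_iw=(8, 8), large_iw=(32, 32), dt=1.0)
        with pytest.raises(ValueError):
            make_iw_grid((16, 16), pc)


class _RollPair:
    def __init__(self, frame, p, q):
        self.frame_a = frame
        self.frame_b = np.roll(frame, (q, p), axis=(0, 1))
        self.dt = 1.0
        self.z_index = 0
        self.z_um = 0.0


class TestAnalyzePlane:
    def test_translation_equivariance_under_integer_roll(self, rng):
        frame = rng.random((64, 96))
        pc = PIVConfig(small_iw=(16, 8), large_iw=(32, 16), dt=1.0,
                       pixel_size=1.0)
        for p, q in [(3, 1), (-4, 2), (0, -3)]:
            f = analyze_plane([_RollPair(frame, p, q)], pc)
            inner = (np.abs(f.grid_x - 48) < 20) & (np.abs(f.grid_y - 32) < 16)
            np.testing.assert_allclose(np.round(f.u_px[inner]), p)
            np.testing.assert_allclose(np.round(f.v_px[inner]), q)

    def test_uniform_translation_recovered_to_tenth_pixel(self):
        from spimpiv.scenes import make_gradient_scene
        cfg = SceneConfig(image_shape=(64, 96), seeding_density=1.0,
                          tracer_diameter=2.0, pixel_size=0.5, dt=1.0)
        pairs = [make_gradient_scene(cfg, 0.0, seed=200 + s,
                                     shift_px=(4.0, 0.0)) for s in range(10)]
        pc = PIVConfig(small_iw=(16, 16), large_iw=(32, 32), dt=1.0,
                       pixel_size=0.5)
        f = analyze_plane(pairs, pc)
        assert f.valid.sum() >= f.n * 0.8
        np.testing.assert_allclose(f.u_px[f.valid], 4.0, atol=0.1)

    def test_sparse_single_pair_vs_averaged_validity(self):
        cfg = SceneConfig(image_shape=(120, 160), flow_rate=0.5,
                          seeding_density=0.2)
        pairs, _ = make_tube_dataset(cfg, 100, [0.0], seed=22)
        pc = PIVConfig(small_iw=(32, 12), large_iw=(64, 16), dt=cfg.dt,
                       pixel_size=cfg.pixel_size)
        inside = None
        f1 = analyze_plane(pairs[:1], pc)
        fN = analyze_plane(pairs, pc)
        inside = np.abs(fN.grid_y - 59.5) * cfg.pixel_size < 18
        assert f1.valid[inside].mean() < 0.6
        assert fN.valid[inside].mean() >= 0.9

    def test_min_intensity_excludes_dark_windows(self):
        dark = np.zeros((32, 64))
        pair = _RollPair(dark, 0, 0)
        pc = PIVConfig(small_iw=(16, 8), large_iw=(32, 16), dt=1.0,
                       min_iw_intensity=1e5)
        f = analyze_plane([pair], pc)
        assert f.excluded.all()
        assert not f.valid.any()

    def test_empty_pair_list_rejected(self):
        pc = PIVConfig(dt=1.0)
        with pytest.raises(ValueError):
            analyze_plane([], pc)


class TestValidateField:
    def _field(self):
        from spimpiv.scenes import make_gradient_scene
        cfg = SceneConfig(image_shape=(64, 96), seeding_density=1.0,
                          tracer_diameter=2.0, pixel_size=0.5, dt=1.0)
        pairs = [make_gradient_scene(cfg, 0.0, seed=300 + s,
                                     shift_px=(4.0, 0.0)) for s in range(4)]
        pc = PIVConfig(small_iw=(16, 16), large_iw=(32, 32), dt=1.0,
                       pixel_size=0.5)
        return analyze_plane(pairs, pc)

    def test_no_rules_leaves_field_unchanged(self):
        f = self._field()
        g = validate_field(f)
        np.testing.assert_array_equal(f.valid, g.valid)

    def test_negative_horizontal_component_discarded(self):
        f = self._field()
        g = validate_field(f, forward_axis_sign=-1)   # flow is +x: all fail
        assert not g.valid.any()
        np.testing.assert_array_equal(g.u_px, f.u_px)  # values retained

    def test_outside_radius_discarded(self):
        f = self._field()
        y_c = 32.0
        g = validate_field(f, center=(y_c, 0.0), radius=5.0, pixel_pitch=0.5)
        r = np.abs(f.grid_y - y_c) * 0.5
        assert not g.valid[r > 5.0].any()
        assert g.valid[r <= 5.0].sum() == f.valid[r <= 5.0].sum()
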
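import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesopipe.roi_manager import (ROI, ROISet, combine, extract_traces,
                                  load_rois, rasterize, rle_decode,
                                  rle_encode, save_rois, threshold_roi)
from .conftest import make_stack


def brute_force_circle(center, radius, shape):
    H, W = shape
    mask = np.zeros(shape, bool)
    for r in range(H):
        for c in range(W):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius ** 2:
                mask[r, c] = True
    return mask


def brute_force_polygon(vertices, shape):
    """Even-odd rule with boundary-in, evaluated point by point."""
    H, W = shape
    mask = np.zeros(shape, bool)
    n = len(vertices)
    for r in range(H):
        for c in range(W):
            inside = False
            on_edge = False
            for i in range(n):
                r1, c1 = vertices[i]
                r2, c2 = vertices[(i + 1) % n]
                if (min(r1, r2) <= r <= max(r1, r2)
                        and min(c1, c2) <= c <= max(c1, c2)
                        and abs((r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)) < 1e-9):
                    on_edge = True
                if (r1 <= r) != (r2 <= r):
                    c_int = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
                    if c < c_int:
                        inside = not inside
            mask[r, c] = inside or on_edge
    return mask


class TestRasterize:
    def test_point_is_single_pixel(self):
        mask = rasterize(ROI("p", "point", {"row": 5, "col": 5}), (11, 11))
        assert mask.sum() == 1 and mask[5, 5]

    def test_half_radius_circle_is_single_pixel(self):
        mask = rasterize(ROI("c", "circle",
                             {"center": (5, 5), "radius": 0.5}), (11, 11))
        assert mask.sum() == 1 and mask[5, 5]

    def test_radius_two_circle_matches_distance_scan(self):
        roi = ROI("c", "circle", {"center": (5, 5), "radius": 2.0})
        mask = rasterize(roi, (11, 11))
        oracle = brute_force_circle((5, 5), 2.0, (11, 11))
        np.testing.assert_array_equal(mask, oracle)
        assert mask.sum() == 13

    def test_unit_square_polygon_matches_even_odd_oracle(self):
        verts = [(0, 0), (0, 1), (1, 1), (1, 0)]
        roi = ROI("sq", "polygon", {"vertices": verts})
        mask = rasterize(roi, (5, 5))
        np.testing.assert_array_equal(mask, brute_force_polygon(verts, (5, 5)))
        assert mask.sum() == 4   # all four boundary corners count as inside

    def test_random_polygons_match_oracle(self, rng):
        for _ in range(10):
            verts = [tuple(v) for v in rng.uniform(0, 11, (5, 2))]
            roi = ROI("poly", "polygon", {"vertices": verts})
            oracle = brute_force_polygon(verts, (12, 12))
            if not oracle.any():
                continue
            np.testing.assert_array_equal(rasterize(roi, (12, 12)), oracle)

    def test_fully_outside_rejected(self):
        with pytest.raises(ValueError):
            rasterize(ROI("p", "point", {"row": 50, "col": 0}), (10, 10))

    def test_resolution_scaling_consistency(self):
        """Area grows ~k^2 under integer upscaling of frame and params."""
        base = rasterize(ROI("c", "circle", {"center": (10, 10), "radius": 5}),
                         (21, 21))
        k = 3
        big = rasterize(ROI("c", "circle",
                            {"center": (10 * k, 10 * k), "radius": 5 * k}),
                        (21 * k, 21 * k))
        perimeter = 2 * np.pi * 5 * k
        assert abs(big.sum() - k ** 2 * base.sum()) <= 4 * perimeter


class TestThresholdRoi:
    def test_single_hot_pixel(self):
        m = np.zeros((5, 5))
        m[2, 3] = 1.0
        roi = threshold_roi(m, "above", 0.5, "hot")
        mask = rasterize(roi, (5, 5))
        assert mask.sum() == 1 and mask[2, 3]

    def test_above_max_rejected(self, rng):
        m = rng.normal(0, 1, (5, 5))
        with pytest.raises(ValueError, match="0 pixels"):
            threshold_roi(m, "above", m.max(), "empty")

    def test_median_cutoff_matches_elementwise_count(self, rng):
        m = rng.normal(0, 1, (16, 16))
        cutoff = float(np.median(m))
        roi = threshold_roi(m, "above", cutoff, "hi")
        assert rasterize(roi, (16, 16)).sum() == int((m > cutoff).sum())

    def test_below_direction(self, rng):
        m = rng.normal(0, 1, (8, 8))
        roi = threshold_roi(m, "below", 0.0, "lo")
        np.testing.assert_array_equal(rasterize(roi, (8, 8)), m < 0.0)


class TestCombine:
    def _circle(self, name, center, radius=2.0):
        return ROI(name, "circle", {"center": center, "radius": radius})

    def test_merge_idempotent(self):
        a = self._circle("a", (5, 5))
        merged = combine([a, a], "merge", (11, 11))
        np.testing.assert_array_equal(rasterize(merged, (11, 11)),
                                      rasterize(a, (11, 11)))

    def test_disjoint_intersection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            combine([self._circle("a", (2, 2), 1), self._circle("b", (8, 8), 1)],
                    "intersect", (11, 11))

    def test_crop_to_mask_is_elementwise_and(self, rng):
        a = self._circle("a", (5, 5), 4)
        aux = rng.random((11, 11)) > 0.5
        if not (rasterize(a, (11, 11)) & aux).any():
            aux[5, 5] = True
        out = combine([a], "crop_to_mask", (11, 11), aux_mask=aux)
        np.testing.assert_array_equal(rasterize(out, (11, 11)),
                                      rasterize(a, (11, 11)) & aux)

    def test_merge_is_union(self):
        a, b = self._circle("a", (3, 3)), self._circle("b", (7, 7))
        out = combine([a, b], "merge", (11, 11))
        np.testing.assert_array_equal(
            rasterize(out, (11, 11)),
            rasterize(a, (11, 11)) | rasterize(b, (11, 11)))


class TestExtractTraces:
    def test_single_pixel_roi_returns_pixel_trace(self, random_stack):
        rois = ROISet([ROI("px", "point", {"row": 2, "col": 3})])
        traces = extract_traces(random_stack, rois)
        np.testing.assert_allclose(traces["px"], random_stack.data[:, 2, 3],
                                   atol=1e-12)

    def test_uniform_frames_give_frame_value(self):
        data = np.arange(10)[:, None, None] * np.ones((10, 6, 6))
        rois = ROISet([ROI("c", "circle", {"center": (3, 3), "radius": 2})])
        traces = extract_traces(make_stack(data), rois)
        np.testing.assert_allclose(traces["c"], np.arange(10), atol=1e-12)

    def test_matches_masked_mean_oracle(self, random_stack, rng):
        rois = ROISet([
            ROI("a", "circle", {"center": (3, 3), "radius": 2}),
            ROI("b", "point", {"row": 0, "col": 0}),
            ROI("c", "mask", {"mask": rng.random((8, 8)) > 0.6}),
        ])
        traces = extract_traces(random_stack, rois)
        for roi in rois:
            mask = rasterize(roi, (8, 8))
            oracle = np.array([random_stack.data[t][mask].mean()
                               for t in range(random_stack.shape[0])])
            np.testing.assert_allclose(traces[roi.name], oracle, atol=1e-12)

    def test_missing_pixels_excluded(self, random_stack):
        data = random_stack.data.copy()
        data[:, 1, 1] = np.nan
        rois = ROISet([ROI("sq", "mask",
                           {"mask": np.ones((8, 8), dtype=bool)})])
        traces = extract_traces(random_stack.with_data(data), rois)
        ok = np.ones((8, 8), bool)
        ok[1, 1] = False
        oracle = data[:, ok].mean(axis=1)
        np.testing.assert_allclose(traces["sq"], oracle, atol=1e-12)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(0.1, 5))
    def test_linearity_in_the_stack(self, a, b):
        stack = make_stack(np.random.default_rng(7).normal(1, 0.1, (20, 8, 8)))
        rois = ROISet([ROI("c", "circle", {"center": (4, 4), "radius": 2.5})])
        t1 = extract_traces(stack, rois)["c"]
        scaled = stack.with_data(b * stack.data + a)
        t2 = extract_traces(scaled, rois)["c"]
        np.testing.assert_allclose(t2, b * t1 + a, atol=1e-9)


class TestPersistence:
    def _set(self, rng):
        return ROISet([
            ROI("pt", "point", {"row": 1, "col": 2}),
            ROI("circ", "circle", {"center": (4.0, 4.0), "radius": 2.5}),
            ROI("poly", "polygon", {"vertices": [[0, 0], [0, 4], [4, 2]]}),
            ROI("msk", "mask", {"mask": rng.random((8, 8)) > 0.5}),
        ])

    def test_round_trip_identity(self, tmp_path, rng):
        rois = self._set(rng)
        save_rois(rois, tmp_path / "rois.json")
        loaded = load_rois(tmp_path / "rois.json")
        assert loaded.names == rois.names
        for name in rois.names:
            a, b = rois[name], loaded[name]
            assert a.kind == b.kind
            np.testing.assert_array_equal(rasterize(a, (8, 8)),
                                          rasterize(b, (8, 8)))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ROISet([ROI("a", "point", {"row": 0, "col": 0}),
                    ROI("a", "point", {"row": 1, "col": 1})])

    def test_rle_against_independent_decoder(self, rng):
        for _ in range(20):
            mask = rng.random((7, 9)) > rng.random()
            enc = rle_encode(mask)
            # independent decoder: expand runs manually
            flat = []
            val = False
            for run in enc["runs"]:
                flat.extend([val] * run)
                val = not val
            np.testing.assert_array_equal(
                np.array(flat, bool).reshape(7, 9), mask)
            np.testing.assert_array_equal(rle_decode(enc), mask)
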
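"""Crown segmentation: NDVI, thresholding, filtering, merging, centroids."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from orchardyield.segmentation import (
    CrownLayer,
    CrownPolygon,
    compute_ndvi,
    extract_centroids,
    filter_multi_tree,
    merge_layers,
    segment_crowns,
    threshold_segment,
)
from orchardyield.synthetic import (
    GroundTruth,
    OrchardParams,
    generate_orchard,
    render_reflectance,
)

from conftest import make_stack, uniform_stack


class TestNDVI:
    def test_equal_bands_give_zero(self):
        stack = uniform_stack(3, 3, nir=0.4, red=0.4)
        np.testing.assert_allclose(compute_ndvi(stack), 0.0)

    def test_hand_value(self):
        stack = uniform_stack(2, 2, nir=0.5, red=0.1)
        np.testing.assert_allclose(compute_ndvi(stack), 0.4 / 0.6, atol=1e-10)

    def test_zero_denominator_is_nodata_not_nan_propagation(self):
        data = np.zeros((2, 2, 4))
        data[0, 0, :] = [0.1, 0.1, 0.1, 0.3]
        ndvi = compute_ndvi(make_stack(data))
        assert ndvi[0, 0] == pytest.approx(0.5)
        assert np.isnan(ndvi[1, 1])

    def test_range_bounded(self, small_orchard):
        _, stack, _, _ = small_orchard
        ndvi = compute_ndvi(stack)
        valid = ndvi[np.isfinite(ndvi)]
        assert valid.min() >= -1.0 and valid.max() <= 1.0


def _ndvi_patch_stack(patches, shape=(12, 12), bg=0.2, fg=0.9):
    """Raster whose NDVI is ``bg`` except ``fg`` on listed pixel sets."""
    # choose nir/red pairs giving the desired NDVI values exactly
    def nr(v):  # nir+red=0.4 -> nir=0.2(1+v), red=0.2(1-v)
        return 0.2 * (1 + v), 0.2 * (1 - v)

    data = np.zeros(shape + (4,))
    n_bg, r_bg = nr(bg)
    data[:, :, 3], data[:, :, 1] = n_bg, r_bg
    for pixels in patches:
        n_fg, r_fg = nr(fg)
        for (r, c) in pixels:
            data[r, c, 3], data[r, c, 1] = n_fg, r_fg
    return make_stack(data)


class TestThresholdSegment:
    def test_uniform_low_ndvi_gives_empty_layer(self):
        stack = _ndvi_patch_stack([])
        layer = threshold_segment(compute_ndvi(stack), 0.6, stack.transform)
        assert len(layer) == 0

    def test_single_patch_one_polygon(self):
        pixels = [(r, c) for r in range(4, 7) for c in range(4, 7)]
        stack = _ndvi_patch_stack([pixels])
        layer = threshold_segment(compute_ndvi(stack), 0.6, stack.transform)
        assert len(layer) == 1
        assert layer.polygons[0].pixel_count == 9

    def test_two_separated_patches_two_polygons(self):
        p1 = [(r, c) for r in range(1, 4) for c in range(1, 4)]
        p2 = [(r, c) for r in range(8, 11) for c in range(8, 11)]
        stack = _ndvi_patch_stack([p1, p2])
        layer = threshold_segment(compute_ndvi(stack), 0.6, stack.transform)
        assert len(layer) == 2

    def test_min_pixels_suppresses_noise(self):
        stack = _ndvi_patch_stack([[(5, 5)]])
        layer = threshold_segment(
            compute_ndvi(stack), 0.6, stack.transform, min_pixels=3
        )
        assert len(layer) == 0

    def test_monotone_in_threshold(self, small_orchard):
        # raising the threshold never increases any component's pixel count
        _, stack, _, _ = small_orchard
        ndvi = compute_ndvi(stack)
        lo = threshold_segment(ndvi, 0.60, stack.transform)
        hi = threshold_segment(ndvi, 0.76, stack.transform)
        assert sum(p.pixel_count for p in hi.polygons) <= sum(
            p.pixel_count for p in lo.polygons
        )


class TestMajorAxisFilter:
    def test_long_polygon_removed(self):
        # 20 px along-row at 0.3 m = 6.0 m major axis
        pixels = [(5, c) for c in range(0, 20)] + [(6, c) for c in range(0, 20)]
        stack = _ndvi_patch_stack([pixels], shape=(12, 22))
        layer = threshold_segment(compute_ndvi(stack), 0.6, stack.transform)
        assert layer.polygons[0].major_axis_m == pytest.approx(6.0)
        assert len(filter_multi_tree(layer, 4.5)) == 0

    def test_single_pixel_kept(self):
        stack = _ndvi_patch_stack([[(5, 5)]])
        layer = threshold_segment(
            compute_ndvi(stack), 0.6, stack.transform, min_pixels=1
        )
        assert len(filter_multi_tree(layer, 4.5)) == 1

    def test_exact_limit_inclusive(self):
        # 15 px * 0.3 m = 4.5 m exactly: kept
        pixels = [(5, c) for c in range(2, 17)]
        stack = _ndvi_patch_stack([pixels], shape=(12, 20))
        layer = threshold_segment(compute_ndvi(stack), 0.6, stack.transform)
        assert layer.polygons[0].major_axis_m == pytest.approx(4.5)
        assert len(filter_multi_tree(layer, 4.5)) == 1


def _poly(geom, t):
    return CrownPolygon(geom, int(geom.area / 0.09), 0.0, t)


class TestMergeLayers:
    def test_contained_high_threshold_polygon_dropped(self):
        small = _poly(box(1.0, 1.0, 1.6, 1.6), 0.83)
        large = _poly(box(0.7, 0.7, 1.9, 1.9), 0.60)
        final = merge_layers(
            [CrownLayer(0.83, [small]), CrownLayer(0.60, [large])]
        )
        assert len(final) == 1
        assert final.polygons[0].source_threshold == 0.60

    def test_non_contained_polygon_added(self):
        a = _poly(box(0, 0, 1, 1), 0.83)
        b = _poly(box(5, 5, 7, 7), 0.60)
        final = merge_layers([CrownLayer(0.83, [a]), CrownLayer(0.60, [b])])
        assert len(final) == 2

    def test_single_layer_is_identity(self):
        a = _poly(box(0, 0, 1, 1), 0.7)
        b = _poly(box(3, 3, 4, 4), 0.7)
        final = merge_layers([CrownLayer(0.7, [a, b])])
        assert len(final) == 2

    def test_merge_idempotent(self):
        layers = [
            CrownLayer(0.83, [_poly(box(1, 1, 1.6, 1.6), 0.83)]),
            CrownLayer(0.60, [_poly(box(0.7, 0.7, 1.9, 1.9), 0.60),
                              _poly(box(5, 5, 6, 6), 0.60)]),
        ]
        once = merge_layers(layers)
        twice = merge_layers([CrownLayer(0.0, once.polygons)])
        assert len(twice) == len(once)
        assert {p.geometry.wkt for p in twice.polygons} == {
            p.geometry.wkt for p in once.polygons
        }

    def test_empty_input_warns_and_returns_empty(self, caplog):
        final = merge_layers([])
        assert len(final) == 0

    def test_containment_free_result(self):
        layers = [
            CrownLayer(0.8, [_poly(box(1, 1, 2, 2), 0.8)]),
            CrownLayer(0.7, [_poly(box(0.5, 0.5, 2.5, 2.5), 0.7)]),
            CrownLayer(0.6, [_poly(box(0, 0, 3, 3), 0.6)]),
        ]
        final = merge_layers(layers)
        assert len(final) == 1
        for p in final.polygons:
            for q in final.polygons:
                if p is not q:
                    assert not p.geometry.within(q.geometry)


class TestMergedCrownScenario:
    def test_two_fused_trees_resolved_by_higher_threshold(self):
        # two high-fertility trees 3 m apart: fused (and axis-filtered) at
        # t=0.60, separated at a higher threshold -> final map has 2 crowns
        df = pd.DataFrame(
            {
                "tree_id": ["a", "b"],
                "x": [7.0, 7.0],
                "y": [7.0, 10.0],
                "row_index": [0, 0],
                "crown_radius_m": [2.2, 2.2],
                "fertility": [1.0, 1.0],
                "yield_kg": [50.0, 50.0],
            }
        )
        p = OrchardParams(reflectance_noise_sd=0.0, seed=0)
        stack = render_reflectance(GroundTruth(df), p)
        crowns, layers = segment_crowns(stack)
        low = [l for l in layers if abs(l.threshold - 0.60) < 1e-6][0]
        assert len(low) == 0  # fused blob removed by the axis filter
        assert len(crowns) == 2
        ys = sorted(c.centroid[1] for c in crowns.polygons)
        assert ys[0] == pytest.approx(7.0, abs=0.5)
        assert ys[1] == pytest.approx(10.0, abs=0.5)


class TestCentroids:
    def test_square_polygon_centroid(self):
        crowns = merge_layers(
            [CrownLayer(0.6, [_poly(box(9.5, 9.5, 10.5, 10.5), 0.6)])]
        )
        inv = extract_centroids(crowns)
        assert inv.table["x"].iloc[0] == pytest.approx(10.0)
        assert inv.table["y"].iloc[0] == pytest.approx(10.0)

    def test_l_shape_centroid_is_area_weighted(self):
        # three unit squares at (0,0),(1,0),(0,1): mean of the square
        # centers (0.5,0.5), (1.5,0.5), (0.5,1.5) -> (5/6, 5/6)
        geom = box(0, 0, 1, 1).union(box(1, 0, 2, 1)).union(box(0, 1, 1, 2))
        crowns = merge_layers([CrownLayer(0.6, [_poly(geom, 0.6)])])
        inv = extract_centroids(crowns)
        assert inv.table["x"].iloc[0] == pytest.approx(5 / 6)
        assert inv.table["y"].iloc[0] == pytest.approx(5 / 6)

    def test_empty_map_rejected(self):
        from orchardyield.segmentation import CrownMap

        with pytest.raises(ValueError, match="empty"):
            extract_centroids(CrownMap())

    def test_ids_sequential_and_unique(self, small_orchard):
        _, stack, _, _ = small_orchard
        crowns, _ = segment_crowns(stack)
        inv = extract_centroids(crowns)
        assert inv.table["tree_id"].is_unique
        assert inv.table["tree_id"].iloc[0] == "C00000"


class TestEndToEndRecovery:
    def test_recovery_on_nontouching_orchard(self):
        # 200 trees, crowns that never touch, fertility well above the
        # segmentability floor: >=95% matched 1:1 within 2.25 m, <=2% FP
        p = OrchardParams(
            n_rows=10,
            trees_per_row=20,
            crown_radius_mean_m=1.6,
            crown_radius_sd_m=0.2,
            jitter_sd_m=0.1,
            seed=21,
        )
        stack, _, truth = generate_orchard(p)
        crowns, _ = segment_crowns(stack)
        cents = crowns.centroids()
        true_xy = truth.table[["x", "y"]].to_numpy()
        from scipy.spatial import cKDTree

        tree = cKDTree(cents)
        d, idx = tree.query(true_xy)
        matched = d <= 2.25
        counts = np.bincount(idx[matched], minlength=len(cents))
        one_to_one = matched & (counts[idx] == 1)
        assert one_to_one.mean() >= 0.95
        # false positives: final crowns not near any true tree
        tree_true = cKDTree(true_xy)
        d2, _ = tree_true.query(cents)
        assert (d2 > 2.25).mean() <= 0.02
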
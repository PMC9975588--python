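"""Vegetation indices, crown coverage and GLCM textures.

The GLCM implementation is checked against two independent oracles: a
brute-force pair-enumeration reimplementation from the definitions, and
scikit-image's graycomatrix/graycoprops for the measures it shares.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orchardyield.features import (
    GLCM_OFFSETS,
    TEXTURE_MEASURES,
    VI_NAMES,
    assemble_feature_table,
    compute_vi_suite,
    crown_mask_and_coverage,
    glcm_matrix,
    glcm_measures,
    glcm_texture_features,
    quantize,
    vi_zonal_means,
)
from orchardyield.segmentation import compute_ndvi

from conftest import make_stack, uniform_stack
from oracles import brute_force_glcm, brute_force_measures


class TestVISuite:
    def test_equal_nir_red(self):
        stack = uniform_stack(2, 2, nir=0.3, red=0.3)
        vis = compute_vi_suite(stack)
        np.testing.assert_allclose(vis["ndvi"], 0.0, atol=1e-12)
        np.testing.assert_allclose(vis["sr"], 1.0, atol=1e-12)

    def test_ndre_and_cire_hand_values(self):
        stack = uniform_stack(2, 2, nir=0.5, red_edge=0.25)
        vis = compute_vi_suite(stack)
        np.testing.assert_allclose(vis["ndre"], 0.25 / 0.75, atol=1e-10)
        np.testing.assert_allclose(vis["ci_red_edge"], 1.0, atol=1e-10)

    def test_savi_hand_value(self):
        stack = uniform_stack(2, 2, nir=0.4, red=0.1)
        vis = compute_vi_suite(stack)
        np.testing.assert_allclose(vis["savi"], 0.45, atol=1e-10)

    def test_thirteen_indices(self):
        assert len(VI_NAMES) == 13
        stack = uniform_stack(2, 2, nir=0.4, red=0.1, green=0.1, red_edge=0.2)
        assert set(compute_vi_suite(stack)) == set(VI_NAMES)

    def test_normalized_indices_bounded(self, small_orchard):
        _, stack, _, _ = small_orchard
        vis = compute_vi_suite(stack)
        for name in ("ndvi", "ndre", "gndvi", "grvi"):
            v = vis[name][np.isfinite(vis[name])]
            assert v.min() >= -1.0 and v.max() <= 1.0

    def test_guarded_division(self):
        data = np.zeros((2, 2, 4))
        vis = compute_vi_suite(make_stack(data))
        assert np.isnan(vis["ndvi"]).all()
        assert np.isnan(vis["sr"]).all()


class TestCoverage:
    def _stack_with_ndvi(self, v, shape=(30, 30)):
        data = np.zeros(shape + (4,))
        data[:, :, 3] = 0.2 * (1 + v)
        data[:, :, 1] = 0.2 * (1 - v)
        return make_stack(data)

    def test_full_coverage(self):
        stack = self._stack_with_ndvi(0.9)
        ndvi = compute_ndvi(stack)
        _, cov = crown_mask_and_coverage(ndvi, (4.5, 4.5), stack.transform)
        assert cov == 1.0

    def test_zero_coverage(self):
        stack = self._stack_with_ndvi(0.3)
        ndvi = compute_ndvi(stack)
        _, cov = crown_mask_and_coverage(ndvi, (4.5, 4.5), stack.transform)
        assert cov == 0.0

    def test_half_disk_coverage(self):
        # left half of the raster above the threshold, centered buffer:
        # by symmetry exactly half the buffer pixels are crown
        stack = self._stack_with_ndvi(0.3)
        v = 0.9
        stack.data[:, :15, 3] = 0.2 * (1 + v)
        stack.data[:, :15, 1] = 0.2 * (1 - v)
        ndvi = compute_ndvi(stack)
        mask, cov = crown_mask_and_coverage(ndvi, (4.5, 4.5), stack.transform)
        assert cov == pytest.approx(0.5)

    def test_buffer_outside_raster_rejected(self):
        stack = self._stack_with_ndvi(0.9, shape=(10, 10))
        ndvi = compute_ndvi(stack)
        with pytest.raises(ValueError, match="outside"):
            crown_mask_and_coverage(ndvi, (0.5, 0.5), stack.transform)

    def test_coverage_monotone_in_threshold(self, small_orchard):
        _, stack, inv, _ = small_orchard
        ndvi = compute_ndvi(stack)
        rec = inv.table.iloc[7]
        covs = [
            crown_mask_and_coverage(
                ndvi, (rec["x"], rec["y"]), stack.transform, ndvi_thresh=t
            )[1]
            for t in (0.3, 0.5, 0.7)
        ]
        assert covs[0] >= covs[1] >= covs[2]


class TestZonalMeans:
    def test_constant_raster(self):
        vis = {"ndvi": np.full((5, 5), 0.7)}
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = mask[3, 3] = True
        assert vi_zonal_means(vis, mask)["ndvi"] == pytest.approx(0.7)

    def test_two_pixel_mean(self):
        vis = {"x": np.array([[0.2, 0.4]])}
        mask = np.array([[True, True]])
        assert vi_zonal_means(vis, mask)["x"] == pytest.approx(0.3)

    def test_empty_mask_gives_nan(self):
        vis = {"x": np.ones((3, 3))}
        out = vi_zonal_means(vis, np.zeros((3, 3), dtype=bool))
        assert np.isnan(out["x"])


class TestGLCM:
    def test_constant_window_degenerate_values(self):
        q = np.zeros((5, 5), dtype=np.intp)
        m = glcm_measures(glcm_matrix(q, levels=8))
        assert m["contrast"] == 0.0
        assert m["dissimilarity"] == 0.0
        assert m["homogeneity"] == pytest.approx(1.0)
        assert m["asm"] == pytest.approx(1.0)
        assert m["entropy"] == pytest.approx(0.0)

    def test_checkerboard_correlation_minus_one(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        # 0-degree offset only: every horizontal neighbor pair differs
        counts = np.zeros((2, 2))
        a = img[:, :-1].ravel()
        b = img[:, 1:].ravel()
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
        p = counts / counts.sum()
        assert glcm_measures(p)["correlation"] == pytest.approx(-1.0)

    def test_toy_image_matches_brute_force(self):
        img = np.array([[0, 1, 1], [2, 0, 1], [2, 2, 0]], dtype=np.intp)
        ours = glcm_measures(glcm_matrix(img, levels=3))
        oracle = brute_force_measures(brute_force_glcm(img, 3))
        for k in TEXTURE_MEASURES:
            assert ours[k] == pytest.approx(oracle[k], abs=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(2, 5),
        st.integers(2, 5),
        st.integers(2, 6),
        st.integers(0, 2**31 - 1),
    )
    def test_property_sweep_matches_brute_force(self, h, w, levels, seed):
        img = np.random.default_rng(seed).integers(0, levels, (h, w))
        ours = glcm_measures(glcm_matrix(img, levels))
        oracle = brute_force_measures(brute_force_glcm(img, levels))
        for k in TEXTURE_MEASURES:
            assert ours[k] == pytest.approx(oracle[k], abs=1e-10)

    def test_matches_scikit_image(self):
        # independent library cross-check on the shared measures
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(5)
        img = rng.integers(0, 8, (9, 9)).astype(np.uint8)
        ours = glcm_measures(glcm_matrix(img, 8))
        sk = graycomatrix(
            img, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=8, symmetric=True, normed=False,
        )
        p = sk[:, :, 0, :].sum(axis=2).astype(float)
        p = p / p.sum()
        for name, sk_name in (
            ("contrast", "contrast"),
            ("dissimilarity", "dissimilarity"),
            ("homogeneity", "homogeneity"),
        ):
            total = 0.0
            # graycoprops averages per angle; compare on the summed matrix
            i = np.arange(8)
            diff = i[:, None] - i[None, :]
            ref = {
                "contrast": (p * diff**2).sum(),
                "dissimilarity": (p * np.abs(diff)).sum(),
                "homogeneity": (p / (1 + diff**2)).sum(),
            }[sk_name]
            assert ours[name] == pytest.approx(ref, abs=1e-10)

    def test_quantize_constant_image(self):
        assert (quantize(np.full((4, 4), 0.3), 32) == 0).all()


class TestFeatureTable:
    def test_shape_and_column_count(self, medium_orchard):
        _, stack, inv, _ = medium_orchard
        table = assemble_feature_table(stack, inv)
        assert len(table.vi_columns) == 14  # 13 VIs + fractional coverage
        assert len(table.texture_columns) == 32
        assert len(table.feature_columns) == 46

    def test_identical_trees_identical_rows(self):
        # a flat raster: every tree sees the same block content
        stack = uniform_stack(60, 60, green=0.1, red=0.05, red_edge=0.3, nir=0.5)
        import pandas as pd

        from orchardyield.io import TreeInventory

        inv = TreeInventory(
            pd.DataFrame(
                {
                    "tree_id": ["a", "b"],
                    "x": [6.0, 12.0],
                    "y": [6.0, 12.0],
                    "yield_kg": [50.0, 50.0],
                }
            )
        )
        table = assemble_feature_table(stack, inv)
        a = table.table[table.feature_columns].iloc[0]
        b = table.table[table.feature_columns].iloc[1]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_edge_trees_skipped_with_reason(self, small_orchard, caplog):
        import pandas as pd

        from orchardyield.io import TreeInventory

        _, stack, inv, _ = small_orchard
        df = pd.concat(
            [
                inv.table,
                pd.DataFrame(
                    {"tree_id": ["edge"], "x": [0.4], "y": [0.4],
                     "row_index": [-1], "yield_kg": [np.nan]}
                ),
            ],
            ignore_index=True,
        )
        table = assemble_feature_table(stack, TreeInventory(df))
        assert "edge" not in set(table.table["tree_id"])
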
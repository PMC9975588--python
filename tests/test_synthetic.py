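"""Synthetic orchard generator: geometry, moments, spectra, determinism."""

import numpy as np
import pandas as pd
import pytest

from orchardyield.segmentation import compute_ndvi
from orchardyield.synthetic import (
    GroundTruth,
    OrchardParams,
    generate_layout,
    generate_orchard,
    generate_yield_surface,
    render_reflectance,
)


def _manual_truth(rows):
    """Build a GroundTruth table by hand for controlled rendering."""
    df = pd.DataFrame(
        rows,
        columns=["tree_id", "x", "y", "row_index", "crown_radius_m", "fertility"],
    )
    df["yield_kg"] = 50.0
    return GroundTruth(df)


class TestLayout:
    def test_zero_jitter_gives_exact_grid(self):
        p = OrchardParams(n_rows=2, trees_per_row=3, jitter_sd_m=0.0, seed=0)
        layout = generate_layout(p)
        assert len(layout) == 6
        xs = np.sort(layout.table["x"].unique())
        ys = np.sort(layout.table["y"].unique())
        np.testing.assert_allclose(np.diff(xs), 6.0)
        np.testing.assert_allclose(np.diff(ys), 4.5)

    def test_same_seed_identical_layout(self):
        p = OrchardParams(n_rows=3, trees_per_row=4, seed=5)
        a, b = generate_layout(p), generate_layout(p)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_single_tree_orchard(self):
        p = OrchardParams(n_rows=1, trees_per_row=1, jitter_sd_m=0.0, seed=0)
        layout = generate_layout(p)
        assert len(layout) == 1
        assert layout.table["x"].iloc[0] == pytest.approx(p.margin_m)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            OrchardParams(row_spacing_m=0.0)

    def test_crown_radii_truncated_above_half_meter(self):
        p = OrchardParams(
            n_rows=5, trees_per_row=20, crown_radius_mean_m=0.8,
            crown_radius_sd_m=0.5, seed=1,
        )
        layout = generate_layout(p)
        assert (layout.table["crown_radius_m"] > 0.5).all()


class TestYieldSurface:
    def test_degenerate_constants_give_constant_yield(self):
        p = OrchardParams(n_rows=2, trees_per_row=3, seed=0)
        layout = generate_layout(p)
        truth = generate_yield_surface(
            layout, p, coefficients=(0.8, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        )
        np.testing.assert_allclose(
            truth.table["yield_kg"], p.yield_mean_kg * 0.8
        )

    def test_configured_moments_recovered(self):
        # Monte-Carlo calibration check: 5 independent orchards x 1000
        # trees; grand mean within 3 empirical SE of the target, pooled CV
        # within 10% relative of the target.
        means, all_yields = [], []
        for seed in range(5):
            p = OrchardParams(n_rows=10, trees_per_row=100, seed=100 + seed)
            layout = generate_layout(p)
            truth = generate_yield_surface(layout, p)
            y = truth.table["yield_kg"].to_numpy()
            means.append(y.mean())
            all_yields.append(y)
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 53.1) <= 3 * se + 0.5
        y = np.concatenate(all_yields)
        # CV about the configured mean, pooling realizations
        cv = y.std() / 53.1
        assert cv == pytest.approx(0.331, rel=0.10)

    def test_fertility_spatially_correlated(self):
        # near pair (1 m) vs far pair (200 m), correlation across 200 seeds
        df = pd.DataFrame(
            {
                "tree_id": ["a", "b", "c"],
                "x": [0.0, 0.0, 0.0],
                "y": [0.0, 1.0, 200.0],
                "row_index": [0, 0, 0],
                "crown_radius_m": [2.2, 2.2, 2.2],
                "fertility": np.nan,
                "yield_kg": np.nan,
            }
        )
        p = OrchardParams(seed=0)
        ferts = np.array(
            [
                generate_yield_surface(GroundTruth(df.copy()), p, seed=s)
                .table["fertility"]
                .to_numpy()
                for s in range(200)
            ]
        )
        near = np.corrcoef(ferts[:, 0], ferts[:, 1])[0, 1]
        far = np.corrcoef(ferts[:, 0], ferts[:, 2])[0, 1]
        assert near > far
        assert near > 0.8  # 1 m apart under a 30 m correlation length

    def test_yields_nonnegative(self):
        p = OrchardParams(n_rows=5, trees_per_row=40, yield_cv=0.9, seed=3)
        layout = generate_layout(p)
        truth = generate_yield_surface(layout, p)
        assert (truth.table["yield_kg"] >= 0).all()


class TestRender:
    def test_core_vs_soil_ndvi(self):
        truth = _manual_truth([["t0", 6.0, 6.0, 0, 2.0, 0.5]])
        p = OrchardParams(reflectance_noise_sd=0.0, seed=0)
        stack = render_reflectance(truth, p)
        ndvi = compute_ndvi(stack)
        row, col = stack.transform.locate(6.0, 6.0)
        assert ndvi[row, col] > 0.6
        assert ndvi[2, 2] < 0.3  # far corner = soil

    def test_core_ndvi_exceeds_lowest_threshold_at_low_fertility(self):
        # segmentability guarantee: fertility 0.2 must still exceed 0.60
        truth = _manual_truth([["t0", 6.0, 6.0, 0, 2.0, 0.2]])
        p = OrchardParams(reflectance_noise_sd=0.0, seed=0)
        stack = render_reflectance(truth, p)
        ndvi = compute_ndvi(stack)
        row, col = stack.transform.locate(6.0, 6.0)
        assert ndvi[row, col] > 0.60

    def test_red_edge_monotone_in_fertility(self):
        rows_hi = [["t0", 6.0, 6.0, 0, 2.0, 1.0]]
        rows_lo = [["t0", 6.0, 6.0, 0, 2.0, 0.0]]
        p = OrchardParams(reflectance_noise_sd=0.0, seed=0)
        hi = render_reflectance(_manual_truth(rows_hi), p)
        lo = render_reflectance(_manual_truth(rows_lo), p)
        m_hi = hi.band("red_edge").mean()
        m_lo = lo.band("red_edge").mean()
        assert m_hi > m_lo

    def test_vigor_pattern_invisible_to_crown_mean_but_visible_at_core(self):
        # +1 vs -1 pattern: crown-mask mean red-edge barely moves (the
        # radial mode integrates to ~zero over the detected crown) while
        # the core pixel shifts by ~2 * pattern_contrast
        p = OrchardParams(reflectance_noise_sd=0.0, seed=0)
        stacks = {}
        for q in (+1.0, -1.0):
            df = _manual_truth([["t0", 6.0, 6.0, 0, 2.0, 0.6]]).table
            df["vigor_pattern"] = q
            stacks[q] = render_reflectance(GroundTruth(df), p)
        ndvi = compute_ndvi(stacks[1.0])
        from orchardyield.features import crown_mask_and_coverage

        mask, _ = crown_mask_and_coverage(
            ndvi, (6.0, 6.0), stacks[1.0].transform
        )
        mean_hi = stacks[1.0].band("red_edge")[mask].mean()
        mean_lo = stacks[-1.0].band("red_edge")[mask].mean()
        row, col = stacks[1.0].transform.locate(6.0, 6.0)
        core_hi = stacks[1.0].band("red_edge")[row, col]
        core_lo = stacks[-1.0].band("red_edge")[row, col]
        assert abs(mean_hi - mean_lo) < 0.02
        # the sampled pixel center sits slightly off the true center, so
        # the radial mode there is a bit below its maximum of 1
        assert core_hi - core_lo == pytest.approx(
            2 * p.pattern_contrast, rel=0.2
        )

    def test_same_seed_bit_identical_raster(self):
        p = OrchardParams(n_rows=2, trees_per_row=3, seed=9)
        a, *_ = generate_orchard(p)
        b, *_ = generate_orchard(p)
        np.testing.assert_array_equal(a.data, b.data)

    def test_incomplete_truth_rejected(self):
        p = OrchardParams(n_rows=1, trees_per_row=1, seed=0)
        layout = generate_layout(p)
        with pytest.raises(ValueError, match="fertility"):
            render_reflectance(layout, p)


class TestGenerateOrchard:
    def test_sampling_stride_hides_yields(self):
        p = OrchardParams(n_rows=21, trees_per_row=2, seed=0)
        _, inv, truth = generate_orchard(p, sampling_stride=7)
        visible_rows = inv.labelled["row_index"].unique()
        assert len(visible_rows) == 3
        assert truth.table["yield_kg"].notna().all()

    def test_stride_one_labels_all(self):
        p = OrchardParams(n_rows=3, trees_per_row=2, seed=0)
        _, inv, _ = generate_orchard(p, sampling_stride=1)
        assert len(inv.labelled) == len(inv)

    def test_footprint_covers_layout(self):
        p = OrchardParams(n_rows=10, trees_per_row=20, seed=0)
        stack, _, _ = generate_orchard(p)
        xmin, ymin, xmax, ymax = stack.transform.bounds(stack.shape)
        assert xmax - xmin >= 10 * 6.0 * (9 / 10)  # (n_rows-1) spacings + margins
        assert ymax - ymin >= 20 * 4.5 * (19 / 20)

    def test_all_reflectance_in_unit_interval(self, small_orchard):
        _, stack, _, _ = small_orchard
        assert stack.data.min() >= 0.0 and stack.data.max() <= 1.0
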
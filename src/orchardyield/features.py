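"""Hand-engineered per-tree features for the baseline regressors.

46 features per tree:

* 13 vegetation indices (structure / greenness / chlorophyll families)
  averaged over crown pixels inside a 2.5 m circular buffer,
* 1 fractional crown coverage (share of buffer pixels with NDVI > 0.5),
* 32 gray-level co-occurrence (GLCM) texture measures: 8 measures
  (contrast, dissimilarity, homogeneity, angular second moment,
  correlation, mean, variance, entropy) x 4 bands, computed on the
  tree block with distance-1 offsets in four directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from orchardyield.blocks import clip_block, locate_pixel
from orchardyield.io import BandStack, TreeInventory

logger = logging.getLogger("orchardyield")

#: Vegetation indices computed by :func:`compute_vi_suite`, in column order.
VI_NAMES: tuple[str, ...] = (
    "ndvi",
    "ndre",
    "gndvi",
    "evi2",
    "savi",
    "osavi",
    "msavi",
    "rdvi",
    "sr",
    "ci_red_edge",
    "ci_green",
    "mtci",
    "grvi",
)

#: GLCM texture measures, in column order.
TEXTURE_MEASURES: tuple[str, ...] = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "correlation",
    "mean",
    "variance",
    "entropy",
)

#: distance-1 offsets (drow, dcol) for directions 0, 45, 90, 135 degrees
GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class FeatureTable:
    """Per-tree engineered features keyed by ``tree_id``.

    Columns: 13 VI crown means, ``frac_coverage``, then 32 texture
    features named ``tex_<measure>_<band>``.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def vi_columns(self) -> list[str]:
        return [f"vi_{n}" for n in VI_NAMES] + ["frac_coverage"]

    @property
    def texture_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("tex_")]

    @property
    def feature_columns(self) -> list[str]:
        return self.vi_columns + self.texture_columns


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out


def compute_vi_suite(stack: BandStack) -> dict[str, np.ndarray]:
    """Per-pixel rasters for the 13 vegetation indices.

    All divisions are guarded: undefined pixels become NaN. Normalized
    difference indices lie in [-1, 1] by construction.
    """
    g = stack.band("green")
    r = stack.band("red")
    re = stack.band("red_edge")
    n = stack.band("nir")
    vis = {
        "ndvi": _safe_div(n - r, n + r),
        "ndre": _safe_div(n - re, n + re),
        "gndvi": _safe_div(n - g, n + g),
        "evi2": 2.5 * _safe_div(n - r, n + 2.4 * r + 1.0),
        "savi": 1.5 * _safe_div(n - r, n + r + 0.5),
        "osavi": _safe_div(n - r, n + r + 0.16),
        "msavi": 0.5
        * (2.0 * n + 1.0 - np.sqrt(np.clip((2.0 * n + 1.0) ** 2 - 8.0 * (n - r), 0.0, None))),
        "rdvi": _safe_div(n - r, np.sqrt(np.clip(n + r, 0.0, None))),
        "sr": _safe_div(n, r),
        "ci_red_edge": _safe_div(n, re) - 1.0,
        "ci_green": _safe_div(n, g) - 1.0,
        "mtci": _safe_div(n - re, re - r),
        "grvi": _safe_div(g - r, g + r),
    }
    return vis


def crown_mask_and_coverage(
    ndvi: np.ndarray,
    center_xy: tuple[float, float],
    transform,
    buffer_radius_m: float = 2.5,
    ndvi_thresh: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Crown mask and fractional coverage inside a circular buffer.

    The mask selects pixels whose center lies within ``buffer_radius_m`` of
    the tree center AND whose NDVI exceeds ``ndvi_thresh``; coverage is the
    mask size divided by the buffer pixel count — a proxy for crown size.
    Raises ``ValueError`` when the buffer crosses the raster edge.
    """
    n_rows, n_cols = ndvi.shape
    px = transform.pixel_size
    x, y = center_xy
    xmin, ymin, xmax, ymax = transform.bounds((n_rows, n_cols))
    if (
        x - buffer_radius_m < xmin
        or x + buffer_radius_m > xmax
        or y - buffer_radius_m < ymin
        or y + buffer_radius_m > ymax
    ):
        raise ValueError("buffer extends outside the raster")
    r_px = int(np.ceil(buffer_radius_m / px)) + 1
    row_c, col_c = transform.locate(x, y)
    r0, r1 = max(0, row_c - r_px), min(n_rows, row_c + r_px + 1)
    c0, c1 = max(0, col_c - r_px), min(n_cols, col_c + r_px + 1)
    cx = transform.x_origin + (np.arange(c0, c1) + 0.5) * px
    cy = transform.y_origin - (np.arange(r0, r1) + 0.5) * px
    d2 = (cy[:, None] - y) ** 2 + (cx[None, :] - x) ** 2
    in_buffer = d2 <= buffer_radius_m**2
    mask = np.zeros(ndvi.shape, dtype=bool)
    sub = np.nan_to_num(ndvi[r0:r1, c0:c1], nan=-np.inf) > ndvi_thresh
    mask[r0:r1, c0:c1] = in_buffer & sub
    n_buffer = int(in_buffer.sum())
    coverage = float(mask.sum()) / n_buffer if n_buffer else 0.0
    return mask, coverage


def vi_zonal_means(
    vi_rasters: dict[str, np.ndarray], mask: np.ndarray
) -> dict[str, float]:
    """Arithmetic mean of each VI over the masked crown pixels.

    An empty mask yields NaN for every VI (the tree is flagged upstream).
    """
    if not mask.any():
        logger.warning("empty crown mask: VI means undefined")
        return {name: float("nan") for name in vi_rasters}
    return {
        name: float(np.nanmean(raster[mask])) for name, raster in vi_rasters.items()
    }


def quantize(image: np.ndarray, levels: int = 32) -> np.ndarray:
    """Quantize an image to ``levels`` gray levels over its observed range.

    A constant image maps to level 0 everywhere.
    """
    lo, hi = float(np.nanmin(image)), float(np.nanmax(image))
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.intp)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(quantized: np.ndarray, levels: int = 32) -> np.ndarray:
    """Symmetric normalized GLCM, distance 1, four directions summed.

    Offsets are (0,1), (-1,1), (-1,0), (-1,-1); each co-occurring pair is
    counted in both orders (symmetric matrix) before normalization.
    """
    n_rows, n_cols = quantized.shape
    counts = np.zeros((levels, levels), dtype=np.float64)
    for dr, dc in GLCM_OFFSETS:
        r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
        c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
        a = quantized[r0:r1, c0:c1].ravel()
        b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    return counts / total if total else counts


def glcm_measures(p: np.ndarray) -> dict[str, float]:
    """The eight texture measures of a normalized GLCM.

    For a constant window (single nonzero cell) the degenerate values are
    contrast 0, dissimilarity 0, homogeneity 1, ASM 1, entropy 0;
    correlation is defined as 0 when either marginal variance vanishes.
    """
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)
    diff = i[:, None] - i[None, :]
    mu_i = float((i[:, None] * p).sum())
    mu_j = float((i[None, :] * p).sum())
    var_i = float(((i[:, None] - mu_i) ** 2 * p).sum())
    var_j = float(((i[None, :] - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        corr = float(
            (((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum())
            / np.sqrt(var_i * var_j)
        )
    else:
        corr = 0.0
    nz = p[p > 0]
    return {
        "contrast": float((diff**2 * p).sum()),
        "dissimilarity": float((np.abs(diff) * p).sum()),
        "homogeneity": float((p / (1.0 + diff**2)).sum()),
        "asm": float((p**2).sum()),
        "correlation": corr,
        "mean": mu_i,
        "variance": var_i,
        "entropy": float(-(nz * np.log(nz)).sum()),
    }


def glcm_texture_features(
    stack: BandStack,
    center: tuple[int, int],
    window_radius_px: int = 10,
    levels: int = 32,
) -> dict[str, float]:
    """32 texture features (8 measures x 4 bands) for one tree block.

    The window (default the full 21 x 21 tree block) is quantized per band
    to ``levels`` gray levels over its observed range; the symmetric
    distance-1 four-direction GLCM is accumulated, normalized, and the
    eight measures computed.
    """
    block = clip_block(stack, center, window_radius_px)
    out: dict[str, float] = {}
    for b, band in enumerate(stack.band_names):
        q = quantize(block[:, :, b], levels)
        measures = glcm_measures(glcm_matrix(q, levels))
        for m in TEXTURE_MEASURES:
            out[f"tex_{m}_{band}"] = measures[m]
    return out


def assemble_feature_table(
    stack: BandStack,
    inventory: TreeInventory,
    buffer_radius_m: float = 2.5,
    coverage_ndvi_thresh: float = 0.5,
    window_radius_px: int = 10,
    levels: int = 32,
) -> FeatureTable:
    """Full 46-column feature table for every feasible tree.

    Trees whose buffer or texture window crosses the raster edge are
    skipped with a logged reason. Column order is stable:
    13 VI means, fractional coverage, 32 textures.
    """
    if len(inventory) == 0:
        raise ValueError("inventory is empty")
    vis = compute_vi_suite(stack)
    ndvi = vis["ndvi"]
    rows = []
    for _, rec in inventory.table.iterrows():
        try:
            mask, coverage = crown_mask_and_coverage(
                ndvi,
                (rec["x"], rec["y"]),
                stack.transform,
                buffer_radius_m,
                coverage_ndvi_thresh,
            )
            row_c, col_c = locate_pixel(
                rec["x"], rec["y"], stack.transform, stack.shape
            )
            tex = glcm_texture_features(stack, (row_c, col_c), window_radius_px, levels)
        except ValueError as exc:
            logger.warning("tree %s skipped in feature table: %s", rec["tree_id"], exc)
            continue
        means = vi_zonal_means(vis, mask)
        row = {"tree_id": rec["tree_id"], "yield_kg": rec["yield_kg"]}
        row.update({f"vi_{name}": means[name] for name in VI_NAMES})
        row["frac_coverage"] = coverage
        row.update(tex)
        rows.append(row)
    if not rows:
        raise ValueError("no trees produced features")
    return FeatureTable(pd.DataFrame(rows))
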
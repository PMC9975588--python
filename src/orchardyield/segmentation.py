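"""Multi-threshold NDVI crown segmentation.

A single NDVI threshold cannot delineate every tree in a mature orchard:
low thresholds merge adjacent crowns into multi-tree blobs, high thresholds
miss small or weak trees. The multi-stage procedure therefore

1. computes NDVI per pixel,
2. segments the NDVI raster at several thresholds (seven over
   [0.60, 0.83] by default), producing one candidate crown layer each,
3. removes polygons whose major axis exceeds the in-row tree spacing
   (a single crown cannot be wider than the planting spacing),
4. merges the filtered layers from low to high threshold: a smaller
   high-threshold polygon is dropped iff it lies spatially within an
   already-kept larger polygon, otherwise added — keeping the largest
   valid polygon per tree while recovering trees the low threshold merged,
5. extracts tree centers as polygon centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import box, union_all
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from orchardyield.io import BandStack, GeoTransform, TreeInventory

logger = logging.getLogger("orchardyield")


@dataclass
class CrownPolygon:
    """One candidate or final crown."""

    geometry: BaseGeometry
    pixel_count: int
    major_axis_m: float
    source_threshold: float
    tree_id: str | None = None

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.geometry.centroid
        return (c.x, c.y)


@dataclass
class CrownLayer:
    """Candidate crown polygons from a single NDVI threshold."""

    threshold: float
    polygons: list[CrownPolygon] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.polygons)


@dataclass
class CrownMap:
    """Final merged, containment-free crown polygons with centroids."""

    polygons: list[CrownPolygon] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.polygons)

    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.polygons]).reshape(-1, 2)


def compute_ndvi(stack: BandStack) -> np.ndarray:
    """Per-pixel NDVI = (NIR - Red) / (NIR + Red), NaN where undefined.

    Pixels with NIR + Red == 0 (and any input nodata) become NaN rather
    than propagating a divide warning.
    """
    nir = stack.band("nir")
    red = stack.band("red")
    denom = nir + red
    ndvi = np.full(nir.shape, np.nan)
    ok = denom > 0
    if stack.mask is not None:
        ok &= ~stack.mask
    np.divide(nir - red, denom, out=ndvi, where=ok)
    return ndvi


def _polygon_from_component(
    rows: np.ndarray, cols: np.ndarray, transform: GeoTransform
) -> BaseGeometry:
    """Union of pixel footprints (map coordinates) for one component."""
    px = transform.pixel_size
    x0 = transform.x_origin + cols * px
    y1 = transform.y_origin - rows * px
    boxes = box(x0, y1 - px, x0 + px, y1)
    return union_all(boxes)


def _major_axis_m(geom: BaseGeometry) -> float:
    """Longer side of the minimum rotated bounding rectangle."""
    mrr = geom.minimum_rotated_rectangle
    if isinstance(mrr, Polygon):
        pts = np.asarray(mrr.exterior.coords)[:4]
        sides = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)[:2]
        return float(sides.max())
    return float(geom.length)  # degenerate (line/point)


def threshold_segment(
    ndvi: np.ndarray,
    t: float,
    transform: GeoTransform,
    min_pixels: int = 3,
) -> CrownLayer:
    """Polygonize 8-connected components of {NDVI >= t}.

    Components smaller than ``min_pixels`` are dropped as noise.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = np.nan_to_num(ndvi, nan=-np.inf) >= t
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    layer = CrownLayer(threshold=t)
    if n == 0:
        return layer
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        sub = labels[sl] == lab
        count = int(sub.sum())
        if count < min_pixels:
            continue
        rr, cc = np.nonzero(sub)
        geom = _polygon_from_component(
            rr + sl[0].start, cc + sl[1].start, transform
        )
        layer.polygons.append(
            CrownPolygon(
                geometry=geom,
                pixel_count=count,
                major_axis_m=_major_axis_m(geom),
                source_threshold=t,
            )
        )
    return layer


def filter_multi_tree(layer: CrownLayer, max_diameter_m: float = 4.5) -> CrownLayer:
    """Drop polygons whose major axis exceeds the tree spacing.

    A single crown's diameter cannot exceed the spacing between adjacent
    trees, so longer polygons must contain multiple trees. Comparison is
    inclusive: a polygon with major axis exactly ``max_diameter_m`` is kept.
    """
    if max_diameter_m <= 0:
        raise ValueError("max_diameter_m must be > 0")
    kept = [p for p in layer.polygons if p.major_axis_m <= max_diameter_m]
    dropped = len(layer.polygons) - len(kept)
    if dropped:
        logger.debug(
            "threshold %.3f: removed %d multi-tree polygon(s)", layer.threshold, dropped
        )
    return CrownLayer(threshold=layer.threshold, polygons=kept)


def _spatially_within(
    candidate: BaseGeometry,
    container: BaseGeometry,
    min_overlap: float = 0.9,
) -> bool:
    """Containment tolerant of raster-polygonization slivers.

    True when the candidate's representative interior point falls inside
    the container and at least ``min_overlap`` of the candidate's area
    overlaps it.
    """
    if not container.contains(candidate.representative_point()):
        return False
    if candidate.area == 0:
        return True
    return candidate.intersection(container).area >= min_overlap * candidate.area


def merge_layers(
    layers: list[CrownLayer], min_overlap: float = 0.9
) -> CrownMap:
    """Combine filtered candidate layers into the final crown map.

    Layers are processed from the lowest threshold (largest surviving
    polygons) upward. A higher-threshold candidate is discarded iff it lies
    spatially within a polygon already kept from a lower threshold;
    otherwise it is added. The result is containment-free and keeps the
    largest valid polygon per tree.
    """
    if not layers:
        logger.warning("merge_layers called with no layers; empty crown map")
        return CrownMap()
    ordered = sorted(layers, key=lambda l: l.threshold)
    final: list[CrownPolygon] = []
    for layer in ordered:
        for cand in layer.polygons:
            if any(
                _spatially_within(cand.geometry, kept.geometry, min_overlap)
                for kept in final
            ):
                continue
            final.append(cand)
    return CrownMap(polygons=final)


def extract_centroids(crowns: CrownMap) -> TreeInventory:
    """One centroid per final crown, with row-major sequential tree ids.

    Ids are assigned scanning from the map's top (max y) downward and left
    to right, so numbering is stable for a given crown map.
    """
    if not crowns.polygons:
        raise ValueError("crown map is empty")
    cents = crowns.centroids()
    order = np.lexsort((cents[:, 0], -cents[:, 1]))
    records = []
    for rank, idx in enumerate(order):
        tid = f"C{rank:05d}"
        crowns.polygons[idx].tree_id = tid
        records.append(
            {"tree_id": tid, "x": cents[idx, 0], "y": cents[idx, 1], "row_index": -1}
        )
    return TreeInventory(pd.DataFrame(records))


def segment_crowns(
    stack: BandStack,
    thresholds: tuple[float, ...] = (),
    max_diameter_m: float = 4.5,
    min_pixels: int = 3,
    min_overlap: float = 0.9,
) -> tuple[CrownMap, list[CrownLayer]]:
    """Full multi-stage segmentation: NDVI -> layers -> filter -> merge."""
    if not thresholds:
        thresholds = tuple(np.linspace(0.60, 0.83, 7).round(6))
    ndvi = compute_ndvi(stack)
    layers = [
        filter_multi_tree(
            threshold_segment(ndvi, t, stack.transform, min_pixels=min_pixels),
            max_diameter_m,
        )
        for t in thresholds
    ]
    crowns = merge_layers(layers, min_overlap=min_overlap)
    logger.info(
        "segmented %d final crowns from %d threshold layers",
        len(crowns),
        len(layers),
    )
    return crowns, layers
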
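"""Raster, vector and tabular I/O plus run configuration.

Conventions
-----------
* Pixel indices are 0-based ``(row, col)``; the map coordinate of a pixel is
  its **center** under the affine geotransform; polygons live in map
  coordinates (meters).
* Reflectance is stored as float in ``[0, 1]``. Integer-scaled rasters
  (0-10000 convention) are rescaled on read when the dtype indicates.
* Rasters are north-up with square pixels; band order is normalized to
  ``(green, red, red_edge, nir)`` on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("orchardyield")

#: Canonical spectral band order used throughout the package.
CANONICAL_BANDS: tuple[str, ...] = ("green", "red", "red_edge", "nir")

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


class RasterFormatError(ValueError):
    """Raised for rasters that violate the 4-band georeferenced contract."""


class InventoryError(ValueError):
    """Raised for malformed tree tables."""


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine geotransform with square pixels.

    ``x_origin``/``y_origin`` are the map coordinates of the **top-left
    corner** of pixel (0, 0); ``pixel_size`` is the edge length in meters.
    Row index increases southwards (decreasing y), matching the GeoTIFF
    convention.
    """

    x_origin: float
    y_origin: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def pixel_center(self, row, col):
        """Map coordinates of the center of pixel ``(row, col)``."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def locate(self, x: float, y: float) -> tuple[int, int]:
        """Indices of the pixel whose footprint contains map point (x, y)."""
        col = int(np.floor((x - self.x_origin) / self.pixel_size))
        row = int(np.floor((self.y_origin - y) / self.pixel_size))
        return row, col

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) footprint for a raster of ``shape``."""
        n_rows, n_cols = shape
        return (
            self.x_origin,
            self.y_origin - n_rows * self.pixel_size,
            self.x_origin + n_cols * self.pixel_size,
            self.y_origin,
        )


@dataclass
class BandStack:
    """A 4-band reflectance raster with named bands and a geotransform.

    ``data`` has shape (rows, cols, 4) with dimensionless reflectance in
    [0, 1]; invalid pixels are flagged in the optional boolean ``mask``
    (True = nodata) and excluded from statistics downstream.
    """

    data: np.ndarray
    band_names: tuple[str, ...]
    transform: GeoTransform
    crs_label: str = "local-meters"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.band_names):
            raise RasterFormatError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.band_names)} band names"
            )
        if not 1 <= len(self.band_names) <= 4:
            raise RasterFormatError(
                "BandStack requires 1-4 spectral bands, got "
                f"{len(self.band_names)}"
            )
        valid = self.data[~self.mask] if self.mask is not None else self.data
        if valid.size and (
            not np.all(np.isfinite(valid))
            or valid.min() < 0.0
            or valid.max() > 1.0
        ):
            raise RasterFormatError(
                "reflectance values must be finite and in [0, 1] "
                "(or flagged in the nodata mask)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def band(self, name: str) -> np.ndarray:
        """Return one band as a 2-D array."""
        return self.data[:, :, self.band_names.index(name)]

    def select_bands(self, names: Sequence[str]) -> "BandStack":
        """A stack restricted to ``names`` (order preserved).

        Full imagery substrates always carry 4 bands; reduced stacks exist
        only for the band-ablation harness.
        """
        idx = [self.band_names.index(n) for n in names]
        return replace(self, data=self.data[:, :, idx], band_names=tuple(names))


@dataclass
class TreeInventory:
    """Per-tree records: id, map coordinates, row index, measured yield.

    Missing yields are NaN (never silently zero). Backed by a DataFrame
    with columns ``tree_id, x, y, row_index, yield_kg``.
    """

    table: pd.DataFrame

    REQUIRED = ("tree_id", "x", "y")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise InventoryError(f"missing required column {col!r}")
        if "row_index" not in df.columns:
            df["row_index"] = -1
        if "yield_kg" not in df.columns:
            df["yield_kg"] = np.nan
        df["tree_id"] = df["tree_id"].astype(str)
        dup = df["tree_id"][df["tree_id"].duplicated()].unique()
        if len(dup):
            raise InventoryError(f"duplicate tree_id values: {', '.join(dup)}")
        for col in ("x", "y", "yield_kg"):
            try:
                df[col] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                raise InventoryError(f"non-numeric values in column {col!r}") from exc
        if (df["yield_kg"].dropna() < 0).any():
            raise InventoryError("negative yield_kg")
        df["row_index"] = df["row_index"].astype(int)
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labelled(self) -> pd.DataFrame:
        """Rows with a measured yield."""
        return self.table[self.table["yield_kg"].notna()]


@dataclass
class RunConfig:
    """Configuration shared across pipeline stages."""

    block_radius_px: int = 10
    ndvi_thresholds: tuple[float, ...] = ()
    max_crown_diameter_m: float = 4.5
    cv_folds: int = 5
    seed: int = 0
    max_trials: int = 50
    batch_size: int = 128
    epochs: int = 100
    min_pixels: int = 3

    def __post_init__(self) -> None:
        if not self.ndvi_thresholds:
            self.ndvi_thresholds = tuple(np.linspace(0.60, 0.83, 7).round(6))
        t = np.asarray(self.ndvi_thresholds, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("ndvi_thresholds must be strictly increasing")
        if t.min() <= 0 or t.max() >= 1:
            raise ValueError("ndvi_thresholds must lie in (0, 1)")
        if self.block_radius_px < 1:
            raise ValueError("block_radius_px must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ndvi_thresholds" in raw:
            raw["ndvi_thresholds"] = tuple(raw["ndvi_thresholds"])
        return cls(**raw)


def default_thresholds(lo: float = 0.60, hi: float = 0.83, n: int = 7) -> tuple[float, ...]:
    """Evenly spaced NDVI segmentation thresholds over [lo, hi]."""
    return tuple(np.linspace(lo, hi, n).round(6))


# ---------------------------------------------------------------------------
# raster I/O


def write_band_stack(stack: BandStack, path: str | Path) -> Path:
    """Write a BandStack as a GeoTIFF with geo-tags and band metadata."""
    path = Path(path)
    desc = json.dumps(
        {"band_names": list(stack.band_names), "crs_label": stack.crs_label}
    )
    t = stack.transform
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (t.pixel_size, t.pixel_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
    ]
    tifffile.imwrite(
        path,
        stack.data.astype(np.float64),
        photometric="minisblack",
        planarconfig="contig",
        description=desc,
        extratags=extratags,
    )
    return path


def read_band_stack(
    path: str | Path,
    band_order: Sequence[str] | None = None,
    scale: float | None = None,
) -> BandStack:
    """Read a GeoTIFF into a BandStack with canonical band order.

    Parameters
    ----------
    band_order
        Names of the bands as stored in the file, when they differ from the
        canonical order and the file carries no band metadata.
    scale
        Reflectance scale divisor for integer rasters; defaults to 10000
        for integer dtypes, 1 otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        tags = page.tags
        desc = None
        if "ImageDescription" in tags:
            try:
                desc = json.loads(tags["ImageDescription"].value)
            except (json.JSONDecodeError, TypeError):
                desc = None
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise RasterFormatError(
                f"{path.name}: not georeferenced (missing GeoTIFF model tags)"
            )
        px = float(tags[_MODEL_PIXEL_SCALE].value[0])
        tie = tags[_MODEL_TIEPOINT].value
        transform = GeoTransform(float(tie[3]), float(tie[4]), px)

    if data.ndim == 3 and data.shape[0] <= 8 < data.shape[1]:
        data = np.moveaxis(data, 0, -1)  # band-first layout
    if data.ndim != 3 or data.shape[2] < 4:
        n = 1 if data.ndim == 2 else data.shape[2]
        raise RasterFormatError(
            f"{path.name}: requires 4 spectral bands, found {n}"
        )

    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / (scale if scale is not None else 10000.0)
    elif scale is not None:
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)

    stored = None
    if desc and "band_names" in desc:
        stored = list(desc["band_names"])
    if band_order is not None:
        stored = list(band_order)
    if stored is None:
        if data.shape[2] != 4:
            raise RasterFormatError(
                f"{path.name}: {data.shape[2]} bands but no band-name mapping"
            )
        stored = list(CANONICAL_BANDS)
    missing = set(CANONICAL_BANDS) - set(stored)
    if missing:
        raise RasterFormatError(
            f"{path.name}: band mapping lacks {sorted(missing)}"
        )
    order = [stored.index(b) for b in CANONICAL_BANDS]
    data = data[:, :, order]
    crs_label = desc.get("crs_label", "unknown") if desc else "unknown"
    return BandStack(
        data=data,
        band_names=CANONICAL_BANDS,
        transform=transform,
        crs_label=crs_label,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def read_tree_table(path: str | Path) -> TreeInventory:
    """Load a per-tree CSV (tree_id, x, y[, row_index, yield_kg])."""
    df = pd.read_csv(path)
    return TreeInventory(df)


def write_tree_table(inventory: TreeInventory, path: str | Path) -> Path:
    path = Path(path)
    inventory.table.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# vector I/O


def write_crown_polygons(crowns, path: str | Path) -> Path:
    """Write a CrownMap (or any crown record list) as GeoJSON.

    Each feature carries the polygon geometry plus centroid coordinates,
    the NDVI threshold the polygon came from, and its major-axis length.
    """
    records = getattr(crowns, "polygons", crowns)
    if not records:
        raise ValueError("no crowns to write")
    features = []
    for rec in records:
        geom: BaseGeometry = rec.geometry
        cx, cy = rec.centroid
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "tree_id": getattr(rec, "tree_id", None),
                    "source_threshold": rec.source_threshold,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "major_axis_m": rec.major_axis_m,
                },
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


def read_crown_polygons(path: str | Path):
    """Read a crown GeoJSON back into (geometry, properties) pairs."""
    with open(path) as fh:
        payload = json.load(fh)
    return [
        (shape(f["geometry"]), f["properties"]) for f in payload["features"]
    ]


def write_point_layer(
    points: Iterable[tuple[float, float]],
    properties: Iterable[dict],
    path: str | Path,
) -> Path:
    """Write a GeoJSON point layer (e.g. the per-tree yield map)."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": props,
        }
        for (x, y), props in zip(points, properties)
    ]
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path
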
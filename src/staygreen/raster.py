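"""Plain TIFF raster I/O with world-file georeferencing, and GeoJSON polygons.

Rasters are single-band float TIFFs (NaN = no data) accompanied by an ESRI
world file (same stem, ``.tfw``) carrying the six-parameter affine
transform.  Only axis-aligned north-up transforms are supported, which is
all a gridded field trial needs.  Plot polygons travel as GeoJSON
FeatureCollections with a ``plot_id`` property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

from .errors import ConfigurationError


@dataclass(frozen=True)
class GridTransform:
    """Axis-aligned geotransform: world = origin + pixel_size * (col, -row)."""

    origin_x: float
    origin_y: float   # top-left corner (y decreases down rows)
    pixel_size: float

    def pixel_centers(self, shape_: tuple[int, int]):
        rows, cols = shape_
        xs = self.origin_x + (np.arange(cols) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(rows) + 0.5) * self.pixel_size
        return xs, ys

    @property
    def crs(self) -> str:
        # planar local CRS; all pipeline layers must share it
        return "EPSG:32632"


def write_raster(path, array: np.ndarray, transform: GridTransform) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    world = [transform.pixel_size, 0.0, 0.0, -transform.pixel_size,
             transform.origin_x + transform.pixel_size / 2,
             transform.origin_y - transform.pixel_size / 2]
    path.with_suffix(".tfw").write_text("\n".join(f"{v:.10f}" for v in world) + "\n")


def read_raster(path) -> tuple[np.ndarray, GridTransform]:
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    tfw = path.with_suffix(".tfw")
    if not tfw.exists():
        raise ConfigurationError(f"missing world file for raster {path}")
    a, rot1, rot2, d, cx, cy = (float(v) for v in tfw.read_text().split())
    if rot1 != 0 or rot2 != 0 or d != -a:
        raise ConfigurationError("only axis-aligned north-up rasters supported")
    return arr, GridTransform(origin_x=cx - a / 2, origin_y=cy + a / 2, pixel_size=a)


def write_plot_polygons(path, polygons: dict) -> None:
    """``polygons``: plot_id -> shapely Polygon."""
    features = [{"type": "Feature",
                 "properties": {"plot_id": str(pid)},
                 "geometry": mapping(poly)}
                for pid, poly in polygons.items()]
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc))


def read_plot_polygons(path) -> dict:
    fc = json.loads(Path(path).read_text())
    out = {}
    for feat in fc["features"]:
        out[feat["properties"]["plot_id"]] = shape(feat["geometry"])
    return out
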
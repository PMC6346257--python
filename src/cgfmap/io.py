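"""Standard-format writers: TIFF rasters, GeoJSON boundaries, CSV tables.

Rasters are plain (multi-band) float TIFFs in abstract pixel coordinates —
there is no coordinate reference system in the synthetic worlds, so no
geo-tags are written. Masked pixels carry the NaN nodata sentinel.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import box, mapping
from shapely.ops import unary_union

NODATA = np.nan


def write_raster(path, values: np.ndarray, grid, mask: bool = True) -> None:
    """Write a per-pixel field (P,) or stack (P, B) as a TIFF raster."""
    arr = np.asarray(values, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if mask:
        arr = arr.copy()
        arr[grid.mask] = NODATA
    img = arr.T.reshape(arr.shape[1], grid.n_rows, grid.n_cols).astype("float32")
    tifffile.imwrite(str(path), img, photometric="minisblack")


def read_raster(path) -> np.ndarray:
    img = tifffile.imread(str(path))
    if img.ndim == 2:
        img = img[None]
    return img.reshape(img.shape[0], -1).T.astype(float)


def write_boundaries(path, grid, level: str = "admin2") -> None:
    """GeoJSON polygons per admin unit, dissolved from pixel squares."""
    ids = getattr(grid, f"{level}_id")
    half = grid.pixel_size / 2.0
    features = []
    for u in np.unique(ids[ids >= 0]):
        sel = np.flatnonzero(ids == u)
        squares = [box(x - half, y - half, x + half, y + half)
                   for x, y in grid.pixel_centers[sel]]
        geom = unary_union(squares)
        px = sel[0]
        features.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {f"{level}_id": int(u),
                           "country_id": int(grid.country_id[px]),
                           "region_id": int(grid.region_id[px])},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def array_checksum(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def write_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
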
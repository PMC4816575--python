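"""GeoTIFF reading and writing.

Rasters are stored as ordinary (Geo)TIFFs carrying the standard
georeferencing tags — ``ModelPixelScale`` (33550), ``ModelTiepoint``
(33922), a minimal ``GeoKeyDirectory`` (34735) naming the EPSG code, and
GDAL's nodata tag (42113).  Band labels travel in the ImageDescription as
JSON so a 12-band monthly climatology round-trips with its month names.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .grid import GeoGrid, GridStack, GridTransform

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids for a plain geographic CRS
_KEY_MODEL_TYPE = 1024  # 2 = geographic
_KEY_RASTER_TYPE = 1025  # 1 = pixel-is-area
_KEY_GEOGRAPHIC_TYPE = 2048  # EPSG code


def _epsg_code(crs: str) -> int:
    if crs.upper().startswith("EPSG:"):
        return int(crs.split(":")[1])
    raise ValueError(f"cannot encode CRS {crs!r}; use 'EPSG:<code>'")


def _geo_extratags(transform: GridTransform, crs: str, nodata: float) -> list:
    code = _epsg_code(crs)
    geokeys = [
        1, 1, 0, 3,  # header: version, rev, minor, number of keys
        _KEY_MODEL_TYPE, 0, 1, 2,
        _KEY_RASTER_TYPE, 0, 1, 1,
        _KEY_GEOGRAPHIC_TYPE, 0, 1, code,
    ]
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.dx, transform.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, transform.x_origin, transform.y_origin, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), tuple(geokeys)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def write_raster(grid, path, nodata: float = float("nan")) -> None:
    """Write a :class:`GeoGrid` or :class:`GridStack` as a GeoTIFF.

    Masked cells are filled with *nodata*, which is declared in the GDAL
    nodata tag so other GIS software recognises it.
    """
    path = Path(path)
    if isinstance(grid, GeoGrid):
        stack = GridStack(grids=[grid], labels=["band_1"])
        labels = None
    else:
        stack = grid
        labels = list(stack.labels)
    data = stack.as_array(fill=nodata).astype("float64")
    desc = json.dumps({"labels": labels, "crs": stack.crs})
    tags = _geo_extratags(stack.transform, stack.crs, nodata)
    with tifffile.TiffWriter(path) as tif:
        for band in data:
            tif.write(band, extratags=tags, description=desc,
                      metadata=None, photometric="minisblack")


def read_raster(path, band: str | int | None = None):
    """Read a GeoTIFF written by :func:`write_raster` (or any north-up
    single/multi-band GeoTIFF with declared georeferencing).

    Returns a :class:`GeoGrid` for single-band files and a
    :class:`GridStack` for multi-band files; *band* selects one layer.
    Files without georeferencing raise; an undeclared nodata value only
    warns and yields an empty mask.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        first = pages[0]
        tags = {t.code: t.value for t in first.tags}
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: no georeferencing (GeoTIFF tags missing)")
        dx, dy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
        tp = tags[_TAG_TIEPOINT]
        # tiepoint maps raster (i, j) to model (x, y); shift back to corner
        x0 = tp[3] - tp[0] * dx
        y0 = tp[4] + tp[1] * dy
        transform = GridTransform(x0, y0, dx, dy)

        crs = None
        if _TAG_GEO_KEYS in tags:
            keys = np.asarray(tags[_TAG_GEO_KEYS]).ravel()
            for k in range(4, len(keys) - 3, 4):
                if keys[k] == _KEY_GEOGRAPHIC_TYPE and keys[k + 1] == 0:
                    crs = f"EPSG:{int(keys[k + 3])}"
        labels = None
        desc = tags.get(270)
        if desc:
            try:
                meta = json.loads(desc)
                labels = meta.get("labels")
                crs = crs or meta.get("crs")
            except (json.JSONDecodeError, AttributeError):
                pass
        if crs is None:
            raise ValueError(f"{path}: no CRS declared")

        nodata = None
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(tags[_TAG_GDAL_NODATA])
            except ValueError:
                pass
        if nodata is None:
            warnings.warn(f"{path}: no nodata value declared; mask left empty")

        arrays = [p.asarray().astype(float) for p in pages]

    grids = []
    for arr in arrays:
        if nodata is None:
            mask = np.zeros(arr.shape, dtype=bool)
        elif np.isnan(nodata):
            mask = ~np.isfinite(arr)
        else:
            mask = arr == nodata
        grids.append(GeoGrid(arr, mask=mask, transform=transform, crs=crs))

    if labels is None or len(labels) != len(grids):
        labels = [f"band_{i + 1}" for i in range(len(grids))]
    stack = GridStack(grids=grids, labels=labels)
    if band is not None:
        return stack.grids[band] if isinstance(band, int) else stack[band]
    if len(stack) == 1:
        return stack.grids[0]
    return stack
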
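"""Single-band GeoTIFF read/write built on tifffile.

Writes the minimal GeoTIFF tag set (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory, GDAL_NODATA) for a north-up raster on a projected grid.
Rasters are stored as float64 so written model outputs reload bit-exactly;
nodata is -9999 on disk and NaN in memory.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .grid import AnalysisGrid, GridLayer, GridError, _epsg_code

NODATA = -9999.0

# GeoTIFF tag / key ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113
_KEY_MODEL_TYPE = 1024      # 1 = projected
_KEY_RASTER_TYPE = 1025     # 1 = PixelIsArea
_KEY_PROJECTED_CS = 3072    # EPSG code of the projected CRS


def write_geotiff(path, layer: GridLayer) -> None:
    """Write a layer as a single-band float64 GeoTIFF with nodata tag set."""
    grid = layer.grid
    x0, _, _, y1 = grid.extent
    values = np.where(layer.nodata_mask, NODATA, layer.values).astype(np.float64)

    keys = [_KEY_MODEL_TYPE, 0, 1, 1, _KEY_RASTER_TYPE, 0, 1, 1]
    code = _epsg_code(grid.crs)
    if code is not None:
        keys += [_KEY_PROJECTED_CS, 0, 1, code]
    n_keys = len(keys) // 4
    geokeys = (1, 1, 0, n_keys, *keys)

    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.resolution, grid.resolution, 0.0), True),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y1, 0.0), True),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys, True),
        (_GDAL_NODATA, "s", 0, str(NODATA), True),
    ]
    tifffile.imwrite(str(path), values, extratags=extratags)


def read_geotiff(path, name: str | None = None) -> GridLayer:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`.

    Reconstructs the grid from the pixel-scale and tiepoint tags; the CRS is
    recovered from the ProjectedCSType geokey when present, else "unknown".
    The area mask is all-true (ownership of the mask lies with the case
    study, which re-attaches its own grid after alignment checks).
    """
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(np.float64)
        tags = {t.code: t.value for t in page.tags.values()}
    if values.ndim != 2:
        raise GridError(f"{path}: expected a single-band raster, got shape {values.shape}")
    if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
        raise GridError(f"{path}: missing georeferencing tags (not a GeoTIFF?)")
    sx, sy = tags[_MODEL_PIXEL_SCALE][:2]
    if abs(sx - sy) > 1e-9:
        raise GridError(f"{path}: non-square pixels ({sx} x {sy}) unsupported")
    x0, y1 = tags[_MODEL_TIEPOINT][3], tags[_MODEL_TIEPOINT][4]
    n_rows, n_cols = values.shape
    extent = (x0, y1 - n_rows * sy, x0 + n_cols * sx, y1)

    crs = "unknown"
    geokeys = tags.get(_GEO_KEY_DIRECTORY)
    if geokeys is not None:
        geokeys = list(geokeys)
        for i in range(4, len(geokeys), 4):
            if geokeys[i] == _KEY_PROJECTED_CS:
                crs = f"EPSG:{geokeys[i + 3]}"

    nodata = NODATA
    if _GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            pass
    values[values == nodata] = np.nan

    grid = AnalysisGrid(extent, float(sx), crs, np.ones(values.shape, dtype=bool))
    if name is None:
        name = str(path)
    return GridLayer(name=name, values=values, grid=grid)
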
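"""Rectified-grid data model and raster transformation operators.

All model layers (human uses, environmental components, pressures) live on a
single axis-aligned regular grid in a projected coordinate system.  The grid
origin is the top-left corner; cells are row-major, pixel-is-area, with
half-open intervals ``[x, x + res)`` horizontally and ``(y - res, y]``
descending vertically.  Nodata is stored as NaN in float64 arrays: it is
treated as 0 inside convolutions and sums and excluded from maxima and
statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
import shapely
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry

__all__ = [
    "AnalysisGrid",
    "GridLayer",
    "GridError",
    "make_grid",
    "rasterize",
    "gaussian_convolve",
    "normalize",
    "log_scale",
    "reclassify",
    "apply_mask",
    "grid_to_json",
    "grid_from_json",
]

#: EPSG codes of common geographic (degree-unit) reference systems.  The
#: analysis grid requires a projected CRS with linear units in meters; these
#: are rejected outright.  Anything else is taken at the caller's word --
#: there is no geodesy engine here by design.
_GEOGRAPHIC_EPSG = {4326, 4258, 4269, 4267, 4283, 4979}


class GridError(ValueError):
    """Raised for invalid grid definitions or misaligned layer operations."""


def _epsg_code(crs: str) -> int | None:
    s = str(crs).strip().upper()
    if s.startswith("EPSG:"):
        try:
            return int(s.split(":", 1)[1])
        except ValueError:
            return None
    return None


def _is_geographic(crs: str) -> bool:
    code = _epsg_code(crs)
    if code is not None:
        return code in _GEOGRAPHIC_EPSG
    s = str(crs).upper()
    return "WGS84" in s.replace(" ", "") or "LONGLAT" in s or "DEGREE" in s


@dataclass(frozen=True)
class AnalysisGrid:
    """Regular analysis grid: extent, resolution, CRS and area-of-analysis mask.

    Parameters
    ----------
    extent
        ``(x_min, y_min, x_max, y_max)`` in projected map units (meters).
    resolution
        Cell edge length in meters, > 0.
    crs
        Projected coordinate reference identifier (e.g. ``"EPSG:3035"``).
        Treated as an opaque label; geographic (degree) systems are rejected.
    area_mask
        Boolean per-cell membership of the area of analysis.
    """

    extent: tuple[float, float, float, float]
    resolution: float
    crs: str
    area_mask: np.ndarray = field(repr=False)

    @property
    def n_rows(self) -> int:
        # tolerant ceil: an extent reconstructed as n*res must give back n
        return int(math.ceil((self.extent[3] - self.extent[1]) / self.resolution - 1e-9))

    @property
    def n_cols(self) -> int:
        return int(math.ceil((self.extent[2] - self.extent[0]) / self.resolution - 1e-9))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` arrays of cell-center coordinates, grid-shaped."""
        x0, y0, x1, y1 = self.extent
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.resolution
        ys = y1 - (np.arange(self.n_rows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def cell_area_m2(self) -> float:
        return float(self.resolution) ** 2

    def is_aligned(self, other: "AnalysisGrid") -> bool:
        return (
            self.shape == other.shape
            and self.extent == other.extent
            and self.resolution == other.resolution
            and self.crs == other.crs
        )

    def __post_init__(self) -> None:
        if self.area_mask.shape != self.shape:
            raise GridError(
                f"area_mask shape {self.area_mask.shape} does not match "
                f"grid shape {self.shape}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnalysisGrid):
            return NotImplemented
        return self.is_aligned(other) and bool(
            np.array_equal(self.area_mask, other.area_mask)
        )

    def __hash__(self) -> int:  # frozen dataclass with an array field
        return hash((self.extent, self.resolution, self.crs))


@dataclass
class GridLayer:
    """A named 2D intensity array aligned to an :class:`AnalysisGrid`.

    Values are non-negative finite intensities or NaN (nodata).  Presence
    layers hold only {0, 1}.
    """

    name: str
    values: np.ndarray
    grid: AnalysisGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"layer {self.name!r}: values shape {self.values.shape} does "
                f"not match grid shape {self.grid.shape}"
            )
        if np.isinf(self.values).any():
            raise GridError(f"layer {self.name!r}: non-finite (inf) values")

    def copy(self, name: str | None = None, values: np.ndarray | None = None) -> "GridLayer":
        return GridLayer(
            name=self.name if name is None else name,
            values=self.values.copy() if values is None else values,
            grid=self.grid,
        )

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata replaced by ``fill`` (nodata counts as 0 in sums)."""
        return np.where(self.nodata_mask, fill, self.values)

    def sum(self) -> float:
        return float(np.nansum(self.values))

    def max(self) -> float:
        return float(np.nanmax(self.values))


def make_grid(
    extent: tuple[float, float, float, float],
    resolution: float,
    crs: str,
    area_polygon: BaseGeometry | dict | None = None,
) -> AnalysisGrid:
    """Subdivide ``extent`` into regular cells of edge ``resolution`` meters.

    The number of rows/columns is ``ceil(extent / resolution)``.  When
    ``area_polygon`` is given, the area-of-analysis mask is its
    rasterization by cell-center containment; otherwise every cell is in.
    """
    if resolution is None or resolution <= 0:
        raise GridError(f"resolution must be > 0, got {resolution!r}")
    x0, y0, x1, y1 = (float(v) for v in extent)
    if not (x1 > x0 and y1 > y0):
        raise GridError(f"degenerate extent {extent!r}")
    if _is_geographic(crs):
        raise GridError(
            f"CRS {crs!r} is geographic (degree units); the analysis grid "
            "requires a projected CRS in meters"
        )
    n_rows = int(math.ceil((y1 - y0) / resolution - 1e-9))
    n_cols = int(math.ceil((x1 - x0) / resolution - 1e-9))
    mask = np.ones((n_rows, n_cols), dtype=bool)
    grid = AnalysisGrid((x0, y0, x1, y1), float(resolution), str(crs), mask)
    if area_polygon is not None:
        geom = _as_geometry(area_polygon)
        X, Y = grid.cell_centers()
        mask = shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(grid.shape)
        grid = AnalysisGrid(grid.extent, grid.resolution, grid.crs, mask)
    return grid


def _as_geometry(obj) -> BaseGeometry:
    if isinstance(obj, BaseGeometry):
        return obj
    if isinstance(obj, dict):
        return shapely_shape(obj)
    raise GridError(f"not a geometry: {type(obj).__name__}")


def _iter_features(features):
    """Yield ``(geometry, properties)`` from GeoJSON-ish input.

    Accepts a FeatureCollection dict, a list of Feature dicts, a single
    Feature/geometry dict, or shapely geometries.
    """
    if isinstance(features, dict):
        t = features.get("type")
        if t == "FeatureCollection":
            feats = features.get("features", [])
        elif t == "Feature":
            feats = [features]
        else:  # bare geometry
            feats = [{"type": "Feature", "geometry": features, "properties": {}}]
    elif isinstance(features, BaseGeometry):
        feats = [{"type": "Feature", "geometry": features, "properties": {}}]
    else:
        feats = list(features)
    for f in feats:
        if isinstance(f, BaseGeometry):
            yield f, {}
        elif isinstance(f, dict) and f.get("type") == "Feature":
            yield _as_geometry(f["geometry"]), (f.get("properties") or {})
        else:
            yield _as_geometry(f), {}


def _check_features_crs(features, grid: AnalysisGrid) -> None:
    """GeoJSON may carry a top-level crs member; reject a declared mismatch."""
    if isinstance(features, dict) and "crs" in features and features["crs"]:
        declared = features["crs"]
        if isinstance(declared, dict):
            declared = declared.get("properties", {}).get("name", "")
        d_code, g_code = _epsg_code(str(declared)), _epsg_code(grid.crs)
        same = (str(declared).upper() == str(grid.crs).upper()) or (
            d_code is not None and d_code == g_code
        )
        if not same:
            raise GridError(
                f"feature CRS {declared!r} does not match grid CRS "
                f"{grid.crs!r} (no reprojection engine)"
            )


def rasterize(
    features,
    grid: AnalysisGrid,
    value_field: str | None = None,
    mode: str = "presence",
    name: str = "rasterized",
) -> GridLayer:
    """Burn vector features onto the grid.

    Polygons cover a cell when the cell center falls inside them; lines and
    points burn every cell they intersect.  ``mode="presence"`` yields a
    binary layer; ``mode="burn_value"`` sums each feature's ``value_field``
    into the cells it covers (additive on overlaps).
    """
    if mode not in ("presence", "burn_value"):
        raise GridError(f"unknown rasterize mode {mode!r}")
    if mode == "burn_value" and not value_field:
        raise GridError("burn_value mode requires a value_field")
    _check_features_crs(features, grid)

    out = np.zeros(grid.shape, dtype=np.float64)
    X, Y = grid.cell_centers()
    xf, yf = X.ravel(), Y.ravel()
    for geom, props in _iter_features(features):
        if geom.is_empty:
            continue
        if mode == "burn_value":
            if value_field not in props:
                raise GridError(
                    f"feature missing value_field {value_field!r} "
                    f"(properties: {sorted(props)})"
                )
            burn = float(props[value_field])
        else:
            burn = 1.0
        covered = _coverage(geom, grid, xf, yf)
        if mode == "presence":
            out.ravel()[covered] = 1.0
        else:
            out.ravel()[covered] += burn
    return GridLayer(name=name, values=out, grid=grid)


def _coverage(geom: BaseGeometry, grid: AnalysisGrid, xf, yf) -> np.ndarray:
    """Boolean flat index of cells covered by one geometry."""
    gtype = geom.geom_type
    if gtype in ("Polygon", "MultiPolygon"):
        return shapely.contains_xy(geom, xf, yf)
    # lines / points: any intersection with the cell box burns the cell
    res = grid.resolution
    x0, _, _, y1 = grid.extent
    gx0, gy0, gx1, gy1 = geom.bounds
    j0 = max(0, int(math.floor((gx0 - x0) / res)))
    j1 = min(grid.n_cols - 1, int(math.floor((gx1 - x0) / res)))
    i0 = max(0, int(math.floor((y1 - gy1) / res)))
    i1 = min(grid.n_rows - 1, int(math.floor((y1 - gy0) / res)))
    covered = np.zeros(grid.shape, dtype=bool)
    if j1 < j0 or i1 < i0:
        return covered.ravel()
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    boxes = shapely.box(
        x0 + jj.ravel() * res,
        y1 - (ii.ravel() + 1) * res,
        x0 + (jj.ravel() + 1) * res,
        y1 - ii.ravel() * res,
    )
    hits = shapely.intersects(boxes, geom)
    covered[ii.ravel()[hits], jj.ravel()[hits]] = True
    return covered.ravel()


def gaussian_convolve(layer: GridLayer, distance_m: float) -> GridLayer:
    """Smooth a layer with an isotropic Gaussian kernel.

    ``distance_m`` is the effective propagation radius: sigma =
    distance_m / 3, so ~99.7% of the mass falls within the stated distance.
    The kernel is truncated at 4 sigma and renormalized to unit sum, so total
    mass is conserved up to boundary truncation.  ``distance_m = 0`` is the
    identity.  Nodata cells contribute 0 mass and stay nodata in the output.
    """
    if distance_m < 0:
        raise GridError(f"propagation distance must be >= 0, got {distance_m}")
    if distance_m == 0:
        return layer.copy()
    sigma_cells = (distance_m / 3.0) / layer.grid.resolution
    nodata = layer.nodata_mask
    smoothed = ndimage.gaussian_filter(
        layer.filled(0.0), sigma=sigma_cells, mode="constant", cval=0.0, truncate=4.0
    )
    smoothed = np.maximum(smoothed, 0.0)
    if nodata.any():
        smoothed[nodata] = np.nan
    return layer.copy(values=smoothed)


def normalize(layer: GridLayer) -> GridLayer:
    """Divide by the maximum non-nodata value, mapping the range into [0, 1].

    An all-zero layer is returned unchanged (zero layers legitimately arise
    from empty use subsets); an all-nodata layer is an error.
    """
    if layer.nodata_mask.all():
        raise GridError(f"layer {layer.name!r} is all nodata; cannot normalize")
    m = np.nanmax(layer.values)
    if m == 0:
        return layer.copy()
    return layer.copy(values=layer.values / m)


def log_scale(layer: GridLayer) -> GridLayer:
    """Cellwise ``log(1 + value)``: monotone, maps 0 to 0."""
    if (layer.filled(0.0) < 0).any():
        raise GridError(f"layer {layer.name!r} has negative values; log_scale needs >= 0")
    return layer.copy(values=np.log1p(layer.values))


def reclassify(layer: GridLayer, breaks, class_values) -> GridLayer:
    """Map each cell to the class of its half-open interval ``[b_i, b_{i+1})``.

    ``len(class_values)`` must be ``len(breaks) + 1``; values below the first
    break take ``class_values[0]``.  Nodata propagates.
    """
    breaks = np.asarray(breaks, dtype=np.float64)
    class_values = np.asarray(class_values, dtype=np.float64)
    if breaks.ndim != 1 or len(breaks) == 0:
        raise GridError("breaks must be a non-empty 1D sequence")
    if not np.all(np.diff(breaks) > 0):
        raise GridError(f"breaks must be strictly increasing, got {breaks.tolist()}")
    if len(class_values) != len(breaks) + 1:
        raise GridError(
            f"need len(breaks)+1 = {len(breaks) + 1} class values, "
            f"got {len(class_values)}"
        )
    nodata = layer.nodata_mask
    idx = np.digitize(layer.filled(0.0), breaks, right=False)
    out = class_values[idx]
    out[nodata] = np.nan
    return layer.copy(values=out)


def apply_mask(layer: GridLayer, mask) -> GridLayer:
    """Set cells outside the mask to nodata; cells inside are unchanged.

    ``mask`` is a boolean array, a binary :class:`GridLayer`, or the string
    ``"area"`` for the grid's area-of-analysis mask.
    """
    if isinstance(mask, str) and mask == "area":
        m = layer.grid.area_mask
    elif isinstance(mask, GridLayer):
        if not mask.grid.is_aligned(layer.grid):
            raise GridError(
                f"mask layer {mask.name!r} is not aligned to layer {layer.name!r}"
            )
        m = mask.filled(0.0) > 0
    else:
        m = np.asarray(mask, dtype=bool)
        if m.shape != layer.grid.shape:
            raise GridError(
                f"mask shape {m.shape} does not match grid shape {layer.grid.shape}"
            )
    out = layer.values.copy()
    out[~m] = np.nan
    return layer.copy(values=out)


# -- grid definition (de)serialization ---------------------------------------

def grid_to_json(grid: AnalysisGrid, area_polygon: BaseGeometry | None = None) -> dict:
    """JSON-able grid definition ``{extent, resolution, crs[, area_polygon]}``."""
    d = {
        "extent": list(grid.extent),
        "resolution": grid.resolution,
        "crs": grid.crs,
    }
    if area_polygon is not None:
        d["area_polygon"] = shapely_mapping(area_polygon)
    return d


def grid_from_json(d: dict) -> AnalysisGrid:
    poly = d.get("area_polygon")
    return make_grid(
        tuple(d["extent"]),
        d["resolution"],
        d["crs"],
        area_polygon=shapely_shape(poly) if poly else None,
    )
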
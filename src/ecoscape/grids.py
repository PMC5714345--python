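"""Raster/vector data model and grid algebra.

A :class:`Grid` is the universal raster currency of the pipeline: digital
numbers, backscatter, texture features, biomass, richness counts and z-scores
all travel as grids.  Grids are north-up, row-major (row 0 = north), square
pixels, in a projected CRS with metric units.  Geographic (degree) rasters are
rejected on IO because every distance and area in the pipeline is metric.

File formats are the plain GIS ones: single-band GeoTIFF for rasters (written
with the standard ModelPixelScale / ModelTiepoint / GDAL_NODATA tags) and
GeoJSON for vector layers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Grid",
    "VectorLayer",
    "read_grid",
    "write_grid",
    "read_vector",
    "write_vector",
    "aggregate",
    "aggregate_circular",
    "slope_aspect",
    "euclidean_distance",
    "landscape_diversity",
    "landscape_fragmentation",
]

DEFAULT_NODATA = -9999.0

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_DESCRIPTION = 270


@dataclass
class Grid:
    """A single-band, north-up raster with square cells in a metric CRS.

    The center of cell ``(r, c)`` is
    ``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``
    where ``(origin_x, origin_y)`` is the north-west corner.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 25.0
    crs_id: str = "local-metric"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        vals = self.values
        ok = vals != self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            ok &= np.isfinite(vals)
        return ok

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Float copy with nodata replaced by ``fill`` (NaN by default)."""
        out = self.values.astype(float, copy=True)
        out[~self.mask()] = fill
        return out

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        nd = self.nodata if nodata is None else nodata
        return replace(self, values=values, nodata=nd)

    @staticmethod
    def from_nan(
        values: np.ndarray, template: "Grid", nodata: float = DEFAULT_NODATA
    ) -> "Grid":
        out = np.asarray(values, dtype=float).copy()
        out[~np.isfinite(out)] = nodata
        return replace(template, values=out, nodata=nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, each shape (nr, nc)."""
        nr, nc = self.shape
        xs = self.origin_x + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def require_aligned(self, other: "Grid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise ValueError(f"misaligned {what}: shape/origin/cell_size differ")


@dataclass
class VectorLayer:
    """Polylines or polygons with per-geometry attribute records."""

    geometries: list[BaseGeometry]
    attributes: list[dict] = field(default_factory=list)
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        if len(self.attributes) != len(self.geometries):
            raise ValueError("attributes must match geometries 1:1")
        for g in self.geometries:
            if g.geom_type in ("Polygon", "MultiPolygon") and not g.is_valid:
                raise ValueError("invalid (self-intersecting?) polygon in layer")

    def __len__(self) -> int:
        return len(self.geometries)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_grid(grid: Grid, path) -> None:
    """Write a grid as a single-band float32 GeoTIFF."""
    desc = json.dumps({"crs_id": grid.crs_id})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(
        str(path),
        grid.values.astype(np.float32),
        photometric="minisblack",
        description=desc,
        extratags=extratags,
    )


def read_grid(path) -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_grid` (or compatible)."""
    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band (single-page) GeoTIFF")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: multi-sample rasters are not supported")
        values = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy}) rejected")
        tie = tags[_TAG_TIEPOINT].value
        origin_x = float(tie[3] - tie[0] * sx)
        origin_y = float(tie[4] + tie[1] * sy)
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs_id = "local-metric"
        if _TAG_DESCRIPTION in tags:
            try:
                crs_id = json.loads(tags[_TAG_DESCRIPTION].value).get("crs_id", crs_id)
            except (json.JSONDecodeError, AttributeError):
                pass
    return Grid(values=values, origin_x=origin_x, origin_y=origin_y,
                cell_size=float(sx), crs_id=crs_id, nodata=nodata)


def write_vector(layer: VectorLayer, path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": attrs}
        for g, attrs in zip(layer.geometries, layer.attributes)
    ]
    doc = {"type": "FeatureCollection", "crs_id": layer.crs_id, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_vector(path) -> VectorLayer:
    with open(path) as fh:
        doc = json.load(fh)
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    attrs = [f.get("properties") or {} for f in doc["features"]]
    return VectorLayer(geoms, attrs, crs_id=doc.get("crs_id", "local-metric"))


# ---------------------------------------------------------------------------
# Grid algebra
# ---------------------------------------------------------------------------

def _pad_to_blocks(arr: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = arr.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), constant_values=np.nan)
    return arr


def aggregate(grid: Grid, factor: int, stat: str = "mean") -> Grid:
    """Block-aggregate a grid by an integer factor.

    Trailing partial blocks use whatever cells are available.  ``mean`` and
    ``sum`` ignore nodata cells; a block that is entirely nodata becomes
    nodata.  ``majority`` takes the modal class (ties broken by smallest
    class value).
    """
    factor = int(factor)
    if factor <= 0:
        raise ValueError("aggregation factor must be a positive integer")
    if factor == 1 and stat in ("mean", "majority"):
        return grid.like(grid.values.copy())
    vals = grid.filled()
    vals = _pad_to_blocks(vals, factor)
    nr, nc = vals.shape
    blocks = vals.reshape(nr // factor, factor, nc // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(nr // factor, nc // factor, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        if stat == "mean":
            out = np.nanmean(blocks, axis=-1)
        elif stat == "sum":
            out = np.nansum(blocks, axis=-1)
            out[np.all(np.isnan(blocks), axis=-1)] = np.nan
        elif stat == "majority":
            out = np.full(blocks.shape[:2], np.nan)
            for r in range(blocks.shape[0]):
                for c in range(blocks.shape[1]):
                    b = blocks[r, c]
                    b = b[np.isfinite(b)]
                    if b.size:
                        classes, counts = np.unique(b, return_counts=True)
                        out[r, c] = classes[np.argmax(counts)]
        else:
            raise ValueError(f"unknown aggregation stat {stat!r}")
    agg = Grid.from_nan(out, grid)
    agg.cell_size = grid.cell_size * factor
    return agg


def aggregate_circular(grid: Grid, factor: int) -> Grid:
    """Block-aggregate an angular grid (degrees) by the circular mean.

    Used for aspect, where the arithmetic mean of {350, 10} would give the
    nonsensical 180 instead of 0.
    """
    rad = np.deg2rad(grid.filled())
    template = grid.like(np.zeros(grid.shape))
    s = aggregate(template.like(np.sin(rad)), factor, "mean").filled()
    c = aggregate(template.like(np.cos(rad)), factor, "mean").filled()
    ang = np.rad2deg(np.arctan2(s, c)) % 360.0
    ang[~np.isfinite(s)] = np.nan
    out = Grid.from_nan(ang, grid)
    out.cell_size = grid.cell_size * factor
    return out


def slope_aspect(dem: Grid) -> tuple[Grid, Grid]:
    """Slope (degrees) and downslope aspect (degrees clockwise from north).

    Uses Horn's 3x3 finite differences.  Border cells and cells with any
    nodata neighbor are nodata; flat cells get nodata aspect.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("slope_aspect needs a grid of at least 3x3 cells")
    z = dem.filled()
    cs = dem.cell_size
    # 3x3 neighborhood, compass naming (row 0 = north)
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cs)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cs)  # +y = north
    slope_deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope azimuth, clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[(dzdx == 0) & (dzdy == 0)] = np.nan

    full_slope = np.full(z.shape, np.nan)
    full_aspect = np.full(z.shape, np.nan)
    full_slope[1:-1, 1:-1] = slope_deg
    full_aspect[1:-1, 1:-1] = aspect
    return Grid.from_nan(full_slope, dem), Grid.from_nan(full_aspect, dem)


def euclidean_distance(target: VectorLayer, template: Grid) -> Grid:
    """Distance (m) from every cell center to the nearest geometry."""
    if len(target) == 0:
        raise ValueError("euclidean_distance: target layer is empty")
    xs, ys = template.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    dist = np.full(pts.shape, np.inf)
    for geom in target.geometries:
        np.minimum(dist, shapely.distance(pts, geom), out=dist)
    return template.like(dist.reshape(template.shape), nodata=DEFAULT_NODATA)


def _window_sum(arr: np.ndarray, size: tuple[int, int], origin=(0, 0)) -> np.ndarray:
    # correlate, not convolve: even-sized kernels must not be flipped
    kernel = np.ones(size)
    return ndimage.correlate(arr, kernel, mode="constant", cval=0.0, origin=origin)


def _check_window(window: int) -> int:
    window = int(window)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    return window


def landscape_diversity(landcover: Grid, window: int = 3) -> Grid:
    """Shannon diversity H = -sum p_k ln p_k of land-cover classes per window."""
    window = _check_window(window)
    vals = landcover.filled()
    valid = np.isfinite(vals).astype(float)
    total = _window_sum(valid, (window, window))
    classes = np.unique(vals[np.isfinite(vals)])
    h = np.zeros(vals.shape)
    for k in classes:
        count = _window_sum(((vals == k) & np.isfinite(vals)).astype(float),
                            (window, window))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, count / total, 0.0)
            h -= np.where(p > 0, p * np.log(p), 0.0)
    h[total == 0] = np.nan
    h[~np.isfinite(vals)] = np.nan
    return Grid.from_nan(h, landcover)


def landscape_fragmentation(landcover: Grid, window: int = 3) -> Grid:
    """Edge-density heterogeneity: fraction of rook-adjacent cell pairs inside
    the window whose classes differ.  0 = homogeneous, 1 = checkerboard."""
    window = _check_window(window)
    vals = landcover.filled()
    valid = np.isfinite(vals)
    half = window // 2

    # pair indicators anchored at the left/top cell of each pair
    hpair = valid[:, :-1] & valid[:, 1:]
    hdiff = hpair & (vals[:, :-1] != vals[:, 1:])
    vpair = valid[:-1, :] & valid[1:, :]
    vdiff = vpair & (vals[:-1, :] != vals[1:, :])

    # a horizontal pair (r, c)-(r, c+1) lies in the window centered at (R, C)
    # iff |r-R| <= half and C-half <= c <= C+half-1: a w x (w-1) box whose
    # anchor column range is shifted half a cell west of center.
    def pair_count(ind: np.ndarray, horizontal: bool) -> np.ndarray:
        arr = ind.astype(float)
        if horizontal:
            arr = np.pad(arr, ((0, 0), (0, 1)))
            # origin shifts the kernel center; kernel cols = window-1 (even),
            # convolve centers it at (window-1)//2 = half-1 past the anchor …
            return _window_sum(arr, (window, window - 1), origin=(0, 0))
        arr = np.pad(arr, ((0, 1), (0, 0)))
        return _window_sum(arr, (window - 1, window), origin=(0, 0))

    n_diff = pair_count(hdiff, True) + pair_count(vdiff, False)
    n_pair = pair_count(hpair, True) + pair_count(vpair, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_pair > 0, n_diff / n_pair, np.nan)
    frac[~valid] = np.nan
    return Grid.from_nan(frac, landcover)
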
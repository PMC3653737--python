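"""2D computational-geometry kernel for per-slice contour operations.

Boolean intersection/union of slice polygons, shoelace areas, boundary
distances, and a pixel-counting rasterization oracle.  The clipper
delegates to shapely; the oracle uses an independent point-in-polygon test
(matplotlib's Path) so the two routes cross-check each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from shapely.geometry import MultiPolygon, Point
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.ops import unary_union

from .errors import OutOfBoundsError, SliceMismatchError, ZeroAreaError
from .model import SLICE_TOL, normalize_contour, signed_area

#: Intersection/union components smaller than this (cm^2) are degenerate
#: touching artefacts (shared edges/vertices) and are dropped.
_AREA_EPS = 1e-12


@dataclass
class SlicePolygonSet:
    """One or more normalized polygons on a single axial plane."""

    z: float
    polygons: list[np.ndarray] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.polygons

    @property
    def total_area(self) -> float:
        return float(sum(signed_area(p) for p in self.polygons))


@dataclass(frozen=True)
class RasterGrid:
    """Regular pixel grid for the rasterization oracle.

    ``origin`` is the lower-left corner of the grid (cm); pixel centres sit
    at ``origin + (index + 0.5) * pixel_size``.
    """

    origin: tuple[float, float]
    pixel_size: float
    dimensions: tuple[int, int]  # (nx, ny)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.dimensions[0] <= 0 or self.dimensions[1] <= 0:
            raise ValueError("grid dimensions must be positive")

    def pixel_centres(self) -> np.ndarray:
        """(nx*ny, 2) array of pixel-centre coordinates."""
        nx, ny = self.dimensions
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    @classmethod
    def covering(cls, polygons: list[np.ndarray], pixel_size: float, pad: float = 0.0) -> "RasterGrid":
        """Smallest grid enclosing all polygons, with optional padding (cm)."""
        allv = np.vstack(polygons)
        lo = allv.min(axis=0) - pad
        hi = allv.max(axis=0) + pad
        n = np.maximum(np.ceil((hi - lo) / pixel_size).astype(int), 1)
        return cls((float(lo[0]), float(lo[1])), pixel_size, (int(n[0]), int(n[1])))


def polygon_area(vertices) -> float:
    """Shoelace area (cm^2) of a normalized simple polygon; always positive.

    Raises :class:`ZeroAreaError` for collinear (zero-area) input.
    """
    a = abs(signed_area(np.asarray(vertices, dtype=float)))
    if a == 0.0:
        raise ZeroAreaError("degenerate polygon with zero area")
    return a


def _to_shapely(s: SlicePolygonSet):
    return unary_union([_ShapelyPolygon(p) for p in s.polygons]) if s.polygons else _ShapelyPolygon()


def _from_shapely(geom, z: float) -> SlicePolygonSet:
    polys: list[np.ndarray] = []
    if geom.is_empty:
        return SlicePolygonSet(z, [])
    parts = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    for part in parts:
        if not isinstance(part, _ShapelyPolygon) or part.area <= _AREA_EPS:
            continue  # lines/points from degenerate touching contribute nothing
        v = np.asarray(part.exterior.coords)[:-1]
        polys.append(normalize_contour(v))
    return SlicePolygonSet(z, polys)


def _check_same_slice(a: SlicePolygonSet, b: SlicePolygonSet) -> None:
    if abs(a.z - b.z) > SLICE_TOL:
        raise SliceMismatchError(f"polygon sets on different slices: z={a.z} vs z={b.z}")


def clip_intersection(a: SlicePolygonSet, b: SlicePolygonSet) -> SlicePolygonSet:
    """Boolean intersection of two same-slice polygon sets.

    Returns the overlap region as disjoint simple polygons (empty if the
    sets are disjoint).  Measure-zero contact (shared edge or vertex) yields
    an empty result.
    """
    _check_same_slice(a, b)
    if a.is_empty or b.is_empty:
        return SlicePolygonSet(a.z, [])
    return _from_shapely(_to_shapely(a).intersection(_to_shapely(b)), a.z)


def clip_union(a: SlicePolygonSet, b: SlicePolygonSet) -> SlicePolygonSet:
    """Boolean union of two same-slice polygon sets (disjoint output)."""
    _check_same_slice(a, b)
    return _from_shapely(unary_union([_to_shapely(a), _to_shapely(b)]), a.z)


def point_to_contours_distance(p, polygons: SlicePolygonSet) -> float | None:
    """Minimum Euclidean distance (cm) from a point to any polygon boundary.

    The distance is to the closed boundary polyline, unsigned: a point
    inside a polygon gets its distance to the nearest edge, and a point on
    a boundary gets 0.  Returns ``None`` (the "no contour" signal) when the
    set is empty — deliberately distinct from a numeric result.
    """
    if polygons.is_empty:
        return None
    pt = Point(float(p[0]), float(p[1]))
    return min(_ShapelyPolygon(v).exterior.distance(pt) for v in polygons.polygons)


def rasterize(polygons: SlicePolygonSet, grid: RasterGrid) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon set.

    Pixel membership is decided at pixel centres with the even-odd fill
    rule.  The mask has shape ``(nx, ny)``; its area is
    ``mask.sum() * pixel_size**2``.

    Raises :class:`OutOfBoundsError` if any polygon extends past the grid.
    """
    nx, ny = grid.dimensions
    mask = np.zeros((nx, ny), dtype=bool)
    if polygons.is_empty:
        return mask
    allv = np.vstack(polygons.polygons)
    lo = np.array(grid.origin)
    hi = lo + np.array([nx, ny]) * grid.pixel_size
    if np.any(allv.min(axis=0) < lo - 1e-9) or np.any(allv.max(axis=0) > hi + 1e-9):
        raise OutOfBoundsError("polygon extends beyond the raster grid")
    centres = grid.pixel_centres()
    inside = np.zeros(len(centres), dtype=int)
    for v in polygons.polygons:
        path = _MplPath(np.vstack([v, v[:1]]), closed=True)
        inside += path.contains_points(centres, radius=0.0)
    # even-odd: an odd crossing count across all polygons means "inside"
    return (inside % 2 == 1).reshape(nx, ny)


def mask_area(mask: np.ndarray, grid: RasterGrid) -> float:
    """Area (cm^2) represented by a rasterization mask."""
    return float(mask.sum()) * grid.pixel_size**2
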
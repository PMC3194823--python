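"""Planar geometric primitives shared by all territory estimators.

All geometry is planar Cartesian: coordinates are unitless in simulations
and metres for field data.  Bearings follow field convention — 0 degrees is
north and angles increase clockwise — and are converted internally to
mathematical (east, counter-clockwise) radians.

Polygons are represented with :class:`shapely.geometry.Polygon`; this module
adds the validation, bearing and ray-casting helpers the estimators need.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import shapely
import shapely.validation
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.polygon import orient


class InvalidGeometryError(ValueError):
    """A ring or polygon violates simplicity/validity requirements."""


class DomainError(ValueError):
    """An input point lies outside the geometric domain of an operation."""


class DegenerateInputError(ValueError):
    """Too few points, or all points collinear."""


class Point2(NamedTuple):
    """A point in the plane with finite coordinates."""

    x: float
    y: float

    @staticmethod
    def of(obj) -> "Point2":
        if isinstance(obj, Point2):
            return obj
        if isinstance(obj, Point):
            return Point2(obj.x, obj.y)
        x, y = obj
        return Point2(float(x), float(y))


def as_point_array(points: Iterable) -> np.ndarray:
    """Coerce an iterable of point-likes to an (n, 2) float array."""
    arr = np.asarray([tuple(Point2.of(p)) for p in points], dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if not np.all(np.isfinite(arr)):
        raise InvalidGeometryError("non-finite coordinates")
    return arr


def make_polygon(exterior: Sequence, holes: Sequence[Sequence] | None = None) -> Polygon:
    """Build a validated polygon: simple rings, CCW exterior, CW holes.

    Raises
    ------
    InvalidGeometryError
        if any ring self-intersects or the polygon is otherwise invalid.
    """
    poly = Polygon(exterior, holes)
    if not poly.is_valid:
        raise InvalidGeometryError(shapely.validation.explain_validity(poly))
    return orient(poly, sign=1.0)


def validate_polygon(poly: Polygon) -> Polygon:
    if not isinstance(poly, Polygon) or poly.is_empty:
        raise InvalidGeometryError("expected a non-empty polygon")
    if not poly.is_valid:
        raise InvalidGeometryError(shapely.validation.explain_validity(poly))
    return poly


def polygon_area(poly: Polygon) -> float:
    """Shoelace area of the exterior ring minus any holes (always >= 0)."""
    validate_polygon(poly)
    return float(poly.area)


def contains(poly: Polygon, p, tol: float = 1e-12) -> bool:
    """Even-odd containment; points on the boundary count as inside.

    ``tol`` absorbs floating-point fuzz for points constructed to lie on
    the boundary (e.g. ray/ring intersections).
    """
    validate_polygon(poly)
    pt = Point(*Point2.of(p))
    return bool(poly.covers(pt)) or poly.boundary.distance(pt) <= tol


def bearing_to_vector(bearing_deg: float) -> np.ndarray:
    """Unit vector for a geographic bearing (0 = north/+y, 90 = east/+x)."""
    rad = math.radians(bearing_deg)
    return np.array([math.sin(rad), math.cos(rad)])


def vector_to_bearing(dx: float, dy: float) -> float:
    """Geographic bearing in [0, 360) of the vector (dx, dy)."""
    return math.degrees(math.atan2(dx, dy)) % 360.0


def ray_boundary_intersections(
    poly: Polygon, origin, bearing_deg: float
) -> list[Point2]:
    """All crossings of the ray from ``origin`` with the exterior ring,
    ordered by increasing distance from the origin."""
    validate_polygon(poly)
    o = np.asarray(Point2.of(origin))
    direction = bearing_to_vector(bearing_deg)
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * math.hypot(maxx - minx, maxy - miny) + 1.0
    seg = LineString([o, o + reach * direction])
    inter = seg.intersection(LineString(poly.exterior.coords))
    pts: list[np.ndarray] = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.is_empty:
            continue
        if isinstance(geom, Point):
            pts.append(np.array([geom.x, geom.y]))
        else:  # collinear overlap: keep both ends of the overlapping piece
            pts.extend(np.asarray(geom.coords))
    pts.sort(key=lambda p: float(np.dot(p - o, direction)))
    return [Point2(*p) for p in pts]


def ray_outermost_intersection(
    poly: Polygon, origin, bearing_deg: float, crossing: str = "outermost"
) -> Point2:
    """Intersection of a ray from an interior point with the exterior ring.

    For concave boundaries the ray may cross several times; by default the
    outermost (farthest) crossing is returned, matching simulated trial
    endpoints placed on the outer edge of a territory.  Set
    ``crossing="first"`` for the nearest crossing instead.

    Raises
    ------
    DomainError
        if ``origin`` is not strictly inside the polygon.
    """
    o = Point2.of(origin)
    validate_polygon(poly)
    if not poly.contains(Point(*o)):
        raise DomainError(f"ray origin {tuple(o)} is not strictly inside the polygon")
    hits = ray_boundary_intersections(poly, o, bearing_deg)
    if not hits:  # impossible for a strictly interior origin
        raise RuntimeError("interior ray found no boundary crossing")
    return hits[-1] if crossing == "outermost" else hits[0]


def collinear(points: np.ndarray, tol: float = 1e-12) -> bool:
    """True when all points lie (numerically) on a single straight line."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return True
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    return bool(s[-1] / scale < tol)
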
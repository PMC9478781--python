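"""Planar geometry primitives shared by the whole pipeline.

All areal computations are planar (Cartesian) and delegate to shapely.
Coordinates are in an abstract length unit for synthetic geographies;
if projected real-world layers are supplied the unit is whatever the
projection uses (the pipeline carries the unit name as metadata only).

Great-circle distance (miles) is available behind an explicit flag for
callers whose center coordinates are geographic lon/lat.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Union

import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

Geometry = Union[Polygon, MultiPolygon]

#: Earth mean radius in miles, used only for the lon/lat distance mode.
EARTH_RADIUS_MILES = 3958.7613

#: Relative sliver tolerance: intersection areas below this fraction of
#: the smaller operand are treated as boundary artifacts, not overlap.
SLIVER_REL_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for invalid geometries (e.g. self-intersecting rings)."""


def _check_valid(geom: BaseGeometry, ident: str | None = None) -> BaseGeometry:
    if not geom.is_valid:
        label = f" for feature {ident!r}" if ident else ""
        raise GeometryError(f"invalid geometry{label}: {shapely.is_valid_reason(geom)}")
    return geom


def area(geom: Geometry, ident: str | None = None) -> float:
    """Planar area of a polygon or multipolygon; empty geometry -> 0."""
    if geom.is_empty:
        return 0.0
    _check_valid(geom, ident)
    return float(geom.area)


def intersection_area(a: Geometry, b: Geometry) -> float:
    """Area of the intersection of two geometries; 0 when disjoint."""
    _check_valid(a)
    _check_valid(b)
    if not a.intersects(b):
        return 0.0
    return float(a.intersection(b).area)


def symmetric_difference_area(a: Geometry, b: Geometry) -> float:
    """Area of the symmetric difference a XOR b; identical inputs -> 0."""
    _check_valid(a)
    _check_valid(b)
    return float(a.symmetric_difference(b).area)


def dissolve(polys: Iterable[Geometry]) -> Geometry:
    """Geometric union of a collection of polygons.

    Removes internal boundaries; the result is a Polygon or MultiPolygon
    (disconnected inputs yield a MultiPolygon).
    """
    polys = list(polys)
    if not polys:
        raise ValueError("dissolve requires at least one polygon")
    for p in polys:
        _check_valid(p)
    merged = unary_union(polys)
    if merged.is_empty:
        raise ValueError("dissolve produced an empty geometry")
    return merged


def distance(a: Sequence[float], b: Sequence[float], lonlat: bool = False) -> float:
    """Distance between two points.

    Euclidean in planar mode; great-circle miles (haversine) when
    ``lonlat`` is set and coordinates are (longitude, latitude) degrees.
    """
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    for v in (ax, ay, bx, by):
        if not math.isfinite(v):
            raise ValueError("non-finite coordinate in distance()")
    if not lonlat:
        return math.hypot(bx - ax, by - ay)
    lam1, phi1, lam2, phi2 = map(math.radians, (ax, ay, bx, by))
    h = (
        math.sin((phi2 - phi1) / 2.0) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_MILES * math.asin(math.sqrt(h))


def overlap_area(a: Geometry, b: Geometry, rel_tol: float = SLIVER_REL_TOL) -> float:
    """Intersection area with sliver suppression.

    Shared boundaries between adjacent cells of a tessellation can yield
    tiny positive intersection areas from floating-point noise; anything
    below ``rel_tol`` of the smaller operand's area is reported as 0 so
    that crosswalks and argmax assignments never pick up phantom overlap.
    """
    inter = intersection_area(a, b)
    floor = rel_tol * min(a.area, b.area)
    return inter if inter > floor else 0.0
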
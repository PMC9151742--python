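"""Vector-geometry kernel: equal-area projection, alpha-shape hulls,
perimeter construction with small-count fallbacks, and active-fireline
extraction.

All metre-valued thresholds of the tracking system (cluster linkage,
extended-area buffers, the 500 m fireline radius) and all km2 areas are
evaluated in a single equal-area projected plane, so the module starts with
a projection.  An Albers equal-area conic on the authalic sphere is used:
it is exactly area-preserving on the sphere, has a closed-form inverse, and
needs no external projection database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import (
    LinearRing,
    LineString,
    MultiPoint,
    MultiPolygon,
    Point,
    Polygon,
)
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

#: Authalic Earth radius (sphere of equal surface area to the WGS84 ellipsoid), m.
EARTH_RADIUS = 6_371_007.181


class AlbersEqualArea:
    """Albers equal-area conic projection on the authalic sphere.

    Parameters are the latitude/longitude of origin and the two standard
    parallels.  Forward maps (lat, lon) degrees to (x, y) metres; inverse
    recovers (lat, lon) to better than 1e-9 degrees.
    """

    def __init__(self, lat0: float = 0.0, lon0: float = -120.0,
                 lat1: float = 34.0, lat2: float = 40.5):
        self.lat0, self.lon0, self.lat1, self.lat2 = lat0, lon0, lat1, lat2
        p1, p2, p0 = map(math.radians, (lat1, lat2, lat0))
        self._n = (math.sin(p1) + math.sin(p2)) / 2.0
        if abs(self._n) < 1e-12:
            raise ValueError("standard parallels must not be symmetric about the equator")
        self._C = math.cos(p1) ** 2 + 2.0 * self._n * math.sin(p1)
        self._rho0 = EARTH_RADIUS * math.sqrt(self._C - 2.0 * self._n * math.sin(p0)) / self._n

    def forward(self, lat, lon):
        """(lat, lon) degrees -> (x, y) metres.  Accepts scalars or arrays."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        phi = np.radians(lat)
        n = self._n
        rho = EARTH_RADIUS * np.sqrt(self._C - 2.0 * n * np.sin(phi)) / n
        theta = n * np.radians(lon - self.lon0)
        x = rho * np.sin(theta)
        y = self._rho0 - rho * np.cos(theta)
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    def inverse(self, x, y):
        """(x, y) metres -> (lat, lon) degrees.  Accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = self._n
        rho = np.hypot(x, self._rho0 - y)
        theta = np.arctan2(np.sign(n) * x, np.sign(n) * (self._rho0 - y))
        sin_phi = (self._C - (rho * n / EARTH_RADIUS) ** 2) / (2.0 * n)
        lat = np.degrees(np.arcsin(np.clip(sin_phi, -1.0, 1.0)))
        lon = self.lon0 + np.degrees(theta / n)
        if x.ndim == 0:
            return float(lat), float(lon)
        return lat, lon

    def params(self) -> dict:
        return {"lat0": self.lat0, "lon0": self.lon0,
                "lat1": self.lat1, "lat2": self.lat2}


@dataclass
class HullGeometry:
    """A fire perimeter: polygon(al) shape in the metre plane."""

    shape: BaseGeometry  # Polygon or MultiPolygon, metres

    @property
    def area_km2(self) -> float:
        return self.shape.area / 1e6

    @property
    def boundary_km(self) -> float:
        return self.shape.boundary.length / 1e3

    @property
    def npart(self) -> int:
        return len(self.shape.geoms) if isinstance(self.shape, MultiPolygon) else 1


@dataclass
class FirelineGeometry:
    """The actively burning subset of a hull boundary (possibly empty)."""

    shape: BaseGeometry  # LineString / MultiLineString / LinearRing / empty

    @property
    def length_km(self) -> float:
        return self.shape.length / 1e3


class DegenerateGeometryError(ValueError):
    """Raised when an alpha shape cannot be built from the given points."""


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay triangle (vectorised)."""
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    # area via cross product; degenerate (collinear) triangles get R = inf
    cross = np.abs((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * cross)
    r[cross == 0.0] = np.inf
    return r


def alpha_shape(points: np.ndarray, alpha: float) -> BaseGeometry:
    """Concave hull of 2-D points: union of Delaunay triangles whose
    circumradius is at most ``alpha``.

    ``alpha`` is the radius (metres) of the disks that carve the concave
    boundary; as ``alpha`` grows the result converges to the convex hull.
    The result may be a MultiPolygon when the point set has gaps wider than
    the disk diameter.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 4 distinct points or a collinear configuration:
        callers must use the small-count fallbacks of :func:`fire_hull`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 4:
        raise DegenerateGeometryError(f"alpha shape needs >= 4 distinct points, got {len(uniq)}")
    try:
        tri = Delaunay(uniq)
    except QhullError as e:
        raise DegenerateGeometryError(f"degenerate point configuration: {e}") from e
    keep = _circumradii(uniq, tri.simplices) <= alpha
    if not keep.any():
        return Polygon()  # every triangle too thin/large: caller falls back
    triangles = [Polygon(uniq[s]) for s in tri.simplices[keep]]
    return unary_union(triangles)


def fire_hull(points: np.ndarray, alpha: float = 1000.0,
              buffer: float = 187.5) -> HullGeometry:
    """Fire perimeter from pixel locations in the metre plane.

    For >= 4 points the alpha shape is used; 3 points fall back to the
    convex hull; 1-2 points to discs of radius ``buffer`` centred on the
    points.  The hull is expanded outward by ``buffer`` (round joins) to
    account for the finite detection footprint, and any point left outside
    (an isolated detection not in any retained triangle) is covered by
    adding its disc, so every input point lies inside the result.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("fire_hull requires at least one point")
    npix = len(pts)
    if npix <= 2:
        # fine discretisation: the disc area should match pi r^2 closely
        return HullGeometry(unary_union(
            [Point(p).buffer(buffer, quad_segs=256) for p in pts]))
    discs = [Point(p).buffer(buffer, quad_segs=32) for p in pts]
    if npix == 3:
        base = MultiPoint(pts).convex_hull
    else:
        try:
            base = alpha_shape(pts, alpha)
        except DegenerateGeometryError:
            base = MultiPoint(pts).convex_hull  # collinear >= 4 points
    if base.is_empty or base.area == 0.0:
        # no triangle survived the circumradius cut: per-pixel discs
        return HullGeometry(unary_union(discs))
    shape = base.buffer(buffer, quad_segs=32, join_style="round")
    uncovered = [d for p, d in zip(pts, discs) if not shape.covers(Point(p))]
    if uncovered:
        shape = unary_union([shape] + uncovered)
    return HullGeometry(shape)


def active_fireline(hull: HullGeometry, new_points: np.ndarray,
                    radius: float = 500.0) -> FirelineGeometry:
    """Actively burning portion of a fire perimeter.

    Returns the subset of the hull boundary lying within ``radius`` metres
    of any newly detected pixel: a linestring, multi-linestring, or — when
    new detections ring the whole perimeter — a closed linear ring.  Empty
    when there are no new points.
    """
    pts = np.asarray(new_points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return FirelineGeometry(LineString())
    boundary = hull.shape.boundary
    near = unary_union([Point(p).buffer(radius, quad_segs=32) for p in pts])
    fline = boundary.intersection(near)
    if fline.is_empty:
        return FirelineGeometry(LineString())
    # a fully covered simple boundary comes back as the whole ring
    if fline.equals(boundary) and isinstance(fline, LineString) and fline.is_closed:
        fline = LinearRing(fline.coords)
    return FirelineGeometry(fline)
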
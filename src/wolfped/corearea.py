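"""Spatio-temporal assignment of territories to recolonization core areas
and minimum-convex-polygon construction."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from shapely.geometry import MultiPoint
from shapely.geometry.polygon import orient

from .geo import vincenty_km


@dataclass
class Territory:
    code: str
    lat: float
    lon: float
    founding_year: int


@dataclass
class ConvexPolygon:
    vertices: tuple[tuple[float, float], ...]   # (x, y), counter-clockwise
    degenerate: bool = False


def minimum_convex_polygon(points: list[tuple[float, float]]) -> ConvexPolygon:
    """Planar convex hull with counter-clockwise vertex order.

    Fewer than three distinct non-collinear points yield a degenerate result
    (the flagged hull holds whatever shapely returns: point or segment ends).
    """
    if not points:
        raise ValueError("no points")
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if hull.geom_type != "Polygon":
        coords = tuple(dict.fromkeys(map(tuple, hull.coords)))
        return ConvexPolygon(coords, degenerate=True)
    ring = orient(hull, sign=1.0).exterior.coords
    return ConvexPolygon(tuple(map(tuple, list(ring)[:-1])), degenerate=False)


@dataclass
class CoreAreaAssignment:
    assignment: dict[str, str]                 # territory -> area label
    seeds: dict[str, tuple[str, int]]
    unassigned: list[str] = field(default_factory=list)
    polygons: dict[str, ConvexPolygon] = field(default_factory=dict)


def assign_core_areas(territories: list[Territory],
                      seeds: dict[str, tuple[str, int]],
                      max_distance_km: float | None = None,
                      ) -> CoreAreaAssignment:
    """Greedy spatio-temporal clustering of territories around seed packs.

    Territories are processed in founding order (year, then code).  Each one
    joins the area of the nearest already-assigned territory founded no later
    than itself; ties break by the smaller founding-year gap, then by area
    label order.  Territories farther than ``max_distance_km`` from every
    eligible member stay unassigned.
    """
    by_code = {t.code: t for t in territories}
    seed_codes = {code for code, _ in seeds.values()}
    if len(seed_codes) != len(seeds):
        raise ValueError("seed territories must be pairwise distinct")
    for label, (code, year) in seeds.items():
        if code not in by_code:
            raise ValueError(f"seed territory {code} unknown")

    assignment: dict[str, str] = {}
    for label in sorted(seeds):
        assignment[seeds[label][0]] = label

    first_seed_year = min(year for _, year in seeds.values())
    rest = sorted((t for t in territories if t.code not in assignment),
                  key=lambda t: (t.founding_year, t.code))
    unassigned: list[str] = []
    for t in rest:
        if t.founding_year < first_seed_year:
            raise ValueError(f"territory {t.code} founded before every seed")
        best = None
        for code, label in assignment.items():
            member = by_code[code]
            if member.founding_year > t.founding_year:
                continue
            d = vincenty_km(t.lat, t.lon, member.lat, member.lon)
            key = (d, t.founding_year - member.founding_year, label)
            if best is None or key < best[0]:
                best = (key, label)
        if best is None or (max_distance_km is not None
                            and best[0][0] > max_distance_km):
            unassigned.append(t.code)
            continue
        assignment[t.code] = best[1]

    polygons = {}
    member_pts: dict[str, list[tuple[float, float]]] = {}
    for code, label in assignment.items():
        member_pts.setdefault(label, []).append((by_code[code].lon,
                                                 by_code[code].lat))
    for label, pts in member_pts.items():
        if len(pts) >= 3:
            polygons[label] = _hull_equirectangular(pts)
    return CoreAreaAssignment(assignment, dict(seeds), unassigned, polygons)


def _hull_equirectangular(lonlat: list[tuple[float, float]]) -> ConvexPolygon:
    """Hull computed in an equirectangular projection about the centroid,
    returned in lon/lat coordinates (regional extents only)."""
    lon0 = sum(p[0] for p in lonlat) / len(lonlat)
    lat0 = sum(p[1] for p in lonlat) / len(lonlat)
    k = math.cos(math.radians(lat0))
    proj = [((lon - lon0) * k, lat - lat0) for lon, lat in lonlat]
    hull = minimum_convex_polygon(proj)
    verts = tuple((round(x / k + lon0, 12), round(y + lat0, 12))
                  for x, y in hull.vertices)
    return ConvexPolygon(verts, hull.degenerate)


def polygons_geojson(result: CoreAreaAssignment) -> dict:
    feats = []
    for label, poly in sorted(result.polygons.items()):
        ring = list(poly.vertices) + [poly.vertices[0]]
        feats.append({"type": "Feature",
                      "properties": {"core_area": label},
                      "geometry": {"type": "Polygon",
                                   "coordinates": [ring]}})
    return {"type": "FeatureCollection", "features": feats}
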
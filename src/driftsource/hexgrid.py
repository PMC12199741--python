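"""Hexagonal settlement tessellation.

Potential landing areas are pointy-top hexagons of fixed horizontal
(edge-to-edge) width laid out in planar lon/lat coordinates — the usual GIS
treatment of a territorial-sea shapefile.  A cell is *active* when it
intersects at least one habitat polygon and no exclusion polygon; backtracked
particles are assigned an origin on first entering an active cell.

Grids may span the 0/360 longitude seam: internally cells live in a continuous
(unwrapped) longitude window starting at the bbox's western edge and point
queries are mapped into that window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Iterable, List, Optional

import numpy as np
import shapely
from shapely.affinity import translate
from shapely.geometry import Polygon, Point, shape, mapping
from shapely.strtree import STRtree

from .errors import GeometryError, ValidationError

SQRT3 = np.sqrt(3.0)


@dataclass
class HexCell:
    id: int
    center: tuple
    polygon: Polygon
    active: bool = False

    @property
    def vertices(self):
        """Six ordered (lon, lat) vertex pairs."""
        return list(self.polygon.exterior.coords)[:6]


def _hexagon(cx: float, cy: float, circumradius: float) -> Polygon:
    # pointy-top: vertices at 90° + k*60°
    ang = np.radians(90 + 60 * np.arange(6))
    return Polygon(zip(cx + circumradius * np.cos(ang), cy + circumradius * np.sin(ang)))


def build_hex_grid(lon_range, lat_range, cell_size: float = 1.0) -> List[HexCell]:
    """Tile a lon/lat bbox with pointy-top hexagons of horizontal width ``cell_size``°.

    ``lon_range`` is wrap-aware: (350, 20) spans the seam.  Cells are returned
    in row-major order with sequential ids; the tiling covers the bbox with no
    gaps or interior overlaps.
    """
    if cell_size <= 0:
        raise ValidationError("cell_size must be positive")
    lon0, lon1 = float(lon_range[0]), float(lon_range[1])
    lat0, lat1 = float(lat_range[0]), float(lat_range[1])
    extent = lon1 - lon0
    if extent <= 0:
        extent += 360.0
    if extent > 360.0:
        raise ValidationError("bbox spans more than 360 degrees of longitude")
    if lat1 <= lat0:
        raise ValidationError("degenerate latitude range")

    w = cell_size                 # horizontal edge-to-edge width
    s = w / SQRT3                 # circumradius
    dy = 1.5 * s                  # row spacing
    cells: List[HexCell] = []
    cid = 0
    row = 0
    cy = lat0 - s
    while cy <= lat1 + s + 1e-12:
        xoff = (w / 2.0) if (row % 2) else 0.0
        cx = lon0 - w + xoff
        while cx <= lon0 + extent + w + 1e-12:
            cells.append(HexCell(id=cid, center=(cx, cy), polygon=_hexagon(cx, cy, s)))
            cid += 1
            cx += w
        row += 1
        cy = lat0 - s + row * dy
    return cells


@dataclass
class SettlementSet:
    """Hex cells with activation state, exclusions, and point location."""

    cells: List[HexCell]
    excluded_ids: frozenset = frozenset()
    provenance: str = ""
    _tree: Optional[STRtree] = dc_field(default=None, repr=False, compare=False)
    _tree_ids: Optional[np.ndarray] = dc_field(default=None, repr=False, compare=False)
    _lon_west: float = dc_field(default=0.0, repr=False, compare=False)

    def __post_init__(self):
        self.excluded_ids = frozenset(self.excluded_ids)
        for c in self.cells:
            if c.id in self.excluded_ids:
                c.active = False
        xs = [c.polygon.bounds[0] for c in self.cells]
        self._lon_west = min(xs) if xs else 0.0

    @property
    def active_ids(self) -> frozenset:
        return frozenset(c.id for c in self.cells if c.active)

    def _ensure_tree(self):
        if self._tree is None:
            act = [c for c in self.cells if c.active]
            self._tree = STRtree([c.polygon for c in act]) if act else STRtree([Point()])
            self._tree_ids = np.array([c.id for c in act], dtype=int)

    def locate_many(self, lons, lats) -> np.ndarray:
        """Active cell id containing each point, or -1; shared edges resolve to
        the lowest id."""
        self._ensure_tree()
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        # map into the grid's unwrapped longitude window
        q = self._lon_west + (lons - self._lon_west) % 360.0
        out = np.full(lons.size, -1, dtype=int)
        if self._tree_ids.size == 0:
            return out
        pts = shapely.points(q, lats)
        pi, ti = self._tree.query(pts, predicate="covered_by")
        for p, t in zip(pi, ti):
            cid = self._tree_ids[t]
            if out[p] < 0 or cid < out[p]:
                out[p] = cid
        return out

    def locate(self, lon, lat):
        """Single-point version of :meth:`locate_many`; returns id or None."""
        r = int(self.locate_many([lon], [lat])[0])
        return None if r < 0 else r


def _validated(polys: Iterable, what: str):
    polys = list(polys)
    for i, p in enumerate(polys):
        if not p.is_valid:
            raise GeometryError(f"{what} polygon {i} is invalid")
    return polys


def activate_cells(cells: List[HexCell], habitat, exclusions=(),
                   provenance: str = "") -> SettlementSet:
    """Flag cells intersecting habitat and not intersecting any exclusion.

    Intersection tests are wrap-aware: each input polygon is also tried
    shifted by ±360° so habitat near the seam activates cells on either side.
    """
    habitat = _validated(habitat, "habitat")
    exclusions = _validated(exclusions, "exclusion")
    shifts = (-360.0, 0.0, 360.0)
    tree = STRtree([c.polygon for c in cells])

    def hit_ids(polys):
        ids = set()
        for p in polys:
            for dx in shifts:
                g = translate(p, xoff=dx) if dx else p
                ids.update(int(i) for i in tree.query(g, predicate="intersects"))
        return ids

    hab = hit_ids(habitat)
    excl = hit_ids(exclusions)
    excluded_ids = frozenset(cells[i].id for i in excl)
    for i, c in enumerate(cells):
        c.active = (i in hab) and (i not in excl)
    return SettlementSet(cells=cells, excluded_ids=excluded_ids, provenance=provenance)


# ----------------------------------------------------------------------
# GeoJSON I/O


def read_polygons(path) -> List[Polygon]:
    """Read (Multi)Polygons from a GeoJSON file or FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []
    feats = gj.get("features", [gj]) if gj.get("type") == "FeatureCollection" else [gj]
    for f in feats:
        g = shape(f.get("geometry", f))
        if g.geom_type == "MultiPolygon":
            geoms.extend(g.geoms)
        else:
            geoms.append(g)
    return geoms


def write_polygons(polys, path):
    fc = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "properties": {}, "geometry": mapping(p)}
                       for p in polys]}
    with open(path, "w") as fh:
        json.dump(fc, fh)


def export_geojson(settlement: SettlementSet, path, counts=None):
    """Write the grid as GeoJSON with activity flags and optional landing counts."""
    counts = counts or {}
    feats = []
    for c in settlement.cells:
        feats.append({
            "type": "Feature",
            "properties": {"id": c.id, "active": bool(c.active),
                           "landings": int(counts.get(c.id, 0))},
            "geometry": mapping(c.polygon),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
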
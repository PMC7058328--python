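"""Landscape composition, configuration and patch-geometry metrics.

The patch-landscape design treats each habitat patch as the observation
unit. Composition is measured in buffer rings around the patch boundary at a
set of nested scales; configuration covers isolation (nearest-patch distance
and the proximity index) and distances to linear/areal landscape elements.

Conventions
-----------
* Vector polygons are authoritative for geometry; the raster is
  authoritative for composition. Cell membership is decided by the cell
  center falling inside a region.
* Buffer rings are measured from the patch boundary outward and exclude the
  focal patch interior: a cell belongs to the ring at scale ``s`` iff
  ``0 < d(center, patch) <= s``.
* The proximity index follows the area / edge-to-edge-distance form; the
  squared-distance variant used by some landscape-metrics software is
  available via ``squared=True``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .grid import Grid

__all__ = [
    "ScaleSet",
    "PatchRecord",
    "DEFAULT_SCALES",
    "buffer_composition",
    "composition_profile",
    "proximity_index",
    "nearest_patch_distance",
    "distance_to_class",
    "distance_to_feature",
    "patch_geometry",
]

#: Buffer distances (m) spanning reported dispersal distances of the species.
DEFAULT_SCALES: tuple[float, ...] = (50, 150, 250, 500, 750, 1000, 1500, 2000, 2500, 3000)


@dataclass(frozen=True)
class ScaleSet:
    """Ordered set of buffer distances in meters."""

    scales: tuple[float, ...] = DEFAULT_SCALES

    def __post_init__(self) -> None:
        s = tuple(self.scales)
        if len(s) == 0 or any(a <= 0 for a in s):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", s)

    def __iter__(self):
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)


@dataclass
class PatchRecord:
    """All per-patch metrics for one habitat patch."""

    patch_id: str
    polygon: Polygon
    area: float
    perimeter: float
    per_area: float
    shape_index: float
    np_dist: float | None = None
    prox: dict[float, float] | None = None
    dist_river: float | None = None
    dist_urban: float | None = None
    dist_crop: float | None = None
    composition: dict[float, dict[str, float]] | None = None


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _ring_cell_values(
    grid: Grid, polygon: Polygon, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Values and center-distances of cells in the ring at the largest scale.

    Returns (values, distances) for cells within ``scale`` of the patch and
    outside it, restricted to the raster extent. Distances are from cell
    center to the patch polygon (0 inside the patch, which is excluded).
    """
    xmin, ymin, xmax, ymax = polygon.bounds
    xs = grid.x_centers()
    ys = grid.y_centers()
    ci = np.nonzero((xs >= xmin - scale) & (xs <= xmax + scale))[0]
    ri = np.nonzero((ys >= ymin - scale) & (ys <= ymax + scale))[0]
    if ci.size == 0 or ri.size == 0:
        return np.empty(0), np.empty(0)
    X, Y = np.meshgrid(xs[ci], ys[ri])
    pts = shapely.points(X.ravel(), Y.ravel())
    dist = shapely.distance(pts, polygon)
    sel = (dist > 0) & (dist <= scale)
    vals = grid.data[np.ix_(ri, ci)].ravel()[sel]
    return vals, dist[sel]


def buffer_composition(
    grid: Grid,
    polygon: Polygon,
    scale: float,
    class_map: dict[str, int],
    habitat_classes: tuple[str, ...] = (),
) -> dict[str, float]:
    """Proportion of each land-cover class in the buffer ring at one scale.

    The ring is the set of raster cells whose centers lie within ``scale``
    meters of the patch polygon but outside it. Proportions are taken over
    classified (non-nodata) ring cells and sum to 1 over the base classes.
    When ``habitat_classes`` is given, an aggregate ``"habitat"`` entry (the
    sum of those base-class proportions) is added.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    vals, _ = _ring_cell_values(grid, polygon, scale)
    return _composition_from_values(vals, grid.nodata, class_map, habitat_classes)


def _composition_from_values(vals, nodata, class_map, habitat_classes):
    vals = vals[vals != nodata]
    if vals.size == 0:
        raise ValueError("buffer ring contains no classified cells")
    out: dict[str, float] = {}
    n = vals.size
    for name, code in class_map.items():
        out[name] = float((vals == code).sum()) / n
    if habitat_classes:
        out["habitat"] = float(sum(out.get(h, 0.0) for h in habitat_classes))
    return out


def composition_profile(
    grid: Grid,
    polygon: Polygon,
    scales: ScaleSet | tuple[float, ...],
    class_map: dict[str, int],
    habitat_classes: tuple[str, ...] = (),
) -> dict[float, dict[str, float]]:
    """Buffer composition at every scale, sharing one distance computation."""
    scales = tuple(scales)
    vals, dist = _ring_cell_values(grid, polygon, max(scales))
    out: dict[float, dict[str, float]] = {}
    for s in scales:
        out[s] = _composition_from_values(vals[dist <= s], grid.nodata, class_map, habitat_classes)
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def proximity_index(
    patches: dict[object, Polygon],
    focal_id: object,
    scale: float,
    squared: bool = False,
    min_distance: float = 5.0,
) -> float:
    """Scale-dependent isolation: sum of area / distance over buffer neighbors.

    Neighbors are every non-focal patch whose polygon intersects the buffer
    of radius ``scale`` around the focal patch — a patch straddling the
    buffer boundary is counted in full. Distance is edge-to-edge; touching
    patches have their distance floored at ``min_distance`` (one cell size)
    so the index stays finite. ``squared=True`` divides by distance².
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    focal = patches[focal_id]
    buf = focal.buffer(scale)
    total = 0.0
    for pid, poly in patches.items():
        if pid == focal_id or not poly.intersects(buf):
            continue
        d = max(focal.distance(poly), min_distance)
        total += poly.area / (d * d if squared else d)
    return total


def nearest_patch_distance(patches: dict[object, Polygon], focal_id: object) -> float:
    """Edge-to-edge Euclidean distance to the nearest other patch."""
    focal = patches[focal_id]
    others = [p for pid, p in patches.items() if pid != focal_id]
    if not others:
        raise ValueError("nearest_patch_distance requires at least two patches")
    return float(min(focal.distance(p) for p in others))


def distance_to_class(grid: Grid, polygon: Polygon, class_code: int) -> float:
    """Distance from the patch edge to the nearest cell of a raster class.

    Cells are treated as filled squares, so a patch touching or overlapping
    a class cell is at distance 0. Raises if the class is absent from the
    raster.
    """
    mask = grid.data == class_code
    if not mask.any():
        raise ValueError(f"class code {class_code} absent from raster")
    xs = grid.x_centers()
    ys = grid.y_centers()
    half = grid.cellsize / 2.0
    xmin, ymin, xmax, ymax = polygon.bounds
    bx0, by0, bx1, by1 = grid.bounds
    diag = float(np.hypot(bx1 - bx0, by1 - by0))
    r = 10 * grid.cellsize
    while True:
        ci = np.nonzero((xs >= xmin - r) & (xs <= xmax + r))[0]
        ri = np.nonzero((ys >= ymin - r) & (ys <= ymax + r))[0]
        sub = mask[np.ix_(ri, ci)]
        rr, cc = np.nonzero(sub)
        if rr.size:
            cx = xs[ci][cc]
            cy = ys[ri][rr]
            boxes = shapely.box(cx - half, cy - half, cx + half, cy + half)
            dmin = float(shapely.distance(boxes, polygon).min())
            # the search window must be wide enough that no closer cell
            # outside it can exist
            if dmin <= r - grid.cellsize or r > diag:
                return dmin
            r = dmin + 2 * grid.cellsize
        else:
            if r > diag:
                raise ValueError("no class cells reachable within the raster extent")
            r *= 2


def distance_to_feature(polygon: Polygon, feature: BaseGeometry) -> float:
    """Distance from the patch edge to a vector feature (e.g. river polyline)."""
    return float(polygon.distance(feature))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def patch_geometry(polygon: Polygon) -> dict[str, float]:
    """Area, perimeter, perimeter/area ratio and square-normalized shape index.

    ``shape_index = perimeter / (4 * sqrt(area))`` equals 1 for a square and
    grows with boundary irregularity.
    """
    area = polygon.area
    if area <= 0:
        raise ValueError("degenerate polygon: zero area")
    perimeter = polygon.length
    return {
        "area": float(area),
        "perimeter": float(perimeter),
        "per_area": float(perimeter / area),
        "shape_index": float(perimeter / (4.0 * np.sqrt(area))),
    }
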
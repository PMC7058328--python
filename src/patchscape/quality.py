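"""Habitat-quality covariates: foliage height diversity, vegetation
structure and DEM-derived slope.

Foliage height diversity (FHD) is the Shannon entropy of a plot's vegetation
coverage distributed over structural classes. A patch's vegetation structure
(``veg_str``) is the mean FHD of each habitat type — pooled across patches
within a region, since single patches rarely sample every type — weighted by
the area each habitat type occupies within the patch.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = [
    "COVERAGE_CLASSES",
    "fhd",
    "pooled_fhd_by_type",
    "patch_veg_structure",
    "dem_slope",
    "horn_slope",
]

#: The nine structural coverage classes recorded in each 25 m² plot.
COVERAGE_CLASSES = (
    "herbs_lt30cm",
    "herbs_40_80cm",
    "herbs_gt90cm",
    "woody_lt2m",
    "woody_gt2m",
    "dry_leaves",
    "rocks_trunks",
    "bare_soil",
    "branches",
)


def fhd(coverages, base: str = "e", mask=None) -> float:
    """Foliage height diversity of one plot's coverage vector.

    Shannon entropy of the normalized coverage proportions: with
    ``q_k = c_k / sum(c)``, FHD = −Σ q_k ln q_k over positive classes.
    Ranges from 0 (one class only) to ln(K) (uniform over K classes).

    Parameters
    ----------
    coverages : array-like
        Coverage percentages per structural class (need not sum to 100).
    base : {"e", "2"}
        Logarithm base; natural log is the Shannon convention.
    mask : boolean array-like, optional
        Classes to include (e.g. to exclude non-foliage categories).
    """
    c = np.asarray(coverages, dtype=float)
    if mask is not None:
        c = c[np.asarray(mask, dtype=bool)]
    if np.any(c < 0):
        raise ValueError("coverages must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero coverage vector: FHD undefined")
    q = c[c > 0] / total
    h = float(-(q * np.log(q)).sum())
    if base == "2":
        h /= np.log(2.0)
    return h


def pooled_fhd_by_type(
    plots: pd.DataFrame,
    coverage_columns=COVERAGE_CLASSES,
    type_column: str = "habitat_type",
    **fhd_kwargs,
) -> dict[str, float]:
    """Mean plot FHD per habitat type, pooling plots across patches."""
    out: dict[str, list[float]] = {}
    for _, row in plots.iterrows():
        out.setdefault(row[type_column], []).append(
            fhd(row[list(coverage_columns)].to_numpy(dtype=float), **fhd_kwargs)
        )
    return {t: float(np.mean(v)) for t, v in out.items()}


def patch_veg_structure(
    mean_fhd: dict[str, float], habitat_type_areas: dict[str, float]
) -> float:
    """Area-weighted mean FHD over the habitat types within a patch.

    ``veg_str = Σ_h FHD̄_h * A_h / Σ_h A_h``; the weights sum to 1 so the
    result is a convex combination of the per-type mean FHD values.
    """
    areas = {t: a for t, a in habitat_type_areas.items() if a > 0}
    if not areas:
        raise ValueError("patch has no habitat-type area")
    missing = sorted(set(areas) - set(mean_fhd))
    if missing:
        raise ValueError(
            f"habitat types with area but no FHD estimate: {', '.join(missing)}"
        )
    total = sum(areas.values())
    return float(sum(mean_fhd[t] * a / total for t, a in areas.items()))


def horn_slope(dem: Grid) -> np.ndarray:
    """Per-cell slope in degrees by Horn's 3×3 finite differences.

    Edge cells use replicated padding. Slope is
    ``atan(sqrt(gx² + gy²))`` with gradients in rise/run units.
    """
    z = np.pad(np.asarray(dem.data, dtype=float), 1, mode="edge")
    cs = dem.cellsize
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def dem_slope(dem: Grid, polygon) -> float:
    """Mean Horn slope (degrees) over DEM cells whose centers fall in the patch.

    If the patch is smaller than one DEM cell and contains no center, the
    slope of the cell containing the patch centroid is used.
    """
    import shapely

    slope = horn_slope(dem)
    X, Y = dem.center_mesh()
    xmin, ymin, xmax, ymax = polygon.bounds
    bx0, by0, bx1, by1 = dem.bounds
    if xmax < bx0 or xmin > bx1 or ymax < by0 or ymin > by1:
        raise ValueError("patch lies outside the DEM extent")
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel())
    if inside.any():
        return float(slope.ravel()[inside].mean())
    cx, cy = polygon.centroid.x, polygon.centroid.y
    if not (bx0 <= cx <= bx1 and by0 <= cy <= by1):
        raise ValueError("patch lies outside the DEM extent")
    r, c = dem.rowcol(cx, cy)
    return float(slope[int(np.clip(r, 0, dem.nrows - 1)), int(np.clip(c, 0, dem.ncols - 1))])
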
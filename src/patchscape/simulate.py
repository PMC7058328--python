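"""Synthetic landscapes, covariates and detection histories with known truth.

Two generators are provided, both seeded and bit-reproducible:

* The full landscape generator builds a land-cover raster (habitat patches
  in a crop/urban matrix crossed by a one-cell-wide river), patch polygons,
  a coarse DEM, the complete covariate table (composition at every buffer
  scale, isolation, distances, geometry, vegetation structure, slope,
  radiation, day of survey) and detection histories from logit-linear
  occupancy and detection models. Defaults emulate the study conditions the
  analysis is designed for: ~40 patches, two surveys per patch, and a low
  landscape habitat proportion (~12%).

* :func:`simulate_occupancy_study` is a lightweight ring-based sampler for
  the scale-of-effect and parameter-recovery experiments: composition at
  nested buffer scales is built from independent per-ring habitat
  densities accumulated area-weighted outward, which reproduces the
  geometry (and hence inter-scale correlation) of nested buffers without
  rasterizing a landscape.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union

from . import io as psio
from .data import DetectionTable
from .grid import Grid
from .metrics import (
    DEFAULT_SCALES,
    composition_profile,
    distance_to_class,
    distance_to_feature,
    nearest_patch_distance,
    patch_geometry,
    proximity_index,
)
from .quality import COVERAGE_CLASSES, dem_slope, patch_veg_structure, pooled_fhd_by_type
from .selection import scale_column

__all__ = [
    "DEFAULT_CLASS_CODES",
    "DEFAULT_HABITAT_CLASSES",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_landscape",
    "simulate_covariates",
    "simulate_detections",
    "simulate_dataset",
    "write_dataset",
    "simulate_nested_composition",
    "simulate_occupancy_study",
]

#: Land-cover class codes (river carries its own code for rasterization).
DEFAULT_CLASS_CODES: dict[str, int] = {
    "bare_soil": 1,
    "rocky_veg": 2,
    "grass": 3,
    "dry_grass": 4,
    "humid_grass": 5,
    "shrubland": 6,
    "trans_veg": 7,
    "woodland": 8,
    "openwood": 9,
    "densewood": 10,
    "crop_pas": 11,
    "urban": 12,
    "river": 13,
}

#: Classes counted as habitat in the default scenario.
DEFAULT_HABITAT_CLASSES: tuple[str, ...] = (
    "bare_soil",
    "rocky_veg",
    "grass",
    "shrubland",
    "trans_veg",
    "woodland",
)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic region.

    ``true_psi_coefs`` is (β0, one coefficient per entry of
    ``psi_covariates``) on the logit scale applied to z-scored covariates;
    composition names among the occupancy covariates are taken at
    ``true_scale_m``. ``true_p_coefs`` is (α0, α_veg, α_day, α_area).
    """

    extent_m: tuple[float, float] = (4000.0, 4000.0)
    cell_size_m: float = 5.0
    n_patches: int = 40
    habitat_fraction_target: float = 0.12
    class_codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_CODES))
    habitat_classes: tuple[str, ...] = DEFAULT_HABITAT_CLASSES
    river: list[tuple[float, float]] | None = None  # None: generated from seed
    scales: tuple[float, ...] = DEFAULT_SCALES
    psi_covariates: tuple[str, ...] = ("habitat",)
    true_psi_coefs: tuple[float, ...] = (0.0, 1.5)
    true_scale_m: float = 250.0
    true_p_coefs: tuple[float, ...] = (0.85, -0.4, 0.3, 0.2)
    n_surveys: int = 2
    matrix_crop_fraction: float = 0.7
    irregular_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.habitat_fraction_target < 1.0:
            raise ValueError("habitat_fraction_target must be in (0, 1)")
        if self.true_scale_m not in tuple(self.scales):
            raise ValueError("true_scale_m must belong to the configured scale set")
        if self.n_surveys < 2:
            raise ValueError("need at least two surveys per patch")
        if len(self.true_psi_coefs) != 1 + len(self.psi_covariates):
            raise ValueError("true_psi_coefs must be (intercept, one per psi covariate)")
        w, h = self.extent_m
        cs = self.cell_size_m
        if abs(w / cs - round(w / cs)) > 1e-9 or abs(h / cs - round(h / cs)) > 1e-9:
            raise ValueError("extent must be divisible by the cell size")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extent_m"] = list(self.extent_m)
        return d


@dataclass
class SyntheticTruth:
    """Latent state and true probabilities behind a simulated table."""

    latent_z: pd.Series
    psi_true: pd.Series
    p_true: pd.DataFrame


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _generate_river(config: SimulationConfig, rng: np.random.Generator) -> LineString:
    w, h = config.extent_m
    cs = config.cell_size_m
    n_vertices = max(8, int(w / (20 * cs)))
    xs = np.linspace(0, w, n_vertices)
    y = np.cumsum(rng.normal(0.0, h * 0.02, size=n_vertices))
    y = gaussian_filter1d(y, 2.0)
    y = h / 2 + y - y.mean()
    y = np.clip(y, 0.15 * h, 0.85 * h)
    return LineString(np.column_stack([xs, y]))


def _rasterize_river(river: LineString, grid: Grid, code: int) -> None:
    """Burn a 1-cell-wide river by sampling the polyline densely."""
    length = river.length
    step = grid.cellsize / 2.0
    ts = np.arange(0, length + step, step)
    pts = [river.interpolate(t) for t in ts]
    r, c = grid.rowcol(np.array([p.x for p in pts]), np.array([p.y for p in pts]))
    ok = (r >= 0) & (r < grid.nrows) & (c >= 0) & (c < grid.ncols)
    grid.data[r[ok], c[ok]] = code


def generate_landscape(config: SimulationConfig):
    """Build the land-cover raster, patch polygons, river and DEM.

    Patches are axis-aligned rectangles, half of them (on average) extended
    with a flange into an L-shape so the shape index varies. Placement
    keeps patches disjoint (>= 2 cells apart) and off the river. Raises if
    the target habitat fraction is infeasible for the requested patch count
    and extent, or if the realized fraction misses the target by more than
    3 percentage points.

    Returns ``(landcover, patches, river, dem, habitat_type_cells)`` where
    ``habitat_type_cells`` maps patch id -> habitat class -> cell count.
    """
    w, h = config.extent_m
    cs = config.cell_size_m
    ncols, nrows = int(round(w / cs)), int(round(h / cs))
    total_cells = ncols * nrows
    target_cells = int(round(config.habitat_fraction_target * total_cells))
    if config.n_patches < 1:
        raise ValueError("need at least one patch")
    if config.habitat_fraction_target > 0.45 and config.n_patches > 1:
        raise ValueError("habitat fraction above 0.45 is infeasible for disjoint patches")
    if target_cells < 4 * config.n_patches:
        raise ValueError("habitat target too small for the requested patch count")

    rng = np.random.default_rng([config.seed, 1])
    grid = Grid(np.zeros((nrows, ncols), dtype=np.int16), cs, 0.0, 0.0, nodata=-9999)

    river = (
        LineString(config.river) if config.river is not None else _generate_river(config, rng)
    )
    river_code = config.class_codes["river"]
    habitat_codes = [config.class_codes[c] for c in config.habitat_classes]

    # degenerate fill: one patch covering the whole extent
    if config.n_patches == 1 and config.habitat_fraction_target >= 0.97:
        code = habitat_codes[0]
        grid.data[:, :] = code
        poly = box(0.0, 0.0, w, h)
        dem = _generate_dem(w, h, rng)
        return (
            grid,
            {"p000": poly},
            river,
            dem,
            {"p000": {config.habitat_classes[0]: total_cells}},
        )

    _rasterize_river(river, grid, river_code)

    # -- patch areas and shapes
    raw = rng.lognormal(0.0, 0.5, size=config.n_patches)
    areas = np.maximum(4, np.round(raw / raw.sum() * target_cells).astype(int))

    blocked = np.zeros_like(grid.data, dtype=bool)
    blocked[grid.data == river_code] = True

    patches: dict[str, Polygon] = {}
    type_map = np.zeros_like(grid.data, dtype=np.int16)
    habitat_type_cells: dict[str, dict[str, int]] = {}

    for k, area in enumerate(areas):
        pid = f"p{k:03d}"
        aspect = rng.uniform(0.5, 2.0)
        lshape = rng.random() < config.irregular_fraction
        # the flange is part of the patch's cell budget, not an addition
        main_area = area * (0.75 if lshape else 1.0)
        pw = max(2, int(round(np.sqrt(main_area * aspect))))
        ph = max(2, int(round(main_area / pw)))
        if lshape:
            fw = max(1, int(round(pw * 0.5)))
            fh = max(1, min(ph, int(round(0.25 * area / fw))))
        else:
            fw = fh = 0
        bw, bh = pw + fw, max(ph, fh)
        placed = False
        for _ in range(400):
            c0 = int(rng.integers(1, max(2, ncols - bw - 1)))
            r0 = int(rng.integers(1, max(2, nrows - bh - 1)))
            sl = (slice(max(0, r0 - 2), r0 + bh + 2), slice(max(0, c0 - 2), c0 + bw + 2))
            if blocked[sl].any():
                continue
            cells = [(r0 + dr, c0 + dc) for dr in range(ph) for dc in range(pw)]
            if lshape:
                cells += [
                    (r0 + dr, c0 + pw + dc) for dr in range(fh) for dc in range(fw)
                ]
            rr = np.array([c[0] for c in cells])
            cc = np.array([c[1] for c in cells])
            # habitat types: vertical split into one or two classes
            t1, t2 = rng.choice(habitat_codes, size=2, replace=True)
            split_col = c0 + (pw + fw) // 2 if rng.random() < 0.6 else None
            codes = np.full(rr.shape, t1, dtype=np.int16)
            if split_col is not None:
                codes[cc >= split_col] = t2
            grid.data[rr, cc] = codes
            type_map[rr, cc] = codes
            blocked[rr.min() - 1: rr.max() + 2, cc.min() - 1: cc.max() + 2] = True
            # polygon in world coordinates (y up; row 0 is the top row)
            def cell_box(r, c):
                x0 = c * cs
                y0 = (nrows - 1 - r) * cs
                return box(x0, y0, x0 + cs, y0 + cs)

            main = box(c0 * cs, (nrows - r0 - ph) * cs, (c0 + pw) * cs, (nrows - r0) * cs)
            if lshape:
                flange = box(
                    (c0 + pw) * cs,
                    (nrows - r0 - fh) * cs,
                    (c0 + pw + fw) * cs,
                    (nrows - r0) * cs,
                )
                poly = unary_union([main, flange])
            else:
                poly = main
            patches[pid] = poly
            counts: dict[str, int] = {}
            for name, code in config.class_codes.items():
                ncell = int((codes == code).sum())
                if ncell:
                    counts[name] = ncell
            habitat_type_cells[pid] = counts
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place patch {k + 1}/{config.n_patches}: "
                "target fraction infeasible for this extent"
            )

    realized = float(np.isin(grid.data, habitat_codes).mean())
    if abs(realized - config.habitat_fraction_target) > 0.03:
        raise ValueError(
            f"realized habitat fraction {realized:.3f} misses target "
            f"{config.habitat_fraction_target:.3f} by more than 3 points"
        )

    # -- matrix: blocky crop/urban mosaic on remaining cells
    blockcells = 40
    field_ = rng.random((nrows // blockcells + 1, ncols // blockcells + 1))
    coarse = np.kron(field_, np.ones((blockcells, blockcells)))[:nrows, :ncols]
    empty = grid.data == 0
    crop = coarse < config.matrix_crop_fraction
    grid.data[empty & crop] = config.class_codes["crop_pas"]
    grid.data[empty & ~crop] = config.class_codes["urban"]

    dem = _generate_dem(w, h, rng)
    return grid, patches, river, dem, habitat_type_cells


def _generate_dem(w: float, h: float, rng: np.random.Generator) -> Grid:
    """30 m DEM: gentle plane plus smooth random relief."""
    dem_cs = 30.0
    dn, dm = int(np.ceil(h / dem_cs)), int(np.ceil(w / dem_cs))
    X, Y = np.meshgrid(np.arange(dm), np.arange(dn))
    relief = gaussian_filter(rng.normal(0.0, 1.0, (dn, dm)), 3.0) * 40.0
    return Grid(100.0 + 0.5 * X + 0.3 * Y + relief, dem_cs, 0.0, 0.0)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _simulate_plots(
    habitat_type_cells: dict[str, dict[str, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vegetation-coverage plots: 1–3 per habitat type per patch.

    Coverage vectors are Dirichlet draws whose concentration profile
    depends on the habitat type, so per-type FHD differs systematically.
    """
    rows = []
    k = len(COVERAGE_CLASSES)
    for pid, counts in habitat_type_cells.items():
        for type_name in counts:
            mu = config.class_codes[type_name] % k
            alpha = 0.4 + 2.0 * np.exp(-0.5 * ((np.arange(k) - mu) / 1.5) ** 2)
            for _ in range(int(rng.integers(1, 4))):
                cov = rng.dirichlet(alpha) * 100.0
                rows.append({"patch_id": pid, "habitat_type": type_name, **dict(zip(COVERAGE_CLASSES, cov))})
    return pd.DataFrame(rows)


def compute_patch_metrics(
    landcover: Grid,
    patches: dict[str, Polygon],
    river: LineString,
    dem: Grid,
    config: SimulationConfig,
) -> pd.DataFrame:
    """All raster/vector-derived site covariates for every patch.

    This is the code path shared by the synthetic generator and the
    metrics stage of the pipeline on user-supplied inputs.
    """
    class_map = {k: v for k, v in config.class_codes.items() if k != "river"}
    rows = []
    pids = list(patches)
    for pid in pids:
        poly = patches[pid]
        rec: dict[str, float] = {"patch_id": pid}
        rec.update(patch_geometry(poly))
        if len(patches) > 1:
            rec["np_dist"] = nearest_patch_distance(patches, pid)
        else:
            rec["np_dist"] = np.nan  # no neighbor exists
        rec["dist_river"] = distance_to_feature(poly, river)
        rec["dist_urban"] = distance_to_class(landcover, poly, config.class_codes["urban"])
        rec["dist_crop"] = distance_to_class(landcover, poly, config.class_codes["crop_pas"])
        comp = composition_profile(
            landcover, poly, config.scales, class_map, config.habitat_classes
        )
        for s in config.scales:
            rec[scale_column("habitat", s)] = comp[s]["habitat"]
            rec[scale_column("crop_pas", s)] = comp[s]["crop_pas"]
            rec[scale_column("urban", s)] = comp[s]["urban"]
            rec[scale_column("prox", s)] = proximity_index(
                patches, pid, s, min_distance=config.cell_size_m
            )
        rec["x"] = poly.centroid.x
        rec["y"] = poly.centroid.y
        rec["slope"] = dem_slope(dem, poly)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("patch_id")


def simulate_covariates(
    patches: dict[str, Polygon],
    landcover: Grid,
    dem: Grid,
    config: SimulationConfig,
    river: LineString,
    habitat_type_cells: dict[str, dict[str, int]],
):
    """Site and survey covariate tables for a generated landscape.

    Returns ``(site_covariates, survey_covariates, plots)``; vegetation
    structure comes from simulated coverage plots pooled by habitat type,
    radiation is a synthetic pass-through covariate (decreasing with
    slope), and day of survey is shared within a patch's visit pair.
    """
    rng = np.random.default_rng([config.seed, 2])
    site = compute_patch_metrics(landcover, patches, river, dem, config)

    plots = _simulate_plots(habitat_type_cells, config, rng)
    mean_fhd = pooled_fhd_by_type(plots)
    cell_area = config.cell_size_m ** 2
    veg = {}
    for pid, counts in habitat_type_cells.items():
        areas = {t: n * cell_area for t, n in counts.items()}
        veg[pid] = patch_veg_structure(mean_fhd, areas)
    site["veg_str"] = pd.Series(veg)
    site["radiation"] = 1200.0 - 8.0 * site["slope"] + rng.normal(0.0, 30.0, len(site))

    day0 = rng.integers(1, 61, size=len(site))
    days = np.column_stack(
        [day0 + (0 if j == 0 else rng.integers(0, 2, size=len(site))) for j in range(config.n_surveys)]
    )
    survey = {
        "day": pd.DataFrame(
            days, index=site.index, columns=[f"y{j + 1}" for j in range(config.n_surveys)]
        )
    }
    return site, survey, plots


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / (s if s > 0 else 1.0)


def _resolve_psi_columns(config: SimulationConfig) -> list[str]:
    scale_dep = ("habitat", "crop_pas", "urban", "prox")
    return [
        scale_column(name, config.true_scale_m) if name in scale_dep else name
        for name in config.psi_covariates
    ]


def simulate_detections(
    site_covariates: pd.DataFrame,
    survey_covariates: dict[str, pd.DataFrame],
    config: SimulationConfig,
) -> tuple[DetectionTable, SyntheticTruth]:
    """Draw latent occupancy and detection histories from the truth.

    Occupancy: ``z_i ~ Bernoulli(psi_i)`` with ``logit(psi) = β'x`` on
    z-scored covariates. Detection: ``y_ij ~ Bernoulli(z_i p_ij)`` with
    ``logit(p) = α0 + α_veg veg + α_day day + α_area area`` (z-scored).
    """
    rng = np.random.default_rng([config.seed, 3])
    n = len(site_covariates)
    J = config.n_surveys
    cols = _resolve_psi_columns(config)
    beta = np.asarray(config.true_psi_coefs, dtype=float)
    eta_psi = np.full(n, beta[0])
    for b, colname in zip(beta[1:], cols):
        eta_psi += b * _zscore(site_covariates[colname].to_numpy(dtype=float))
    if not np.isfinite(eta_psi).all():
        raise ValueError("non-finite occupancy linear predictor")
    psi = special.expit(eta_psi)

    alpha = np.asarray(config.true_p_coefs, dtype=float)
    day = survey_covariates["day"].to_numpy(dtype=float)
    eta_p = (
        alpha[0]
        + alpha[1] * _zscore(site_covariates["veg_str"].to_numpy(dtype=float))[:, None]
        + alpha[2] * ((day - day.mean()) / (day.std() if day.std() > 0 else 1.0))
        + alpha[3] * _zscore(site_covariates["area"].to_numpy(dtype=float))[:, None]
    )
    if not np.isfinite(eta_p).all():
        raise ValueError("non-finite detection linear predictor")
    p = special.expit(eta_p)

    z = rng.random(n) < psi
    y = ((rng.random((n, J)) < p) & z[:, None]).astype(int)

    idx = site_covariates.index
    ycols = [f"y{j + 1}" for j in range(J)]
    table = DetectionTable(
        y=pd.DataFrame(y, index=idx, columns=ycols),
        site_covariates=site_covariates,
        survey_covariates={k: v for k, v in survey_covariates.items()},
    )
    truth = SyntheticTruth(
        latent_z=pd.Series(z.astype(int), index=idx, name="z"),
        psi_true=pd.Series(psi, index=idx, name="psi"),
        p_true=pd.DataFrame(p, index=idx, columns=ycols),
    )
    return table, truth


def simulate_dataset(config: SimulationConfig) -> dict:
    """Run the full generator: landscape, covariates, detections, truth."""
    landcover, patches, river, dem, type_cells = generate_landscape(config)
    site, survey, plots = simulate_covariates(
        patches, landcover, dem, config, river, type_cells
    )
    table, truth = simulate_detections(site, survey, config)
    return {
        "config": config,
        "landcover": landcover,
        "patches": patches,
        "river": river,
        "dem": dem,
        "habitat_type_cells": type_cells,
        "plots": plots,
        "table": table,
        "truth": truth,
    }


def write_dataset(dataset: dict, out_dir: str | Path) -> None:
    """Write every artifact of a simulated region as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset["landcover"].write_ascii(out / "landcover.asc")
    dataset["dem"].write_ascii(out / "dem.asc", fmt="%.4f")
    psio.write_patches_geojson(dataset["patches"], out / "patches.geojson")
    psio.write_line_geojson(dataset["river"], out / "river.geojson")
    dataset["plots"].to_csv(out / "plots.csv", index=False)
    dataset["table"].to_csv(out)
    truth = dataset["truth"]
    pd.concat([truth.latent_z, truth.psi_true, truth.p_true], axis=1).to_csv(
        out / "truth.csv", index_label="patch_id"
    )
    psio.write_config_echo(dataset["config"].to_dict(), out / "config_echo.yaml")


# ---------------------------------------------------------------------------
# lightweight ring-based study generator
# ---------------------------------------------------------------------------

def simulate_nested_composition(
    n_sites: int,
    scales=DEFAULT_SCALES,
    mean: float = 0.12,
    ring_sd: float = 0.08,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Habitat proportions at nested buffer scales from per-ring densities.

    Each annulus between consecutive scales gets an independent habitat
    density (truncated normal around ``mean``); the proportion at scale
    ``s_k`` is the area-weighted cumulative mean of the ring densities out
    to ``s_k`` — exactly the geometry of nested buffer measurements, which
    induces the characteristic correlation between adjacent scales.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    scales = sorted(scales)
    edges = np.array([0.0] + list(scales))
    ring_areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    dens = np.clip(
        rng.normal(mean, ring_sd, size=(n_sites, len(scales))), 0.005, 0.995
    )
    cum = np.cumsum(dens * ring_areas, axis=1) / np.cumsum(ring_areas)
    return pd.DataFrame(
        cum, columns=[scale_column("habitat", s) for s in scales],
        index=pd.Index([f"s{i}" for i in range(n_sites)], name="patch_id"),
    )


def simulate_occupancy_study(
    n_sites: int,
    scales=DEFAULT_SCALES,
    true_scale: float = 250.0,
    beta: tuple[float, float] = (0.0, 1.5),
    p_coefs: tuple[float, ...] = (0.85, -0.4, 0.3, 0.2),
    habitat_mean: float = 0.12,
    ring_sd: float = 0.08,
    n_surveys: int = 2,
    seed: int = 0,
) -> tuple[DetectionTable, SyntheticTruth]:
    """Fast covariate-level study: multi-scale composition plus detections.

    The habitat proportion at ``true_scale`` (z-scored) drives occupancy
    with slope ``beta[1]``. Detection covariates (veg_str, day, area) are
    always generated; a length-1 ``p_coefs`` gives constant detection.
    Site coordinates are uniform over a square, for spatial diagnostics.
    """
    if true_scale not in set(scales):
        raise ValueError("true_scale must be a member of the scale set")
    rng = np.random.default_rng(seed)
    comp = simulate_nested_composition(n_sites, scales, habitat_mean, ring_sd, rng)
    site = comp.copy()
    site["veg_str"] = np.abs(rng.normal(1.0, 0.4, n_sites))
    site["area"] = rng.lognormal(9.0, 0.8, n_sites)
    site["x"] = rng.uniform(0, 10_000, n_sites)
    site["y"] = rng.uniform(0, 10_000, n_sites)
    day0 = rng.integers(1, 61, n_sites)
    days = np.column_stack(
        [day0 + (0 if j == 0 else rng.integers(0, 2, n_sites)) for j in range(n_surveys)]
    )
    survey = {
        "day": pd.DataFrame(days, index=site.index, columns=[f"y{j+1}" for j in range(n_surveys)])
    }

    x = _zscore(site[scale_column("habitat", true_scale)].to_numpy())
    psi = special.expit(beta[0] + beta[1] * x)
    alpha = np.asarray(p_coefs, dtype=float)
    if alpha.size == 1:
        eta_p = np.full((n_sites, n_surveys), alpha[0])
    else:
        day = days.astype(float)
        eta_p = (
            alpha[0]
            + alpha[1] * _zscore(site["veg_str"].to_numpy())[:, None]
            + alpha[2] * ((day - day.mean()) / (day.std() or 1.0))
            + alpha[3] * _zscore(site["area"].to_numpy())[:, None]
        )
    p = special.expit(eta_p)
    z = rng.random(n_sites) < psi
    y = ((rng.random((n_sites, n_surveys)) < p) & z[:, None]).astype(int)
    ycols = [f"y{j + 1}" for j in range(n_surveys)]
    table = DetectionTable(
        y=pd.DataFrame(y, index=site.index, columns=ycols),
        site_covariates=site,
        survey_covariates=survey,
    )
    truth = SyntheticTruth(
        latent_z=pd.Series(z.astype(int), index=site.index, name="z"),
        psi_true=pd.Series(psi, index=site.index, name="psi"),
        p_true=pd.DataFrame(p, index=site.index, columns=ycols),
    )
    return table, truth
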
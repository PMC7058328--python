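"""End-to-end regional analysis: orchestrates every stage in order.

Stage order mirrors the analysis design: covariate/metric computation →
detection-structure scan → scale-of-effect profiles → collinearity
filtering and model sets → global models with a spatial-autocorrelation
check (PCNM autocovariate added only when Moran's I is significant) →
parametric-bootstrap goodness of fit on the globals → all-subsets
expansion → ΔAIC retention → classification evaluation of the selected
models. Every stage is a pure function of (inputs, config, seed) and each
artifact is written as CSV or JSON under the output directory.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .data import DetectionTable
from .evaluation import evaluate_model
from .grid import Grid
from .occupancy import detection_model_scan, fit_occupancy
from .selection import (
    ModelSet,
    all_subsets_selection,
    assemble_global_model,
    build_model_sets,
    candidates_to_frame,
    collinearity_filter,
    scale_profile_scan,
    SCALE_DEPENDENT,
)
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .spatial import global_morans_i, pcnm_autocovariate

__all__ = ["RegionRun", "run_region_analysis", "load_inputs"]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class RegionRun:
    """Artifacts and key results of one full regional analysis."""

    out_dir: Path
    config_hash: str
    seed: int
    table: DetectionTable
    detection_scan: pd.DataFrame
    profiles: dict
    model_sets: list
    selected: pd.DataFrame
    evaluations: list[dict]
    diagnostics: dict = field(default_factory=dict)


def load_inputs(config: dict) -> tuple[DetectionTable, dict]:
    """Load user-supplied inputs (non-simulated run) from config paths."""
    paths = config["inputs"]
    table = DetectionTable.from_csv(paths["detections_dir"])
    extras = {}
    if "landcover" in paths:
        extras["landcover"] = Grid.read_ascii(paths["landcover"])
    if "dem" in paths:
        extras["dem"] = Grid.read_ascii(paths["dem"])
    if "patches" in paths:
        extras["patches"] = psio.read_patches_geojson(paths["patches"])
    if "river" in paths:
        extras["river"] = psio.read_line_geojson(paths["river"])
    return table, extras


def _simulation_config(config: dict, seed: int) -> SimulationConfig:
    sim = config["simulation"]
    return SimulationConfig(
        extent_m=tuple(sim.get("extent_m", (4000.0, 4000.0))),
        cell_size_m=sim.get("cell_size_m", 10.0),
        n_patches=sim.get("n_patches", 40),
        habitat_fraction_target=sim.get("habitat_fraction_target", 0.12),
        scales=tuple(config["scales"]),
        psi_covariates=tuple(sim.get("psi_covariates", ("habitat",))),
        true_psi_coefs=tuple(sim.get("true_psi_coefs", (0.0, 1.5))),
        true_scale_m=sim.get("true_scale_m", 250.0),
        true_p_coefs=tuple(sim.get("true_p_coefs", (0.85, -0.4, 0.3, 0.2))),
        n_surveys=sim.get("n_surveys", 2),
        seed=seed,
    )


def run_region_analysis(config: dict, seed: int, out_dir: str | Path) -> RegionRun:
    """Execute the full pipeline and write all artifacts.

    Idempotent given (config, seed): rerunning writes byte-identical JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    psio.write_config_echo(config, out / "config_echo.yaml")

    scales = list(config["scales"])
    p_covs = tuple(config["detection_covariates"])

    # -- stage 1: data ----------------------------------------------------
    if config.get("simulation", {}).get("enabled", False):
        sim_cfg = _simulation_config(config, seed)
        dataset = simulate_dataset(sim_cfg)
        write_dataset(dataset, out / "data")
        table = dataset["table"]
    else:
        table, _ = load_inputs(config)
    site = table.site_covariates
    site.to_csv(out / "patch_metrics.csv", index_label="patch_id")

    # -- stage 2: detection-structure scan --------------------------------
    scan = detection_model_scan(table, p_covariates=p_covs)
    scan.drop(columns=["result"]).to_csv(out / "detection_scan.csv", index=False)

    # -- stage 3: scale-of-effect profiles --------------------------------
    scale_vars = [
        v for v in config["roster"]
        if v in SCALE_DEPENDENT and f"{v}_{int(scales[0])}" in site.columns
    ]
    profiles = {}
    scales_of_effect = {}
    for var in scale_vars:
        prof = scale_profile_scan(table, var, scales, p_covariates=p_covs)
        profiles[var] = prof
        scales_of_effect[var] = prof.scale_of_effect
        prof.table.to_csv(out / f"scale_profile_{var}.csv", index=False)
    _dump_json(scales_of_effect, out / "scales_of_effect.json")

    # -- stage 4: collinearity and model sets ------------------------------
    # strength = univariate RN2 at each variable's own scale of effect
    strengths: dict[str, float] = {}
    null = fit_occupancy(table, (), p_covs).null_results()
    ms_columns = {}
    for var in config["roster"]:
        if var in profiles:
            col = f"{var}_{int(profiles[var].scale_of_effect)}"
        else:
            col = var
        ms_columns[var] = col
        if site[col].nunique() <= 1:
            strengths[var] = 0.0
            continue
        res = fit_occupancy(table, (col,), p_covs)
        strengths[var] = res.nagelkerke_r2(null)
    cov_ms = site[[ms_columns[v] for v in config["roster"]]].copy()
    cov_ms.columns = list(config["roster"])
    retained, corr_pairs, dropped = collinearity_filter(
        cov_ms,
        config["roster"],
        strengths,
        rs_threshold=config["rs_threshold"],
        vif_threshold=config["vif_threshold"],
        flagged_pairs=[tuple(p) for p in config["flagged_pairs"]],
    )
    model_sets = build_model_sets(corr_pairs, retained)
    _dump_json(
        {
            "retained": retained,
            "correlated_pairs": [list(p) for p in corr_pairs],
            "dropped": dropped,
            "strengths": strengths,
            "sets": [{"set_id": s.set_id, "variables": list(s.variables)} for s in model_sets],
        },
        out / "model_sets.json",
    )

    # -- stages 5-8: per scale label: global model, SAC, GOF, dredge -------
    coords = site[["x", "y"]].to_numpy() if {"x", "y"} <= set(site.columns) else None
    all_rows = []
    evaluations = []
    diagnostics: dict[str, dict] = {}
    for label in config["selection_scales"]:
        for mset in model_sets:
            terms = assemble_global_model(
                mset, label, profiles, available_columns=site.columns
            )
            key = f"{label}_{mset.set_id}"
            work_table = table
            g = fit_occupancy(work_table, terms, p_covs)
            diag: dict = {"psi_terms": terms}
            if coords is not None:
                moran = global_morans_i(
                    g.residuals_conditional(), coords,
                    n_permutations=config["moran_permutations"], seed=seed,
                )
                diag["moran_i"] = moran.I
                diag["moran_p"] = moran.p_value
                if moran.p_value < config["sac_alpha"]:
                    auto, _, _, rho = pcnm_autocovariate(coords, g.residuals_conditional())
                    site2 = site.copy()
                    site2["pcnm_auto"] = auto
                    work_table = DetectionTable(
                        y=table.y, site_covariates=site2,
                        survey_covariates=table.survey_covariates,
                    )
                    terms = terms + ["pcnm_auto"]
                    g = fit_occupancy(work_table, terms, p_covs)
                    diag["autocovariate"] = {"spearman_rho": rho}
            gof = g.gof(B=config["gof_bootstrap"], seed=seed)
            diag["gof"] = {"chi2_obs": gof.chi2_obs, "p_value": gof.p_value, "c_hat": gof.c_hat}
            diagnostics[key] = diag

            cands = all_subsets_selection(
                work_table, terms, p_terms=p_covs,
                delta_threshold=config["delta_threshold"],
            )
            frame = candidates_to_frame(cands)
            frame.insert(0, "scale_label", str(label))
            frame.insert(1, "set_id", mset.set_id)
            all_rows.append(frame)
            for cand in cands:
                if not cand.selected:
                    continue
                try:
                    rep = evaluate_model(cand.result)
                    rn2 = cand.result.nagelkerke_r2(null)
                except ValueError:
                    continue
                evaluations.append(
                    {
                        "scale_label": str(label),
                        "set_id": mset.set_id,
                        "psi_terms": list(cand.psi_terms),
                        "p_terms": list(cand.p_terms),
                        "delta_aic": cand.delta_aic,
                        "rn2": rn2,
                        **rep.to_dict(),
                    }
                )

    ranked = pd.concat(all_rows, ignore_index=True)
    ranked.to_csv(out / "ranked_models.csv", index=False)
    selected = ranked[ranked["selected"]].reset_index(drop=True)
    _dump_json(diagnostics, out / "diagnostics.json")
    _dump_json(evaluations, out / "evaluations.json")
    _dump_json(
        {
            "config_hash": cfg_hash,
            "seed": seed,
            "n_sites": table.n_sites,
            "n_surveys": table.n_surveys,
            "n_models_fitted": int(len(ranked)),
            "n_selected": int(len(selected)),
        },
        out / "run_log.json",
    )
    return RegionRun(
        out_dir=out,
        config_hash=cfg_hash,
        seed=seed,
        table=table,
        detection_scan=scan,
        profiles=profiles,
        model_sets=model_sets,
        selected=selected,
        evaluations=evaluations,
        diagnostics=diagnostics,
    )
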
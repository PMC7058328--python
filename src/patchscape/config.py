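"""Default analysis configuration and YAML loading.

All selection thresholds live here with the analysis defaults: Spearman
|r_s| > 0.60 flags collinearity, VIF < 10 is required, models within
ΔAIC < 2 of the best are retained, spatial autocorrelation is acted on at
alpha = 0.05, and Kappa is optimized on the 0.01-step threshold grid.
"""
from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .metrics import DEFAULT_SCALES

__all__ = ["default_config", "load_config"]

_DEFAULTS: dict = {
    "scales": list(DEFAULT_SCALES),
    "rs_threshold": 0.60,
    "vif_threshold": 10.0,
    "delta_threshold": 2.0,
    "sac_alpha": 0.05,
    "moran_permutations": 999,
    "gof_bootstrap": 100,
    "detection_covariates": ["veg_str", "day", "area"],
    # occupancy-variable roster: scale-dependent families are resolved to
    # columns per scale label at assembly time
    "roster": ["habitat", "crop_pas", "np_dist", "dist_river", "area", "veg_str"],
    "flagged_pairs": [],
    # scale labels to dredge; "ms" = multi-scale, numbers = single scales
    "selection_scales": ["ms", 250, 1000],
    "simulation": {
        "enabled": True,
        "extent_m": [4000.0, 4000.0],
        "cell_size_m": 10.0,
        "n_patches": 40,
        "habitat_fraction_target": 0.12,
        "true_scale_m": 250.0,
        "psi_covariates": ["habitat"],
        "true_psi_coefs": [0.0, 1.5],
        "true_p_coefs": [0.85, -0.4, 0.3, 0.2],
        "n_surveys": 2,
    },
    "inputs": {},  # paths for non-simulated runs: landcover, patches, river, dem, detections dir
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, filling unspecified keys from the defaults."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg
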
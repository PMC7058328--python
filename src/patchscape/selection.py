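"""Scale-of-effect scans, collinearity filtering, model sets and
all-subsets selection by ΔAIC.

Workflow: each scale-dependent variable (landscape composition proportions
and the proximity index) gets a univariate occupancy fit at every buffer
scale; the scale with the highest Nagelkerke R² is its scale of effect.
Candidate covariates are then pruned for collinearity (Spearman |r_s| above
a threshold, then iterative VIF), with ecologically important correlated
pairs kept via alternative model sets instead of dropping a member. Global
models (single-scale or multi-scale) are expanded into all subsets, crossed
with all detection-covariate subsets, and models within ΔAIC of the best
are retained.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DetectionTable
from .occupancy import OccupancyResults, fit_occupancy

__all__ = [
    "ScaleProfile",
    "ModelSet",
    "ModelCandidate",
    "DETECTION_COVARIATES",
    "scale_column",
    "scale_profile_scan",
    "spearman_matrix",
    "vif_table",
    "collinearity_filter",
    "build_model_sets",
    "assemble_global_model",
    "all_subsets_selection",
]

#: Detection covariates fixed for all occupancy-structure comparisons.
DETECTION_COVARIATES: tuple[str, ...] = ("veg_str", "day", "area")

#: Variable families measured per buffer scale.
SCALE_DEPENDENT: tuple[str, ...] = ("habitat", "crop_pas", "urban", "densewood", "humid_grass", "prox")


def scale_column(variable: str, scale: float) -> str:
    """Column name of a scale-dependent variable at one buffer scale."""
    return f"{variable}_{int(round(scale))}"


@dataclass
class ScaleProfile:
    """Univariate fit quality of one variable across the buffer scales."""

    variable: str
    table: pd.DataFrame  # columns: scale, rn2, coef, sign, converged
    scale_of_effect: float
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.scale_of_effect not in set(self.table["scale"]):
            raise ValueError("scale_of_effect must be one of the scanned scales")


def scale_profile_scan(
    table: DetectionTable,
    variable: str,
    scales,
    p_covariates: tuple[str, ...] = DETECTION_COVARIATES,
    **fit_kwargs,
) -> ScaleProfile:
    """Find the scale of effect of one variable by univariate occupancy fits.

    One model per scale with the variable (at that scale) as the only
    occupancy covariate and the full detection structure; the scale of
    effect maximizes Nagelkerke R², ties going to the smallest scale. A
    failed fit at one scale marks the profile incomplete but the scan
    continues.
    """
    scales = sorted(scales)
    null = None
    rows = []
    incomplete = False
    for s in scales:
        col = scale_column(variable, s)
        if col not in table.site_covariates.columns:
            raise KeyError(f"missing column {col!r} in site covariates")
        try:
            res = fit_occupancy(
                table, psi_covariates=(col,), p_covariates=p_covariates, **fit_kwargs
            )
            if null is None:
                null = res.null_results()
            rn2 = res.nagelkerke_r2(null)
            coef = float(res.beta_psi[1])
            rows.append(
                {
                    "scale": s,
                    "rn2": rn2,
                    "coef": coef,
                    "sign": "+" if coef >= 0 else "-",
                    "converged": res.converged,
                }
            )
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"scale {s} fit failed for {variable}: {exc}")
            rows.append(
                {"scale": s, "rn2": np.nan, "coef": np.nan, "sign": "", "converged": False}
            )
            incomplete = True
    df = pd.DataFrame(rows)
    if df["rn2"].notna().any():
        # idxmax on the ascending-sorted scan resolves ties to the smallest scale
        best = float(df.loc[df["rn2"].idxmax(), "scale"])
    else:
        raise RuntimeError(f"all scale fits failed for {variable}")
    return ScaleProfile(variable=variable, table=df, scale_of_effect=best, incomplete=incomplete)


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

def spearman_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of the covariate columns."""
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("need at least two covariates")
    rho = stats.spearmanr(covariates.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    return pd.DataFrame(rho, index=cols, columns=cols)


def vif_table(covariates: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each column (with an intercept)."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    vals = [variance_inflation_factor(X, i + 1) for i in range(covariates.shape[1])]
    return pd.Series(vals, index=covariates.columns)


def collinearity_filter(
    covariates: pd.DataFrame,
    candidate_vars,
    univariate_strengths: dict[str, float],
    rs_threshold: float = 0.60,
    vif_threshold: float = 10.0,
    flagged_pairs=(),
):
    """Prune correlated covariates, keeping the stronger of each pair.

    Pairs with Spearman ``|r_s|`` above the threshold lose their weaker
    member (lower univariate Nagelkerke R²), unless the pair is flagged as
    ecologically important — flagged correlated pairs are returned so both
    members can be explored through alternative model sets. Remaining
    variables then undergo iterative VIF pruning (drop the highest VIF
    until all are below the threshold). Constant columns are excluded with
    a warning.

    Returns ``(retained, correlated_pairs, dropped)`` where ``dropped``
    maps variable -> reason.
    """
    candidate_vars = list(candidate_vars)
    if len(candidate_vars) < 2:
        raise ValueError("need at least two candidate variables")
    dropped: dict[str, str] = {}
    usable = []
    for v in candidate_vars:
        if covariates[v].nunique() <= 1:
            warnings.warn(f"covariate {v!r} is constant; excluded")
            dropped[v] = "constant"
        else:
            usable.append(v)
    if len(usable) < 2:
        return usable, [], dropped
    flagged = {frozenset(p) for p in flagged_pairs}
    rho = spearman_matrix(covariates[usable])
    pairs = [
        (abs(rho.loc[a, b]), a, b)
        for i, a in enumerate(usable)
        for b in usable[i + 1:]
        if abs(rho.loc[a, b]) > rs_threshold
    ]
    pairs.sort(reverse=True)
    retained = list(usable)
    correlated_pairs: list[tuple[str, str]] = []
    for r, a, b in pairs:
        if a not in retained or b not in retained:
            continue
        if frozenset((a, b)) in flagged:
            correlated_pairs.append((a, b))
            continue
        weaker = min((a, b), key=lambda v: univariate_strengths.get(v, -np.inf))
        retained.remove(weaker)
        dropped[weaker] = f"|r_s|={r:.2f} with {(b if weaker == a else a)}"
    # iterative VIF pruning over variables not held in flagged pairs
    in_pairs = {v for p in correlated_pairs for v in p}
    while True:
        free = [v for v in retained if v not in in_pairs]
        if len(free) < 2:
            break
        vifs = vif_table(covariates[free])
        if vifs.max() < vif_threshold:
            break
        worst = vifs.idxmax()
        retained.remove(worst)
        dropped[worst] = f"vif={vifs.max():.1f}"
    return retained, correlated_pairs, dropped


# ---------------------------------------------------------------------------
# model sets and global models
# ---------------------------------------------------------------------------

@dataclass
class ModelSet:
    """One roster of occupancy variables (one member per correlated pair)."""

    set_id: str
    variables: tuple[str, ...]
    scale_label: object = None  # a scale in meters or "ms"


def build_model_sets(correlated_pairs, roster) -> list[ModelSet]:
    """One model set per combination of correlated-pair members.

    With two flagged pairs this yields four sets; with one pair, two; with
    none, a single global set containing the whole roster.
    """
    roster = list(roster)
    if not roster:
        raise ValueError("empty variable roster")
    seen: set[str] = set()
    for a, b in correlated_pairs:
        for v in (a, b):
            if v in seen:
                raise ValueError(f"variable {v!r} appears in two correlated pairs")
            seen.add(v)
    base = [v for v in roster if v not in seen]
    sets = []
    choices = list(itertools.product(*correlated_pairs)) if correlated_pairs else [()]
    for i, choice in enumerate(choices, start=1):
        members = tuple(base) + tuple(choice)
        label = "+".join(choice) if choice else "global"
        sets.append(ModelSet(set_id=f"set{i}_{label}", variables=members))
    return sets


def assemble_global_model(
    model_set: ModelSet,
    scale_label,
    profiles: dict[str, ScaleProfile] | None = None,
    available_columns=None,
    scale_dependent=SCALE_DEPENDENT,
) -> list[str]:
    """Resolve a model set's roster into concrete psi-term column names.

    Single-scale (``scale_label`` = buffer distance): every scale-dependent
    variable is taken at that scale. Multi-scale (``scale_label="ms"``):
    each scale-dependent variable is taken at its own scale of effect from
    ``profiles``. Scale-independent variables pass through unchanged.
    """
    terms = []
    for var in model_set.variables:
        if var in scale_dependent:
            if scale_label == "ms":
                if profiles is None or var not in profiles:
                    raise KeyError(f"no scale profile available for {var!r}")
                terms.append(scale_column(var, profiles[var].scale_of_effect))
            else:
                terms.append(scale_column(var, float(scale_label)))
        else:
            terms.append(var)
    if available_columns is not None:
        missing = [t for t in terms if t not in set(available_columns)]
        if missing:
            raise KeyError(f"missing variable-at-scale columns: {', '.join(missing)}")
    return terms


# ---------------------------------------------------------------------------
# all-subsets (dredge-style) selection
# ---------------------------------------------------------------------------

@dataclass
class ModelCandidate:
    """One fitted subset model in an all-subsets expansion."""

    psi_terms: tuple[str, ...]
    p_terms: tuple[str, ...]
    result: OccupancyResults
    delta_aic: float = np.nan
    selected: bool = False


def all_subsets_selection(
    table: DetectionTable,
    psi_terms,
    p_terms: tuple[str, ...] = DETECTION_COVARIATES,
    delta_threshold: float = 2.0,
    use_aicc: bool = False,
    guard: int = 50_000,
    n_starts: int = 2,
    **fit_kwargs,
) -> list[ModelCandidate]:
    """Fit every psi-subset × detection-subset and retain ΔAIC < threshold.

    ``2^len(psi_terms) * 2^len(p_terms)`` models are fitted (guarded
    against combinatorial blow-up). ΔAIC is relative to the best candidate;
    AIC is the default criterion with AICc available by flag.
    """
    psi_terms = list(psi_terms)
    n_models = 2 ** len(psi_terms) * 2 ** len(p_terms)
    if n_models > guard:
        raise ValueError(
            f"{n_models} candidate models exceed the guard ({guard}); reduce the roster"
        )
    candidates: list[ModelCandidate] = []
    for r in range(len(psi_terms) + 1):
        for psi_sub in itertools.combinations(psi_terms, r):
            for q in range(len(p_terms) + 1):
                for p_sub in itertools.combinations(p_terms, q):
                    res = fit_occupancy(
                        table,
                        psi_covariates=psi_sub,
                        p_covariates=p_sub,
                        n_starts=n_starts,
                        **fit_kwargs,
                    )
                    candidates.append(
                        ModelCandidate(psi_terms=psi_sub, p_terms=p_sub, result=res)
                    )
    ics = np.array(
        [c.result.aicc if use_aicc else c.result.aic for c in candidates]
    )
    best = ics.min()
    for c, ic in zip(candidates, ics):
        c.delta_aic = float(ic - best)
        c.selected = c.delta_aic < delta_threshold
    candidates.sort(key=lambda c: c.delta_aic)
    return candidates


def candidates_to_frame(candidates: list[ModelCandidate]) -> pd.DataFrame:
    """Tidy ranked table of an all-subsets run (one row per candidate)."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "psi_terms": " + ".join(c.psi_terms) if c.psi_terms else "1",
                "p_terms": " + ".join(c.p_terms) if c.p_terms else "1",
                "k": c.result.k,
                "loglik": c.result.llf,
                "aic": c.result.aic,
                "aicc": c.result.aicc,
                "delta_aic": c.delta_aic,
                "selected": c.selected,
                "converged": c.result.converged,
            }
        )
    return pd.DataFrame(rows)
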
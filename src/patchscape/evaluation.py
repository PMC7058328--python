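"""Classification-based evaluation of selected occupancy models.

Observed "presence" for the confusion matrix is naive occupancy (detected
in at least one survey); predicted presence is the unconditional occupancy
probability thresholded at a cutoff. Reported indices: percent correctly
classified (PCC), rank-based AUC, Cohen's Kappa at threshold 0.5 and at the
Kappa-maximizing threshold over the 0.00–1.00 grid in steps of 0.01.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EvaluationReport",
    "classification_indices",
    "auc",
    "optimize_kappa_threshold",
    "evaluate_model",
    "prediction_curve",
]

#: The 101 evaluation thresholds (0.00, 0.01, ..., 1.00).
THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def _confusion(observed: np.ndarray, predicted: np.ndarray) -> dict[str, int]:
    tp = int(((observed == 1) & (predicted == 1)).sum())
    tn = int(((observed == 0) & (predicted == 0)).sum())
    fp = int(((observed == 0) & (predicted == 1)).sum())
    fn = int(((observed == 1) & (predicted == 0)).sum())
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def _kappa_from_confusion(c: dict[str, int]) -> float:
    n = c["tp"] + c["fp"] + c["fn"] + c["tn"]
    po = (c["tp"] + c["tn"]) / n
    pe = (
        (c["tp"] + c["fp"]) * (c["tp"] + c["fn"])
        + (c["fn"] + c["tn"]) * (c["fp"] + c["tn"])
    ) / n**2
    if pe >= 1.0:
        if po == 1.0:
            return 1.0
        raise ValueError("degenerate marginals (p_e = 1) with imperfect agreement")
    return (po - pe) / (1.0 - pe)


def classification_indices(observed, predicted_psi, threshold: float) -> dict:
    """Confusion matrix, PCC and Kappa at one probability threshold.

    A site is predicted present iff its occupancy probability is at least
    the threshold (``>=`` at the boundary).
    """
    obs = np.asarray(observed, dtype=int)
    psi = np.asarray(predicted_psi, dtype=float)
    if obs.shape != psi.shape:
        raise ValueError("observed and predicted must have equal length")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    pred = (psi >= threshold).astype(int)
    conf = _confusion(obs, pred)
    n = obs.size
    pcc = (conf["tp"] + conf["tn"]) / n
    return {"confusion": conf, "pcc": pcc, "kappa": _kappa_from_confusion(conf), "threshold": threshold}


def auc(observed, predicted_psi) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve.

    Equals the probability that a randomly chosen presence site outranks a
    randomly chosen absence site, with ties counted half.
    """
    obs = np.asarray(observed, dtype=int)
    psi = np.asarray(predicted_psi, dtype=float)
    n1 = int(obs.sum())
    n0 = obs.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both presence and absence sites")
    ranks = rankdata(psi)
    u = ranks[obs == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def optimize_kappa_threshold(observed, predicted_psi):
    """Maximize Kappa over the 101-point threshold grid.

    Returns ``(kappa_opt, threshold, grid)`` where ``grid`` is a DataFrame
    of Kappa at every threshold. Ties go to the smallest threshold.
    """
    kappas = []
    for t in THRESHOLD_GRID:
        try:
            kappas.append(classification_indices(observed, predicted_psi, t)["kappa"])
        except ValueError:
            kappas.append(-np.inf)
    kappas = np.asarray(kappas)
    j = int(np.argmax(kappas))  # argmax takes the first (smallest) threshold on ties
    grid = pd.DataFrame({"threshold": THRESHOLD_GRID, "kappa": kappas})
    return float(kappas[j]), float(THRESHOLD_GRID[j]), grid


@dataclass
class EvaluationReport:
    """PCC, AUC and the two Kappa statistics for one selected model."""

    pcc: float
    auc: float
    kappa_05: float
    kappa_opt: float
    opt_threshold: float
    n_sites: int
    confusion_05: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "pcc": self.pcc,
            "auc": self.auc,
            "kappa_05": self.kappa_05,
            "kappa_opt": self.kappa_opt,
            "opt_threshold": self.opt_threshold,
            "n_sites": self.n_sites,
            "confusion_05": self.confusion_05,
        }


def evaluate_model(results, observed=None) -> EvaluationReport:
    """Evaluate a fitted occupancy model against naive presence/absence."""
    if observed is None:
        observed = results.model.detected.astype(int)
    psi = results.psi_hat
    at_half = classification_indices(observed, psi, 0.5)
    kappa_opt, thr, _ = optimize_kappa_threshold(observed, psi)
    return EvaluationReport(
        pcc=at_half["pcc"],
        auc=auc(observed, psi),
        kappa_05=at_half["kappa"],
        kappa_opt=kappa_opt,
        opt_threshold=thr,
        n_sites=len(np.asarray(observed)),
        confusion_05=at_half["confusion"],
    )


def prediction_curve(results, variable: str, grid=None, n_points: int = 100) -> pd.DataFrame:
    """Occupancy probability against one covariate, others held at their means.

    The grid is in the covariate's original (unstandardized) units; by
    default it spans the training mean ± 2 SD.
    """
    model = results.model
    name = f"psi_{variable}"
    if name not in model.psi_names:
        raise KeyError(f"variable {variable!r} not in the occupancy part of the fit")
    mu, sd = model.scaler.get(variable, (0.0, 1.0))
    if grid is None:
        grid = np.linspace(mu - 2 * sd, mu + 2 * sd, n_points)
    grid = np.asarray(grid, dtype=float)
    df = pd.DataFrame({variable: grid})
    # every other covariate at its training mean
    for other in model.psi_names[1:]:
        col = other[len("psi_"):]
        if col != variable:
            df[col] = model.scaler.get(col, (0.0, 1.0))[0]
    psi = results.predict_psi(df)
    return pd.DataFrame({variable: grid, "psi": psi})
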
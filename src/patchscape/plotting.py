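"""Plot helpers for scale profiles and prediction curves."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import prediction_curve

__all__ = ["plot_scale_profile", "plot_prediction_curve"]


def plot_scale_profile(profile, ax=None):
    """Univariate fit quality (Nagelkerke R²) across buffer scales."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.table["scale"], profile.table["rn2"], marker="o")
    ax.axvline(profile.scale_of_effect, ls="--", color="grey")
    ax.set_xlabel("buffer scale (m)")
    ax.set_ylabel("Nagelkerke $R^2$")
    ax.set_title(profile.variable)
    return ax


def plot_prediction_curve(results, variable, grid=None, ax=None):
    """Predicted occupancy probability against one covariate."""
    if ax is None:
        _, ax = plt.subplots()
    curve = prediction_curve(results, variable, grid=grid)
    ax.plot(curve[variable], curve["psi"])
    ax.set_xlabel(variable)
    ax.set_ylabel(r"occupancy probability $\hat\psi$")
    ax.set_ylim(-0.02, 1.02)
    return ax
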
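"""Detection-history container shared by the modelling and selection stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DetectionTable"]


@dataclass
class DetectionTable:
    """Binary site × survey detection histories plus covariates.

    Parameters
    ----------
    y : DataFrame, shape (n_sites, n_surveys)
        Binary detection histories, indexed by patch id.
    site_covariates : DataFrame
        One row per site, aligned with ``y``; values in original units.
    survey_covariates : dict of str -> DataFrame
        Survey-varying covariates (e.g. day of survey); each frame is
        site × survey, aligned with ``y``.
    """

    y: pd.DataFrame
    site_covariates: pd.DataFrame = None
    survey_covariates: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = pd.DataFrame(self.y)
        vals = self.y.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("detection histories must be binary (0/1), no missing surveys")
        if self.site_covariates is None:
            self.site_covariates = pd.DataFrame(index=self.y.index)
        if not self.site_covariates.index.equals(self.y.index):
            raise ValueError("site_covariates index must match y index")
        if not np.isfinite(self.site_covariates.select_dtypes("number").to_numpy()).all():
            raise ValueError("site covariates contain non-finite values")
        for name, frame in self.survey_covariates.items():
            if frame.shape != self.y.shape:
                raise ValueError(f"survey covariate {name!r} must be site × survey")
            if not np.isfinite(frame.to_numpy(dtype=float)).all():
                raise ValueError(f"survey covariate {name!r} contains non-finite values")

    # -- basic summaries --------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.y.shape[1]

    def detected(self) -> np.ndarray:
        """Boolean per site: detected in at least one survey."""
        return self.y.to_numpy().sum(axis=1) > 0

    def naive_occupancy(self) -> float:
        """Fraction of sites with at least one detection (uncorrected for p)."""
        return float(self.detected().mean())

    def detection_summary(self) -> dict[int, int]:
        """Histogram: number of surveys with a detection -> number of sites."""
        counts = self.y.to_numpy().sum(axis=1)
        return {int(k): int((counts == k).sum()) for k in range(self.n_surveys + 1)}

    def history_counts(self) -> dict[str, int]:
        """Counts of each observed history string (e.g. '10')."""
        out: dict[str, int] = {}
        for row in self.y.to_numpy():
            key = "".join(str(int(v)) for v in row)
            out[key] = out.get(key, 0) + 1
        return dict(sorted(out.items()))

    @classmethod
    def from_history_counts(cls, counts: dict[str, int]) -> "DetectionTable":
        """Build a covariate-free table from history-string counts.

        Useful for reconstructing a detection table from a published
        summary such as "17 sites detected twice, 7 once, 18 never".
        """
        rows = []
        for hist, n in counts.items():
            rows.extend([[int(c) for c in hist]] * n)
        y = pd.DataFrame(rows, columns=[f"y{j + 1}" for j in range(len(next(iter(counts))))])
        y.index = pd.Index([f"s{i}" for i in range(len(y))], name="patch_id")
        return cls(y=y)

    # -- I/O --------------------------------------------------------------
    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.y.to_csv(directory / "detections.csv", index_label="patch_id")
        self.site_covariates.to_csv(directory / "site_covariates.csv", index_label="patch_id")
        for name, frame in self.survey_covariates.items():
            frame.to_csv(directory / f"survey_{name}.csv", index_label="patch_id")

    @classmethod
    def from_csv(cls, directory: str | Path) -> "DetectionTable":
        directory = Path(directory)
        y = pd.read_csv(directory / "detections.csv", index_col="patch_id")
        site = pd.read_csv(directory / "site_covariates.csv", index_col="patch_id")
        survey: dict[str, pd.DataFrame] = {}
        for f in sorted(directory.glob("survey_*.csv")):
            name = f.stem[len("survey_"):]
            survey[name] = pd.read_csv(f, index_col="patch_id")
        return cls(y=y, site_covariates=site, survey_covariates=survey)
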
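"""Single-season occupancy model with imperfect detection.

The model treats true occupancy ``z_i ~ Bernoulli(psi_i)`` as latent and the
binary survey outcomes as ``y_ij | z_i ~ Bernoulli(z_i * p_ij)``. Both the
occupancy probability ``psi`` and the per-survey detection probability ``p``
are logistic functions of linear predictors. The marginal likelihood of a
site's history integrates over the latent state: a site with at least one
detection must be occupied, while an all-zero history mixes "occupied but
never detected" with "not occupied":

    L_i = psi_i * prod_j p_ij^y_ij (1-p_ij)^(1-y_ij)        if any y_ij = 1
    L_i = psi_i * prod_j (1-p_ij) + (1 - psi_i)             otherwise

Estimation is by maximum likelihood with analytic gradients, multiple
jittered quasi-Newton starts, and a finite-difference Hessian for Wald
standard errors. Covariates are z-scored at model construction so reported
coefficients are on the standardized scale.

API shape follows the statsmodels convention: build an
:class:`OccupancyModel` (usually via :meth:`OccupancyModel.from_table`),
call :meth:`~OccupancyModel.fit`, and work with the returned
:class:`OccupancyResults` (``params``, ``bse``, ``aic``, ``summary()``,
``predict_psi``, ``simulate``, ``gof`` ...).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .data import DetectionTable

__all__ = [
    "OccupancyModel",
    "OccupancyResults",
    "GofResult",
    "fit_occupancy",
    "nagelkerke_r2",
    "detection_model_scan",
    "gof_parametric_bootstrap",
]

_CLIP = 1e-10
_BOUNDARY_LOGIT = 15.0


def _expit_clipped(eta: np.ndarray) -> np.ndarray:
    return np.clip(special.expit(eta), _CLIP, 1.0 - _CLIP)


class OccupancyModel:
    """Single-season occupancy model for one detection table.

    Parameters
    ----------
    y : ndarray, shape (n, J)
        Binary detection histories.
    X_psi : ndarray, shape (n, k_psi)
        Occupancy design matrix (first column should be the intercept).
    X_p : ndarray, shape (n, J, k_p), optional
        Detection design matrix; omit when ``p_fixed`` is given.
    p_fixed : float, optional
        Fix the detection probability at a constant (no detection
        parameters are estimated). ``p_fixed=1`` reduces the MLE of psi to
        naive occupancy.
    """

    def __init__(
        self,
        y,
        X_psi,
        X_p=None,
        psi_names=None,
        p_names=None,
        p_fixed: float | None = None,
        scaler: dict | None = None,
        index=None,
    ):
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be (n_sites, n_surveys)")
        self.n, self.J = self.y.shape
        self.X_psi = np.asarray(X_psi, dtype=float)
        self.p_fixed = p_fixed
        if p_fixed is None:
            if X_p is None:
                X_p = np.ones((self.n, self.J, 1))
            self.X_p = np.asarray(X_p, dtype=float)
            self.k_p = self.X_p.shape[2]
        else:
            if not 0.0 <= p_fixed <= 1.0:
                raise ValueError("p_fixed must be a probability")
            self.X_p = None
            self.k_p = 0
        self.k_psi = self.X_psi.shape[1]
        self.psi_names = list(psi_names) if psi_names is not None else [
            "psi_const" if i == 0 else f"psi_x{i}" for i in range(self.k_psi)
        ]
        self.p_names = list(p_names) if p_names is not None else [
            "p_const" if i == 0 else f"p_x{i}" for i in range(self.k_p)
        ]
        self.scaler = scaler or {}
        self.index = index
        if not np.isfinite(self.X_psi).all() or (
            self.X_p is not None and not np.isfinite(self.X_p).all()
        ):
            raise ValueError("design matrices contain non-finite values")
        self.detected = self.y.sum(axis=1) > 0

    # -- construction -----------------------------------------------------
    @classmethod
    def from_table(
        cls,
        table: DetectionTable,
        psi_covariates=(),
        p_covariates=(),
        standardize: bool = True,
        p_fixed: float | None = None,
    ) -> "OccupancyModel":
        """Build a model from a :class:`DetectionTable`.

        Site covariates used for detection are broadcast across surveys;
        names present in ``table.survey_covariates`` vary by survey.
        Covariates are z-scored over sites (survey covariates over all
        site × survey values); the scaling is stored for prediction.
        """
        n, J = table.n_sites, table.n_surveys
        scaler: dict[str, tuple[float, float]] = {}

        def z(col: str, values: np.ndarray) -> np.ndarray:
            if not standardize:
                scaler[col] = (0.0, 1.0)
                return values
            m, s = float(np.mean(values)), float(np.std(values))
            if s == 0:
                raise ValueError(f"covariate {col!r} is constant; cannot standardize")
            scaler[col] = (m, s)
            return (values - m) / s

        X_psi = np.ones((n, 1 + len(psi_covariates)))
        for i, name in enumerate(psi_covariates):
            X_psi[:, 1 + i] = z(name, table.site_covariates[name].to_numpy(dtype=float))

        X_p = None
        if p_fixed is None:
            X_p = np.ones((n, J, 1 + len(p_covariates)))
            for i, name in enumerate(p_covariates):
                if name in table.survey_covariates:
                    vals = table.survey_covariates[name].to_numpy(dtype=float)
                    X_p[:, :, 1 + i] = z(name, vals)
                else:
                    vals = z(name, table.site_covariates[name].to_numpy(dtype=float))
                    X_p[:, :, 1 + i] = vals[:, None]

        return cls(
            y=table.y.to_numpy(),
            X_psi=X_psi,
            X_p=X_p,
            psi_names=["psi_(Intercept)"] + [f"psi_{c}" for c in psi_covariates],
            p_names=(
                [] if p_fixed is not None else ["p_(Intercept)"] + [f"p_{c}" for c in p_covariates]
            ),
            p_fixed=p_fixed,
            scaler=scaler,
            index=table.y.index,
        )

    # -- likelihood -------------------------------------------------------
    def _split(self, params):
        beta = params[: self.k_psi]
        alpha = params[self.k_psi:]
        return beta, alpha

    def _probs(self, params):
        beta, alpha = self._split(params)
        psi = _expit_clipped(self.X_psi @ beta)
        if self.p_fixed is not None:
            p = np.full((self.n, self.J), np.clip(self.p_fixed, _CLIP, 1 - _CLIP))
        else:
            p = _expit_clipped(self.X_p @ alpha)
        return psi, p

    def loglike_obs(self, params) -> np.ndarray:
        """Per-site log-likelihood contributions."""
        psi, p = self._probs(params)
        logf = self.y * np.log(p) + (1 - self.y) * np.log1p(-p)
        cond = logf.sum(axis=1)
        det = self.detected
        out = np.empty(self.n)
        out[det] = np.log(psi[det]) + cond[det]
        q = np.exp(cond[~det])  # prob of all-zero history given occupied
        out[~det] = np.log(psi[~det] * q + (1 - psi[~det]))
        return out

    def nloglike(self, params) -> float:
        params = np.asarray(params, dtype=float)
        if not np.isfinite(params).all():
            raise ValueError("non-finite parameter vector")
        return float(-self.loglike_obs(params).sum())

    def score(self, params) -> np.ndarray:
        """Analytic gradient of the negative log-likelihood."""
        params = np.asarray(params, dtype=float)
        psi, p = self._probs(params)
        det = self.detected
        q = np.exp((np.log1p(-p)).sum(axis=1))  # prod_j (1 - p_ij)
        L0 = psi * q + (1 - psi)  # likelihood of all-zero sites

        # d logL / d eta_psi
        g_psi_eta = np.where(det, 1 - psi, psi * (1 - psi) * (q - 1) / L0)
        grad_beta = self.X_psi.T @ g_psi_eta

        if self.p_fixed is not None:
            return -grad_beta
        # d logL / d eta_p(ij)
        g_p_eta = np.where(
            det[:, None],
            self.y - p,
            (-psi * q / L0)[:, None] * p,
        )
        grad_alpha = np.einsum("ij,ijk->k", g_p_eta, self.X_p)
        return -np.concatenate([grad_beta, grad_alpha])

    # -- fitting ----------------------------------------------------------
    def _start_values(self) -> np.ndarray:
        naive = np.clip(self.detected.mean(), 0.05, 0.95)
        start = np.zeros(self.k_psi + self.k_p)
        start[0] = special.logit(naive)
        if self.k_p:
            det_rate = np.clip(self.y[self.detected].mean() if self.detected.any() else 0.5, 0.05, 0.95)
            start[self.k_psi] = special.logit(det_rate)
        return start

    def fit(
        self,
        start=None,
        n_starts: int = 5,
        seed: int = 0,
        gtol: float = 1e-6,
        maxiter: int = 500,
    ) -> "OccupancyResults":
        """Maximize the likelihood from several jittered starts.

        The best of ``n_starts`` quasi-Newton (BFGS) runs is returned;
        ``converged`` reflects the gradient norm at the optimum, and fits
        with any coefficient beyond ±15 on the logit scale are flagged as
        boundary estimates.
        """
        k = self.k_psi + self.k_p
        if self.n <= k:
            raise ValueError(f"need more sites ({self.n}) than parameters ({k})")
        rng = np.random.default_rng(seed)
        base = np.asarray(start, dtype=float) if start is not None else self._start_values()
        best = None
        errors = []
        for s in range(max(1, n_starts)):
            x0 = base if s == 0 else base + rng.normal(0, 0.5, size=k)
            try:
                res = optimize.minimize(
                    self.nloglike,
                    x0,
                    jac=self.score,
                    method="BFGS",
                    options={"gtol": gtol, "maxiter": maxiter},
                )
            except (ValueError, FloatingPointError) as exc:  # pragma: no cover
                errors.append(str(exc))
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                "all optimizer starts failed: " + "; ".join(errors[:3])
            )
        grad = self.score(best.x)
        converged = bool(np.max(np.abs(grad)) < 1e-3)
        at_boundary = bool(np.max(np.abs(best.x)) > _BOUNDARY_LOGIT)
        return OccupancyResults(
            model=self,
            params=best.x,
            llf=-float(best.fun),
            converged=converged,
            at_boundary=at_boundary,
            optimizer_message=str(best.message),
        )

    # -- simulation -------------------------------------------------------
    def simulate(self, params, rng) -> np.ndarray:
        """Draw one detection-history matrix from the model at ``params``."""
        psi, p = self._probs(np.asarray(params, dtype=float))
        z = rng.random(self.n) < psi
        return ((rng.random((self.n, self.J)) < p) & z[:, None]).astype(int)


@dataclass
class OccupancyResults:
    """Fit results: estimates, uncertainty, diagnostics and predictions."""

    model: OccupancyModel
    params: np.ndarray
    llf: float
    converged: bool
    at_boundary: bool
    optimizer_message: str = ""
    _cache: dict = field(default_factory=dict, repr=False)

    # -- parameter views --------------------------------------------------
    @property
    def beta_psi(self) -> np.ndarray:
        return self.params[: self.model.k_psi]

    @property
    def beta_p(self) -> np.ndarray:
        return self.params[self.model.k_psi:]

    @property
    def param_names(self) -> list[str]:
        return self.model.psi_names + self.model.p_names

    @property
    def nobs(self) -> int:
        return self.model.n

    @property
    def k(self) -> int:
        return len(self.params)

    # -- information criteria ---------------------------------------------
    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k
        if n - k - 1 <= 0:
            return float("inf")
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    # -- fitted probabilities ---------------------------------------------
    @property
    def psi_hat(self) -> np.ndarray:
        return self.model._probs(self.params)[0]

    @property
    def p_hat(self) -> np.ndarray:
        return self.model._probs(self.params)[1]

    # -- uncertainty ------------------------------------------------------
    def cov_params(self) -> np.ndarray:
        """Inverse observed-information covariance (finite-diff Hessian)."""
        if "cov" not in self._cache:
            k = self.k
            h = 1e-5 * np.maximum(1.0, np.abs(self.params))
            H = np.empty((k, k))
            for j in range(k):
                e = np.zeros(k)
                e[j] = h[j]
                H[:, j] = (self.model.score(self.params + e) - self.model.score(self.params - e)) / (
                    2 * h[j]
                )
            H = (H + H.T) / 2.0
            self._cache["cov"] = np.linalg.pinv(H)
        return self._cache["cov"]

    @property
    def bse(self) -> np.ndarray:
        var = np.diag(self.cov_params()).copy()
        var[var < 0] = np.nan
        return np.sqrt(var)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        zq = special.ndtri(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - zq * se, self.params + zq * se])

    # -- derived statistics -----------------------------------------------
    def null_results(self) -> "OccupancyResults":
        """Intercept-only psi and p fit on the same data (the RN² null)."""
        if "null" not in self._cache:
            m = self.model
            if m.k_psi == 1 and m.k_p <= 1 and m.p_fixed is None:
                self._cache["null"] = self
            else:
                null = OccupancyModel(
                    y=m.y,
                    X_psi=np.ones((m.n, 1)),
                    X_p=np.ones((m.n, m.J, 1)),
                    psi_names=["psi_(Intercept)"],
                    p_names=["p_(Intercept)"],
                )
                self._cache["null"] = null.fit()
        return self._cache["null"]

    def nagelkerke_r2(self, null: "OccupancyResults | None" = None) -> float:
        nul = null if null is not None else self.null_results()
        return nagelkerke_r2(self.llf, nul.llf, self.nobs)

    # -- prediction & simulation ------------------------------------------
    def predict_psi(self, site_covariates: pd.DataFrame | None = None) -> np.ndarray:
        """Occupancy probability for new sites (covariates in original units).

        Covariates are standardized with the training means/SDs stored on
        the model. With no argument, returns the fitted ``psi_hat``.
        """
        if site_covariates is None:
            return self.psi_hat
        m = self.model
        X = np.ones((len(site_covariates), m.k_psi))
        for j, name in enumerate(m.psi_names[1:], start=1):
            col = name[len("psi_"):]
            if col not in site_covariates.columns:
                raise KeyError(f"unknown covariate {col!r} for prediction")
            mu, sd = m.scaler.get(col, (0.0, 1.0))
            X[:, j] = (site_covariates[col].to_numpy(dtype=float) - mu) / sd
        return _expit_clipped(X @ self.beta_psi)

    def simulate(self, rng_or_seed=0) -> np.ndarray:
        rng = (
            rng_or_seed
            if isinstance(rng_or_seed, np.random.Generator)
            else np.random.default_rng(rng_or_seed)
        )
        return self.model.simulate(self.params, rng)

    def gof(self, B: int = 200, seed: int = 0) -> "GofResult":
        return gof_parametric_bootstrap(self, B=B, seed=seed)

    def residuals_conditional(self) -> np.ndarray:
        """Conditional-occupancy residuals ``z*_i − psi_hat_i``.

        ``z*_i`` is 1 for sites with a detection; otherwise the posterior
        probability of occupancy given an all-zero history.
        """
        psi, p = self.model._probs(self.params)
        q = np.exp(np.log1p(-p).sum(axis=1))
        zstar = np.where(self.model.detected, 1.0, psi * q / (psi * q + 1 - psi))
        return zstar - psi

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Single-season occupancy model (logit links)",
            f"  sites: {self.nobs}   surveys: {self.model.J}   parameters: {self.k}",
            f"  logLik: {self.llf:.4f}   AIC: {self.aic:.3f}   AICc: {self.aicc:.3f}",
            f"  converged: {self.converged}   boundary: {self.at_boundary}",
            "",
            f"  {'term':<24}{'estimate':>12}{'std.err':>12}{'z':>9}",
        ]
        se = self.bse
        for name, est, s in zip(self.param_names, self.params, se):
            zval = est / s if s and np.isfinite(s) and s > 0 else np.nan
            lines.append(f"  {name:<24}{est:>12.4f}{s:>12.4f}{zval:>9.2f}")
        try:
            lines.append("")
            lines.append(f"  Nagelkerke R2: {self.nagelkerke_r2():.4f}")
        except Exception:
            pass
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def fit_occupancy(
    table: DetectionTable,
    psi_covariates=(),
    p_covariates=(),
    standardize: bool = True,
    p_fixed: float | None = None,
    **fit_kwargs,
) -> OccupancyResults:
    """Convenience wrapper: build the model from a table and fit it."""
    model = OccupancyModel.from_table(
        table, psi_covariates, p_covariates, standardize=standardize, p_fixed=p_fixed
    )
    return model.fit(**fit_kwargs)


def nagelkerke_r2(llf: float, llf_null: float, n: int) -> float:
    """Nagelkerke's rescaled R² from full and null log-likelihoods.

    ``R² = [1 − exp(2(ll0 − ll1)/n)] / [1 − exp(2 ll0 / n)]``, bounded to
    [0, 1]. Raises if the full model fits worse than the null beyond
    numerical tolerance (an optimizer failure).
    """
    if llf < llf_null - 1e-6:
        raise ValueError(
            f"full-model logLik {llf:.6f} below null {llf_null:.6f}: fit failure"
        )
    cox_snell = 1.0 - np.exp(2.0 * (llf_null - llf) / n)
    max_r2 = 1.0 - np.exp(2.0 * llf_null / n)
    if max_r2 <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_r2, 0.0, 1.0))


def detection_model_scan(
    table: DetectionTable,
    p_covariates: tuple[str, ...] = ("veg_str", "day", "area"),
    criterion: str = "aicc",
    **fit_kwargs,
) -> pd.DataFrame:
    """Rank the 2^k detection structures with constant occupancy.

    Fits every subset of ``p_covariates`` (including the constant-``p``
    model) with intercept-only psi and ranks by AICc (or AIC). Returns a
    DataFrame with one row per candidate, its information criterion and the
    difference to the best model; fitted results are in column ``result``.
    """
    rows = []
    for r in range(len(p_covariates) + 1):
        for combo in itertools.combinations(p_covariates, r):
            res = fit_occupancy(table, psi_covariates=(), p_covariates=combo, **fit_kwargs)
            ic = res.aicc if criterion == "aicc" else res.aic
            rows.append(
                {
                    "p_terms": " + ".join(combo) if combo else "1",
                    "k": res.k,
                    "loglik": res.llf,
                    criterion: ic,
                    "converged": res.converged,
                    "result": res,
                }
            )
    df = pd.DataFrame(rows).sort_values(criterion, kind="mergesort").reset_index(drop=True)
    df[f"delta_{criterion}"] = df[criterion] - df[criterion].iloc[0]
    return df


@dataclass
class GofResult:
    """Parametric-bootstrap goodness of fit for an occupancy model."""

    chi2_obs: float
    p_value: float
    c_hat: float
    B: int
    n_failed: int
    chi2_boot: np.ndarray

    def __repr__(self) -> str:  # compact: the bootstrap vector is long
        return (
            f"GofResult(chi2_obs={self.chi2_obs:.4f}, p_value={self.p_value:.4f}, "
            f"c_hat={self.c_hat:.4f}, B={self.B}, n_failed={self.n_failed})"
        )


def _history_chi2(y: np.ndarray, psi: np.ndarray, p: np.ndarray) -> float:
    """Observed-vs-expected chi-square over the 2^J history cohorts."""
    n, J = y.shape
    chi2 = 0.0
    for h in itertools.product((0, 1), repeat=J):
        harr = np.array(h, dtype=float)
        logf = harr * np.log(p) + (1 - harr) * np.log1p(-p)
        pr = psi * np.exp(logf.sum(axis=1))
        if not any(h):
            pr = pr + (1 - psi)
        E = pr.sum()
        O = float((y == harr).all(axis=1).sum())
        chi2 += (O - E) ** 2 / E
    return float(chi2)


def gof_parametric_bootstrap(
    results: OccupancyResults, B: int = 200, seed: int = 0
) -> GofResult:
    """MacKenzie–Bailey parametric-bootstrap goodness of fit.

    The observed chi-square compares history-cohort counts with their
    expectations under the fitted model. ``B`` datasets are simulated from
    the fit, each refitted (warm-started at the fitted parameters), and the
    bootstrap chi-squares give the p-value (share of replicates at least as
    extreme) and the overdispersion ratio ``c_hat = chi2_obs / mean(chi2_b)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    model = results.model
    psi, p = model._probs(results.params)
    chi2_obs = _history_chi2(model.y, psi, p)
    rng = np.random.default_rng(seed)
    boot = []
    n_failed = 0
    for _ in range(B):
        yb = model.simulate(results.params, rng)
        mb = OccupancyModel(
            y=yb,
            X_psi=model.X_psi,
            X_p=model.X_p,
            psi_names=model.psi_names,
            p_names=model.p_names,
            p_fixed=model.p_fixed,
        )
        try:
            rb = mb.fit(start=results.params, n_starts=1)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        psib, pb = mb._probs(rb.params)
        boot.append(_history_chi2(yb, psib, pb))
    if not boot:
        raise RuntimeError("all bootstrap refits failed")
    boot_arr = np.asarray(boot)
    return GofResult(
        chi2_obs=chi2_obs,
        p_value=float((boot_arr >= chi2_obs).mean()),
        c_hat=float(chi2_obs / boot_arr.mean()),
        B=B,
        n_failed=n_failed,
        chi2_boot=boot_arr,
    )
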
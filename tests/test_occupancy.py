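"""Occupancy-model likelihood, fitting and diagnostics against oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy import special

from patchscape.data import DetectionTable
from patchscape.occupancy import (
    OccupancyModel,
    _history_chi2,
    detection_model_scan,
    fit_occupancy,
    gof_parametric_bootstrap,
    nagelkerke_r2,
)
from patchscape.simulate import simulate_occupancy_study


def enumeration_nll(y, X_psi, X_p, params):
    """Independent oracle: sum over the latent state per site."""
    k1 = X_psi.shape[1]
    psi = special.expit(X_psi @ params[:k1])
    p = special.expit(np.einsum("ijk,k->ij", X_p, params[k1:]))
    total = 0.0
    for i in range(y.shape[0]):
        L = 0.0
        for z in (0, 1):
            pr_y = 1.0
            for j in range(y.shape[1]):
                pdet = z * p[i, j]
                pr_y *= pdet if y[i, j] else (1 - pdet)
            L += (psi[i] if z else 1 - psi[i]) * pr_y
        total -= np.log(L)
    return total


def random_dataset(rng, n=None, J=None):
    n = n or int(rng.integers(2, 9))
    J = J or int(rng.integers(2, 4))
    X_psi = np.column_stack([np.ones(n), rng.normal(size=n)])
    X_p = np.dstack([np.ones((n, J)), rng.normal(size=(n, J))])
    params = rng.uniform(-2, 2, size=4)
    psi = special.expit(X_psi @ params[:2])
    p = special.expit(np.einsum("ijk,k->ij", X_p, params[2:]))
    z = rng.random(n) < psi
    y = ((rng.random((n, J)) < p) & z[:, None]).astype(int)
    return y, X_psi, X_p, params


class TestLikelihood:
    def test_matches_latent_state_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y, X_psi, X_p, params = random_dataset(rng)
            model = OccupancyModel(y, X_psi, X_p)
            assert model.nloglike(params) == pytest.approx(
                enumeration_nll(y, X_psi, X_p, params), abs=1e-12
            )

    def test_closed_form_single_history(self):
        # psi -> 1, p = 0.5, J = 2, history "10": L = 0.25
        y = np.array([[1, 0]])
        model = OccupancyModel(y, np.ones((1, 1)), p_fixed=0.5)
        nll = model.nloglike(np.array([25.0]))  # psi = expit(25) ≈ 1
        assert np.exp(-nll) == pytest.approx(0.25, abs=1e-9)

    def test_detected_site_has_no_mixture_term(self):
        # for a detected site, dL/dpsi is (1-psi): exactly the pure-psi term
        y = np.array([[1, 1]])
        model = OccupancyModel(y, np.ones((1, 1)), np.ones((1, 2, 1)))
        params = np.array([0.3, 0.1])
        ll = model.loglike_obs(params)[0]
        psi = special.expit(0.3)
        p = special.expit(0.1)
        assert ll == pytest.approx(np.log(psi * p * p), abs=1e-12)

    def test_score_matches_numeric_gradient(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y, X_psi, X_p, params = random_dataset(rng, n=15)
            model = OccupancyModel(y, X_psi, X_p)
            got = model.score(params)
            h = 1e-6
            for k in range(len(params)):
                e = np.zeros_like(params)
                e[k] = h
                num = (model.nloglike(params + e) - model.nloglike(params - e)) / (2 * h)
                assert got[k] == pytest.approx(num, abs=1e-5)

    def test_nonfinite_params_raise(self):
        model = OccupancyModel(np.array([[0, 1]]), np.ones((1, 1)), np.ones((1, 2, 1)))
        with pytest.raises(ValueError):
            model.nloglike(np.array([np.nan, 0.0]))


class TestFit:
    def test_constant_model_matches_grid_oracle(self, core_table):
        res = fit_occupancy(core_table)
        grid = np.arange(1e-4, 1, 1e-4)
        P, Q = np.meshgrid(grid, grid, indexing="ij")
        ll = (
            17 * np.log(P * Q * Q)
            + 7 * np.log(P * Q * (1 - Q))
            + 18 * np.log(P * (1 - Q) ** 2 + 1 - P)
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert res.psi_hat[0] == pytest.approx(grid[i], abs=1e-3)
        assert res.p_hat[0, 0] == pytest.approx(grid[j], abs=1e-3)

    def test_all_ones_histories_flagged_at_boundary(self):
        table = DetectionTable.from_history_counts({"11": 12})
        res = fit_occupancy(table)
        assert res.at_boundary
        assert res.psi_hat[0] > 0.999
        assert res.p_hat[0, 0] > 0.999

    def test_p_fixed_one_recovers_naive_occupancy(self, core_table):
        res = fit_occupancy(core_table, p_fixed=1.0)
        assert res.psi_hat[0] == pytest.approx(core_table.naive_occupancy(), abs=1e-6)

    def test_simulation_recovery_within_three_se(self):
        table, _ = simulate_occupancy_study(
            500, beta=(special.logit(0.6), 0.0), p_coefs=(special.logit(0.7),), seed=21
        )
        res = fit_occupancy(table)
        se = res.bse
        assert abs(res.params[0] - special.logit(0.6)) < 3 * se[0]
        assert abs(res.params[1] - special.logit(0.7)) < 3 * se[1]

    def test_aic_identity_and_aicc_ordering(self):
        table, _ = simulate_occupancy_study(60, seed=3)
        for covs in [(), ("habitat_250",)]:
            res = fit_occupancy(table, psi_covariates=covs, p_covariates=("veg_str",))
            assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k)
            assert res.aicc >= res.aic

    def test_needs_more_sites_than_params(self):
        table = DetectionTable.from_history_counts({"11": 1, "00": 1})
        with pytest.raises(ValueError, match="sites"):
            fit_occupancy(table)

    def test_deterministic_given_seed(self):
        table, _ = simulate_occupancy_study(80, seed=9)
        r1 = fit_occupancy(table, psi_covariates=("habitat_250",), seed=4)
        r2 = fit_occupancy(table, psi_covariates=("habitat_250",), seed=4)
        assert np.array_equal(r1.params, r2.params)


class TestNagelkerke:
    def test_null_fit_gives_zero(self, core_table):
        res = fit_occupancy(core_table)
        assert res.nagelkerke_r2(res) == 0.0

    def test_formula_oracle(self):
        # hand-computed from two log-likelihoods
        ll1, ll0, n = -40.0, -55.0, 42
        want = (1 - np.exp(2 * (ll0 - ll1) / n)) / (1 - np.exp(2 * ll0 / n))
        assert nagelkerke_r2(ll1, ll0, n) == pytest.approx(want)

    def test_perfect_fit_limit_approaches_one(self):
        assert nagelkerke_r2(-1e-9, -30.0, 40) == pytest.approx(1.0, abs=1e-6)

    def test_worse_than_null_raises(self):
        with pytest.raises(ValueError, match="fit failure"):
            nagelkerke_r2(-60.0, -55.0, 42)

    def test_bounded_zero_one_on_fits(self):
        table, _ = simulate_occupancy_study(100, seed=13)
        res = fit_occupancy(table, psi_covariates=("habitat_250",), p_covariates=("day",))
        assert 0.0 <= res.nagelkerke_r2() <= 1.0


class TestDetectionScan:
    def test_always_eight_candidates_with_best_delta_zero(self):
        table, _ = simulate_occupancy_study(60, seed=17)
        scan = detection_model_scan(table, n_starts=2)
        assert len(scan) == 8
        assert scan["delta_aicc"].iloc[0] == 0.0
        assert set(scan["p_terms"]) == {
            "1", "veg_str", "day", "area", "veg_str + day", "veg_str + area",
            "day + area", "veg_str + day + area",
        }

    def test_strong_vegetation_effect_recovered(self):
        hits = 0
        reps = 20
        for r in range(reps):
            table, _ = simulate_occupancy_study(
                300, beta=(0.0, 1.0), p_coefs=(0.5, -2.0, 0.3, 0.2), seed=500 + r
            )
            scan = detection_model_scan(table, n_starts=2)
            hits += "veg_str" in scan["p_terms"].iloc[0]
        assert hits >= 0.9 * reps


class TestGof:
    def test_expected_history_counts_sum_to_n(self):
        table, _ = simulate_occupancy_study(50, seed=23)
        res = fit_occupancy(table, psi_covariates=("habitat_250",))
        psi, p = res.model._probs(res.params)
        total = 0.0
        import itertools

        for h in itertools.product((0, 1), repeat=2):
            harr = np.array(h, dtype=float)
            pr = psi * np.prod(p**harr * (1 - p) ** (1 - harr), axis=1)
            if not any(h):
                pr = pr + 1 - psi
            total += pr.sum()
        assert total == pytest.approx(res.nobs, abs=1e-8)

    def test_chi2_hand_calculation(self):
        # psi = p = 0.5 fixed, histories 11/10/01/00 once each:
        # E_11 = E_10 = E_01 = 0.5, E_00 = 2.5 -> chi2 = 3*0.5 + 1.5²/2.5
        y = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        psi = np.full(4, 0.5)
        p = np.full((4, 2), 0.5)
        assert _history_chi2(y, psi, p) == pytest.approx(3 * 0.5 + 1.5**2 / 2.5)

    def test_bootstrap_p_value_and_c_hat_finite(self):
        table, _ = simulate_occupancy_study(60, seed=31)
        res = fit_occupancy(table, psi_covariates=("habitat_250",))
        g = res.gof(B=50, seed=1)
        assert 0.0 <= g.p_value <= 1.0
        assert g.c_hat > 0
        assert g.B == 50

    def test_b_zero_raises(self):
        table, _ = simulate_occupancy_study(30, seed=37)
        res = fit_occupancy(table)
        with pytest.raises(ValueError):
            gof_parametric_bootstrap(res, B=0)


class TestPredict:
    def test_at_training_means_gives_intercept_logistic(self):
        table, _ = simulate_occupancy_study(80, seed=41)
        res = fit_occupancy(table, psi_covariates=("habitat_250", "veg_str"))
        mu_h = table.site_covariates["habitat_250"].mean()
        mu_v = table.site_covariates["veg_str"].mean()
        new = pd.DataFrame({"habitat_250": [mu_h], "veg_str": [mu_v]})
        assert res.predict_psi(new)[0] == pytest.approx(
            special.expit(res.beta_psi[0]), abs=1e-12
        )

    def test_hand_linear_predictor(self):
        # linear predictor 0.5 -> logistic = 0.6225 (construct directly)
        y = np.array([[0, 1]] * 6)
        model = OccupancyModel(y, np.ones((6, 1)), np.ones((6, 2, 1)))
        from patchscape.occupancy import OccupancyResults

        res = OccupancyResults(model=model, params=np.array([0.5, 0.0]),
                               llf=0.0, converged=True, at_boundary=False)
        assert res.psi_hat[0] == pytest.approx(0.62245933, abs=1e-6)

    def test_unknown_covariate_raises(self):
        table, _ = simulate_occupancy_study(40, seed=43)
        res = fit_occupancy(table, psi_covariates=("habitat_250",))
        with pytest.raises(KeyError, match="unknown"):
            res.predict_psi(pd.DataFrame({"nope": [1.0]}))

    def test_monotone_in_single_covariate(self):
        table, _ = simulate_occupancy_study(150, beta=(0.0, 1.5), seed=47)
        res = fit_occupancy(table, psi_covariates=("habitat_250",))
        grid = np.linspace(0.0, 0.4, 30)
        psi = res.predict_psi(pd.DataFrame({"habitat_250": grid}))
        diffs = np.diff(psi)
        assert (diffs >= 0).all() or (diffs <= 0).all()

    def test_residuals_conditional_bounds(self):
        table, _ = simulate_occupancy_study(60, seed=53)
        res = fit_occupancy(table, psi_covariates=("habitat_250",))
        r = res.residuals_conditional()
        assert ((r > -1) & (r < 1)).all()

    def test_summary_contains_terms(self):
        table, _ = simulate_occupancy_study(60, seed=59)
        res = fit_occupancy(table, psi_covariates=("habitat_250",), p_covariates=("day",))
        text = res.summary()
        assert "psi_habitat_250" in text and "p_day" in text and "AIC" in text
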
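"""Scale-of-effect scans, collinearity filtering and all-subsets selection."""
import itertools

import numpy as np
import pandas as pd
import pytest

from patchscape.data import DetectionTable
from patchscape.occupancy import fit_occupancy
from patchscape.selection import (
    ModelSet,
    all_subsets_selection,
    assemble_global_model,
    build_model_sets,
    candidates_to_frame,
    collinearity_filter,
    scale_column,
    scale_profile_scan,
    spearman_matrix,
    vif_table,
)
from patchscape.simulate import simulate_occupancy_study

SCALES = (50, 150, 250, 500, 750, 1000, 1500, 2000, 2500, 3000)


class TestScaleProfile:
    def test_exact_tie_selects_smallest_scale(self):
        table, _ = simulate_occupancy_study(80, scales=SCALES, seed=61)
        site = table.site_covariates.copy()
        # make every scale column identical: all fits tie exactly
        for s in SCALES:
            site[scale_column("habitat", s)] = site[scale_column("habitat", 250)]
        tied = DetectionTable(table.y, site, table.survey_covariates)
        prof = scale_profile_scan(tied, "habitat", SCALES)
        assert prof.scale_of_effect == 50

    def test_scale_of_effect_member_and_rows(self):
        table, _ = simulate_occupancy_study(100, scales=SCALES, seed=67)
        prof = scale_profile_scan(table, "habitat", SCALES)
        assert len(prof.table) == len(SCALES)
        assert prof.scale_of_effect in SCALES

    def test_permutation_invariant_to_scale_order(self):
        table, _ = simulate_occupancy_study(100, scales=SCALES, seed=71)
        a = scale_profile_scan(table, "habitat", SCALES)
        b = scale_profile_scan(table, "habitat", tuple(reversed(SCALES)))
        assert a.scale_of_effect == b.scale_of_effect
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_failed_scale_marks_incomplete_but_continues(self):
        table, _ = simulate_occupancy_study(80, scales=SCALES, seed=73)
        site = table.site_covariates.copy()
        site[scale_column("habitat", 50)] = 0.0  # constant: standardization fails
        broken = DetectionTable(table.y, site, table.survey_covariates)
        with pytest.warns(UserWarning, match="scale 50"):
            prof = scale_profile_scan(broken, "habitat", SCALES)
        assert prof.incomplete
        assert np.isnan(prof.table.loc[prof.table["scale"] == 50, "rn2"]).all()
        assert prof.scale_of_effect in SCALES

    def test_missing_column_raises(self):
        table, _ = simulate_occupancy_study(50, scales=SCALES, seed=79)
        with pytest.raises(KeyError, match="prox_50"):
            scale_profile_scan(table, "prox", SCALES)


class TestCollinearity:
    @staticmethod
    def _strengths(names):
        return {n: 1.0 - 0.1 * i for i, n in enumerate(names)}

    def test_duplicated_column_drops_weaker(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]  # |r_s| = 1
        df["c"] = rng.normal(size=50)
        retained, pairs, dropped = collinearity_filter(
            df, ["a", "b", "c"], {"a": 0.5, "b": 0.2, "c": 0.4}
        )
        assert "b" in dropped and "a" in retained and "c" in retained
        assert pairs == []

    def test_independent_covariates_all_kept(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(500, 5)), columns=list("abcde"))
        retained, pairs, dropped = collinearity_filter(
            df, list("abcde"), self._strengths("abcde")
        )
        assert retained == list("abcde")
        assert not dropped
        assert vif_table(df).max() < 10

    def test_spearman_matches_rank_formula(self):
        # hand 6-row table, no ties: r_s = 1 - 6 Σ d² / (n(n²-1))
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5])
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        d2 = ((rx - ry) ** 2).sum()
        want = 1 - 6 * d2 / (6 * 35)
        got = spearman_matrix(pd.DataFrame({"x": x, "y": y})).loc["x", "y"]
        assert got == pytest.approx(want)

    def test_vif_orthogonal_columns_is_one(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame(
            {
                "s1": np.sin(2 * np.pi * t / n),
                "s2": np.sin(4 * np.pi * t / n),
                "s3": np.cos(2 * np.pi * t / n),
            }
        )
        assert np.allclose(vif_table(df).to_numpy(), 1.0, atol=1e-6)

    def test_flagged_pair_kept_for_model_sets(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        df = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.1, 200), "c": rng.normal(size=200)})
        retained, pairs, dropped = collinearity_filter(
            df, ["a", "b", "c"], {"a": 0.5, "b": 0.4, "c": 0.3},
            flagged_pairs=[("a", "b")],
        )
        assert ("a", "b") in pairs or ("b", "a") in pairs
        assert set(retained) == {"a", "b", "c"}

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=30), "k": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            retained, _, dropped = collinearity_filter(df, ["a", "k"], {"a": 0.5})
        assert dropped["k"] == "constant"

    def test_vif_pruning_drops_redundant(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=300)
        x2 = rng.normal(size=300)
        df = pd.DataFrame({
            "x1": x1, "x2": x2,
            # near-linear combination but Spearman with each parent < 0.6
            "x3": 0.55 * x1 + 0.55 * x2 + rng.normal(0, 0.05, 300),
        })
        rho = spearman_matrix(df).abs()
        assert rho.loc["x3", "x1"] < 0.9  # not caught by the pair rule alone
        retained, _, dropped = collinearity_filter(
            df, ["x1", "x2", "x3"], {"x1": 0.5, "x2": 0.4, "x3": 0.6},
            rs_threshold=0.95, vif_threshold=10.0,
        )
        assert len(retained) < 3 and any("vif" in v for v in dropped.values())


class TestModelSets:
    def test_two_pairs_give_four_sets(self):
        sets = build_model_sets(
            [("np_dist", "prox"), ("crop_pas", "urban")],
            ["np_dist", "prox", "crop_pas", "urban", "dist_river"],
        )
        assert len(sets) == 4
        rosters = {frozenset(s.variables) for s in sets}
        assert frozenset({"dist_river", "np_dist", "crop_pas"}) in rosters
        assert frozenset({"dist_river", "prox", "urban"}) in rosters

    def test_one_pair_gives_two_sets(self):
        sets = build_model_sets([("habitat", "urban")], ["habitat", "urban", "area"])
        assert len(sets) == 2

    def test_no_pairs_gives_single_global_set(self):
        sets = build_model_sets([], ["a", "b"])
        assert len(sets) == 1
        assert sets[0].variables == ("a", "b")

    def test_empty_roster_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_model_sets([], [])

    def test_variable_in_two_pairs_raises(self):
        with pytest.raises(ValueError, match="two correlated pairs"):
            build_model_sets([("a", "b"), ("b", "c")], ["a", "b", "c"])


class TestAssembleGlobal:
    PROFILES = None  # profiles stub built per test

    def _profiles(self):
        from patchscape.selection import ScaleProfile

        def prof(var, soe):
            df = pd.DataFrame({"scale": list(SCALES), "rn2": 0.1})
            return ScaleProfile(variable=var, table=df, scale_of_effect=soe)

        return {"habitat": prof("habitat", 2000), "urban": prof("urban", 500)}

    def test_single_scale_suffixes(self):
        ms = ModelSet("s", ("habitat", "urban", "np_dist"))
        terms = assemble_global_model(ms, 150)
        assert terms == ["habitat_150", "urban_150", "np_dist"]

    def test_multi_scale_uses_scale_of_effect(self):
        ms = ModelSet("s", ("habitat", "urban"))
        terms = assemble_global_model(ms, "ms", self._profiles())
        assert terms == ["habitat_2000", "urban_500"]

    def test_missing_profile_raises(self):
        ms = ModelSet("s", ("crop_pas",))
        with pytest.raises(KeyError, match="crop_pas"):
            assemble_global_model(ms, "ms", self._profiles())

    def test_missing_column_named(self):
        ms = ModelSet("s", ("habitat",))
        with pytest.raises(KeyError, match="habitat_150"):
            assemble_global_model(ms, 150, available_columns=["habitat_250"])

    def test_np_dist_passes_through_without_prox(self):
        ms = ModelSet("s", ("np_dist", "dist_river"))
        assert assemble_global_model(ms, 500) == ["np_dist", "dist_river"]


class TestAllSubsets:
    def test_counts_and_best_selected(self):
        table, _ = simulate_occupancy_study(70, seed=83)
        cands = all_subsets_selection(
            table, ["habitat_250"], p_terms=("veg_str",), n_starts=1
        )
        assert len(cands) == 2 ** 1 * 2 ** 1  # 2^k psi subsets × 2 p subsets
        assert cands[0].delta_aic == 0.0 and cands[0].selected
        assert all(c.delta_aic >= 0 for c in cands)

    def test_two_psi_terms_fit_exactly_2k_times_8(self):
        table, _ = simulate_occupancy_study(70, seed=89)
        cands = all_subsets_selection(table, ["habitat_250", "area"], n_starts=1)
        assert len(cands) == 4 * 8

    def test_null_subset_matches_null_fit_aic(self):
        table, _ = simulate_occupancy_study(70, seed=97)
        cands = all_subsets_selection(
            table, ["habitat_250"], p_terms=("veg_str",), n_starts=1
        )
        null_cand = next(c for c in cands if not c.psi_terms and not c.p_terms)
        direct = fit_occupancy(table)
        assert null_cand.result.aic == pytest.approx(direct.aic, abs=1e-6)

    def test_guard_raises_before_fitting(self):
        table, _ = simulate_occupancy_study(30, seed=101)
        with pytest.raises(ValueError, match="guard"):
            all_subsets_selection(table, [f"v{i}" for i in range(20)], guard=100)

    def test_candidates_frame_columns(self):
        table, _ = simulate_occupancy_study(60, seed=103)
        frame = candidates_to_frame(
            all_subsets_selection(table, ["habitat_250"], p_terms=(), n_starts=1)
        )
        assert {"psi_terms", "aic", "delta_aic", "selected"} <= set(frame.columns)

    def test_true_driver_in_every_selected_model(self):
        hits, reps = 0, 15
        for r in range(reps):
            table, _ = simulate_occupancy_study(300, beta=(0.0, 2.0), seed=700 + r)
            site = table.site_covariates.copy()
            rng = np.random.default_rng(r)
            site["noise"] = rng.normal(size=len(site))
            t2 = DetectionTable(table.y, site, table.survey_covariates)
            cands = all_subsets_selection(
                t2, ["habitat_250", "noise"], p_terms=("veg_str",), n_starts=1
            )
            hits += all("habitat_250" in c.psi_terms for c in cands if c.selected)
        assert hits >= 0.9 * reps
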
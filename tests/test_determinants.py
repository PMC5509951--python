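"""Dichotomization, univariate screening, model fitting and selection."""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from oracle import naive_ols
import mhealth_ei as m
from mhealth_ei.determinants import (DEFAULT_VARIABLES, VariableSpec,
                                     dichotomize, fit_full_model,
                                     fit_reduced_model, screened_variables,
                                     summarize_by_category, univariate_screen)
from mhealth_ei.synthetic_cohort import SimulationConfig, simulate_cohort


def analysis_frame(dataset, results):
    return dichotomize(dataset.participants).merge(
        results[["participant_id", "ei"]], on="participant_id")


class TestDichotomize:
    def test_raw_labels_map_to_analysis_groups(self):
        raw = pd.DataFrame({
            "education": ["trade certificate", "higher degree", "diploma"],
            "income": ["Aus $2000 or more per week", "Aus $1000-$1499 per week",
                       "Aus $120-$299 per week"],
            "employment": ["casual paid work", "unemployed or laid off",
                           "full or part-time studying"],
            "marital": ["married", "never married", "widowed"],
        })
        out = dichotomize(raw)
        assert out["education"].tolist() == ["no_university", "degree",
                                             "no_university"]
        assert out["income"].tolist() == ["higher_income", "average",
                                          "below_average"]
        assert out["employment"].tolist() == ["working_or_studying",
                                              "not_in_labor_force",
                                              "working_or_studying"]
        assert out["marital"].tolist() == ["relationship", "single", "single"]

    def test_already_dichotomized_is_identity(self):
        raw = pd.DataFrame({"education": ["degree", "no_university"],
                            "parity": ["primiparous", "multiparous"]})
        pd.testing.assert_frame_equal(dichotomize(raw), raw)

    def test_unmapped_label_flagged_as_missing(self):
        out = dichotomize(pd.DataFrame({"education": ["apprenticeship"]}))
        assert out["education"].isna().all()

    def test_unlisted_country_collapses_to_other(self):
        out = dichotomize(pd.DataFrame({"country_of_birth":
                                        ["Ireland", "Australia"]}))
        assert out["country_of_birth"].tolist() == ["other", "australia"]


class TestUnivariateScreen:
    def _frame(self, ei, **cols):
        return pd.DataFrame({"ei": ei, **cols})

    def test_identical_groups_give_null_result(self):
        frame = self._frame([10.0] * 20,
                            parity=["primiparous", "multiparous"] * 10)
        res = univariate_screen(frame, [VariableSpec("parity", "categorical")])
        assert res[0].statistic == 0.0
        assert res[0].p_value == pytest.approx(1.0)

    def test_perfect_monotone_association_gives_spearman_one(self):
        rng = np.random.default_rng(0)
        age = np.sort(rng.uniform(20, 40, 60))
        ei = np.exp(age / 4.0)  # monotone and wildly non-normal
        frame = self._frame(ei, mother_age_years=age)
        res = univariate_screen(frame,
                                [VariableSpec("mother_age_years", "continuous")])
        assert res[0].test_used == "spearman"
        assert res[0].statistic == pytest.approx(1.0)

    def test_single_level_variable_skipped(self):
        frame = self._frame([1.0, 2.0, 3.0], device=["ios"] * 3)
        res = univariate_screen(frame, [VariableSpec("device", "categorical")])
        assert res[0].skipped and not res[0].passes_screen

    def test_three_level_variable_uses_oneway_family(self):
        rng = np.random.default_rng(1)
        frame = self._frame(rng.normal(30, 5, 90),
                            recruitment=["practitioner", "web_based",
                                         "family_or_friends"] * 30)
        res = univariate_screen(frame,
                                [VariableSpec("recruitment", "categorical")])
        assert res[0].test_used in ("anova", "kruskal_wallis")
        assert np.isfinite(res[0].p_value)

    def test_both_branches_always_reported(self):
        rng = np.random.default_rng(2)
        frame = self._frame(rng.normal(30, 5, 40),
                            parity=rng.choice(["primiparous", "multiparous"], 40))
        res = univariate_screen(frame, [VariableSpec("parity", "categorical")])
        assert np.isfinite(res[0].parametric_p)
        assert np.isfinite(res[0].nonparametric_p)

    def test_large_injected_system_effect_always_screens_in(self):
        """A strong system-type effect passes P<=.25 in all 100 replicates."""
        hits = 0
        for seed in range(1, 101):
            ds, _ = simulate_cohort(SimulationConfig(seed=seed))
            res = m.combine_frame(m.score_cohort(ds))
            screen = univariate_screen(analysis_frame(ds, res))
            hits += "system" in screened_variables(screen)
        assert hits == 100


class TestLinearModels:
    def _exact_frame(self):
        parity = ["primiparous", "multiparous"] * 15
        ei = [10.0 + 5.0 * (p == "primiparous") for p in parity]
        return pd.DataFrame({"ei": ei, "parity": parity})

    def test_exact_linear_recovery(self):
        model = fit_full_model(self._exact_frame(), ["parity"])
        assert model.coefficient("parity", "primiparous") == pytest.approx(5.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_reference_level_coded_as_baseline(self):
        model = fit_full_model(self._exact_frame(), ["parity"])
        assert model.coefficient("parity", "multiparous") == 0.0
        table = model.to_frame()
        ref = table[table["is_reference"]]
        assert ref["B"].tolist() == [1.00]

    def test_constant_outcome_gives_zero_slopes_and_r2(self):
        frame = pd.DataFrame({"ei": [30.0] * 20,
                              "parity": ["primiparous", "multiparous"] * 10})
        model = fit_full_model(frame, ["parity"])
        assert model.coefficient("parity", "primiparous") == 0.0
        assert model.r_squared == 0.0

    def test_collinear_design_is_fatal_with_diagnostic(self):
        frame = pd.DataFrame({
            "ei": [1.0, 2.0, 3.0, 4.0],
            "parity": ["primiparous", "multiparous"] * 2,
            "education": ["degree", "no_university"] * 2})  # aliased
        with pytest.raises(ValueError, match="rank deficient"):
            fit_full_model(frame, ["parity", "education"])

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        n = 40
        frame = pd.DataFrame({
            "mother_age_years": rng.uniform(20, 40, n),
            "parity": rng.choice(["primiparous", "multiparous"], n),
        })
        frame["ei"] = (20 + 0.3 * frame["mother_age_years"]
                       + 4 * (frame["parity"] == "primiparous") + rng.normal(0, 2, n))
        model = fit_full_model(frame, ["mother_age_years", "parity"])
        X = np.column_stack([np.ones(n), frame["mother_age_years"],
                             (frame["parity"] == "primiparous").astype(float)])
        beta = naive_ols(X, frame["ei"])
        assert model.coefficient("mother_age_years") == pytest.approx(
            beta[1], abs=1e-8)
        assert model.coefficient("parity", "primiparous") == pytest.approx(
            beta[2], abs=1e-8)

    def test_backward_elimination_drops_exactly_the_null_variable(self):
        rng = np.random.default_rng(7)
        n = 200
        frame = pd.DataFrame({
            "parity": rng.choice(["primiparous", "multiparous"], n),
            "device": rng.choice(["ios", "android"], n)})
        frame["ei"] = (20 + 6 * (frame["parity"] == "primiparous")
                       + rng.normal(0, 1, n))
        full = fit_full_model(frame, ["parity", "device"])
        reduced = fit_reduced_model(frame, full)
        assert reduced.variables == ["parity"]

    def test_all_significant_full_model_is_kept_unchanged(self):
        rng = np.random.default_rng(8)
        n = 200
        frame = pd.DataFrame({
            "parity": rng.choice(["primiparous", "multiparous"], n),
            "system": rng.choice(["app_only", "both_app_and_email"], n)})
        frame["ei"] = (20 + 6 * (frame["parity"] == "primiparous")
                       + 5 * (frame["system"] == "both_app_and_email")
                       + rng.normal(0, 1, n))
        full = fit_full_model(frame, ["parity", "system"])
        reduced = fit_reduced_model(frame, full)
        assert sorted(reduced.variables) == ["parity", "system"]

    def test_intercept_only_model_when_nothing_survives(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame({
            "ei": rng.normal(30, 5, 300),
            "device": rng.choice(["ios", "android"], 300)})
        full = fit_full_model(frame, ["device"])
        reduced = fit_reduced_model(frame, full)
        assert reduced.variables == [] or reduced.variable_pvalues[
            reduced.variables[0]] <= 0.05


class TestRecoverySimulations:
    def test_injected_effects_recovered_within_15_percent(self):
        """Paired effects-on/effects-off runs isolate the injected shifts.

        Infant age at registration also carries a small structural effect
        (late joiners lose period-1 scoring opportunities), so the injected
        component is estimated as the paired coefficient difference.
        """
        effects = {"parity=primiparous": 4.0, "infant_age_at_T1_weeks": -0.5}
        d_parity, d_age = [], []
        for seed in range(1, 101):
            cfg = replace(SimulationConfig(seed=seed), effect_sizes=effects)
            coefs = {}
            for label, fn in (("on", m.simulate_cohort), ("off", m.null_cohort)):
                ds, _ = fn(cfg)
                res = m.combine_frame(m.score_cohort(ds))
                full = fit_full_model(analysis_frame(ds, res),
                                      ["parity", "infant_age_at_T1_weeks"])
                coefs[label] = (full.coefficient("parity", "primiparous"),
                                full.coefficient("infant_age_at_T1_weeks"))
            d_parity.append(coefs["on"][0] - coefs["off"][0])
            d_age.append(coefs["on"][1] - coefs["off"][1])
        assert np.mean(d_parity) == pytest.approx(4.0, rel=0.15)
        assert np.mean(d_age) == pytest.approx(-0.5, rel=0.15)

    def test_true_effects_retained_among_null_covariates(self):
        """Four clearly detectable determinants survive selection alongside
        four null covariates."""
        true_vars = ["parity", "system", "recruitment", "infant_age_at_T1_weeks"]
        null_vars = ["education", "device", "infant_sex", "marital"]
        analysis_vars = [s for s in DEFAULT_VARIABLES
                         if s.name in true_vars + null_vars]
        effects = {"parity=primiparous": 6.0, "system=both_app_and_email": 8.0,
                   "recruitment=practitioner": 8.0,
                   "infant_age_at_T1_weeks": -0.9}
        all_kept = 0
        for seed in range(1, 101):
            ds, _ = simulate_cohort(
                replace(SimulationConfig(seed=seed), effect_sizes=effects))
            res = m.combine_frame(m.score_cohort(ds))
            frame = analysis_frame(ds, res)
            screen = univariate_screen(frame, analysis_vars)
            keep = screened_variables(screen)
            full = fit_full_model(frame, keep, analysis_vars)
            reduced = fit_reduced_model(frame, full, analysis_vars)
            all_kept += set(true_vars) <= set(reduced.variables)
        assert all_kept >= 90


class TestSummary:
    def _frame(self):
        return pd.DataFrame({
            "category": ["poor"] * 3 + ["moderate"] * 3 + ["high"] * 2,
            "mother_age_years": [20.0, 30.0, 40.0, 25.0, 35.0, 30.0, 28.0, 32.0],
            "parity": ["primiparous", "multiparous", "primiparous",
                       "multiparous", "multiparous", "primiparous",
                       "primiparous", "primiparous"],
        })

    VARS = [VariableSpec("mother_age_years", "continuous"),
            VariableSpec("parity", "categorical")]

    def test_hand_computed_means_and_percentages(self):
        out = summarize_by_category(self._frame(), self.VARS)
        poor_age = out[(out.variable == "mother_age_years")
                       & (out.category == "poor")].iloc[0]
        assert poor_age["mean"] == pytest.approx(30.0)
        assert poor_age["sd"] == pytest.approx(10.0)
        assert poor_age["n"] == 3
        high_prim = out[(out.variable == "parity") & (out.category == "high")
                        & (out.level == "primiparous")].iloc[0]
        assert high_prim["n"] == 2
        assert high_prim["percent"] == pytest.approx(100.0)

    def test_percentages_sum_to_100_within_category(self):
        out = summarize_by_category(self._frame(), self.VARS)
        for cat in ("poor", "moderate", "high"):
            sub = out[(out.variable == "parity") & (out.category == cat)]
            assert sub["percent"].sum() == pytest.approx(100.0)

    def test_row_order_invariance(self):
        frame = self._frame()
        shuffled = frame.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = summarize_by_category(frame, self.VARS)
        b = summarize_by_category(shuffled, self.VARS)
        pd.testing.assert_frame_equal(a, b)
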
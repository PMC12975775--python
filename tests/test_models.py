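import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from sddscore.models import (
    FitFailureError,
    ModelSpec,
    descriptive_tables,
    fit_logistic,
    fit_ordinal,
    run_battery,
)
from sddscore.outcomes import COUNT_LEVELS


def two_by_two(a=30, b=70, c=10, d=90):
    """Saturated design: exposed cases a / non-cases b, unexposed c / d.

    Exposure is coded as a 0.1-unit step of the score so the per-10% OR is
    the plain 2x2 odds ratio."""
    score = [0.1] * (a + b) + [0.0] * (c + d)
    y = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({"sdds_available": score, "any_adverse": y})


class TestFitLogistic:
    def test_saturated_2x2_matches_cross_product(self):
        t = fit_logistic(two_by_two(), ModelSpec(level=1, exposure_form="per_10pct"))
        assert t["or"].iloc[0] == pytest.approx((30 * 90) / (70 * 10), abs=1e-6)

    def test_null_effect_gives_unit_or(self, rng):
        n = 20_000
        df = pd.DataFrame(
            {
                "sdds_available": rng.random(n),
                "any_adverse": rng.random(n) < 0.2,
            }
        )
        t = fit_logistic(df, ModelSpec(level=1, exposure_form="per_10pct"))
        assert t["or"].iloc[0] == pytest.approx(1.0, abs=0.03)

    def test_per10_equals_exp_point1_beta_dual_route(self, rng):
        """Independent route: raw statsmodels fit on the native [0,1] scale,
        transformed with exp(0.1*beta)."""
        n = 5000
        s = rng.random(n)
        y = (rng.random(n) < expit(-2 + 2.0 * s)).astype(float)
        df = pd.DataFrame({"sdds_available": s, "any_adverse": y})
        t = fit_logistic(df, ModelSpec(level=1, exposure_form="per_10pct"))
        raw = sm.Logit(y, sm.add_constant(s)).fit(disp=0)
        assert t["or"].iloc[0] == pytest.approx(
            float(np.exp(0.1 * raw.params[1])), abs=1e-8
        )

    def test_rescaling_score_leaves_per10_or_unchanged(self, rng):
        n = 5000
        s = rng.random(n)
        y = (rng.random(n) < expit(-2 + 2.0 * s)).astype(float)
        df1 = pd.DataFrame({"sdds_available": s, "any_adverse": y})
        raw = sm.Logit(y, sm.add_constant(s)).fit(disp=0)
        raw_scaled = sm.Logit(y, sm.add_constant(s / 3.0)).fit(disp=0)
        # beta rescales by 3, exp(0.1*beta) on the unit scale is invariant
        assert float(np.exp(0.1 * raw.params[1])) == pytest.approx(
            float(np.exp(0.1 * raw_scaled.params[1] / 3.0)), abs=1e-8
        )
        t = fit_logistic(df1, ModelSpec(level=1, exposure_form="per_10pct"))
        assert t["or"].iloc[0] == pytest.approx(
            float(np.exp(0.1 * raw.params[1])), abs=1e-8
        )

    def test_quintile_reference_row(self, scored_cohort):
        t = fit_logistic(
            scored_cohort, ModelSpec(level=1, exposure_form="quintile"),
            quintile_col="quintile",
        )
        ref = t[t["contrast"] == "Q1"].iloc[0]
        assert ref["or"] == 1.0 and np.isnan(ref["ci_low"])
        est = t[t["contrast"] != "Q1"]
        assert ((est["ci_low"] <= est["or"]) & (est["or"] <= est["ci_high"])).all()
        # per-level Ns partition the cohort
        assert t["n"].sum() == len(scored_cohort)

    def test_adjusted_models_run(self, scored_cohort):
        for level in (2, 3):
            t = fit_logistic(
                scored_cohort, ModelSpec(level=level, exposure_form="per_10pct")
            )
            assert t["or"].iloc[0] > 1.0

    def test_covariate_uncorrelated_with_all_barely_moves_or(self, rng):
        n = 50_000
        s = rng.random(n)
        y = (rng.random(n) < expit(-2.5 + 1.5 * s)).astype(float)
        noise = rng.standard_normal(n)
        df = pd.DataFrame(
            {"sdds_available": s, "any_adverse": y, "t2dm": noise}
        )
        base = fit_logistic(df, ModelSpec(level=1, exposure_form="per_10pct"))
        adj = fit_logistic(
            df,
            ModelSpec(level=1, exposure_form="per_10pct", extra_adjustment=["t2dm"]),
        )
        assert abs(adj["or"].iloc[0] - base["or"].iloc[0]) < 0.01

    def test_stratification_restricts_rows(self, scored_cohort):
        t = fit_logistic(
            scored_cohort,
            ModelSpec(level=1, exposure_form="per_10pct", stratum="female"),
        )
        n_female = int((scored_cohort["sex_at_birth"] == "Female").sum())
        assert t["n"].iloc[0] == n_female

    def test_complete_separation_is_reported(self):
        df = pd.DataFrame(
            {
                "sdds_available": [0.0] * 20 + [1.0] * 20,
                "any_adverse": [0] * 20 + [1] * 20,
            }
        )
        with pytest.raises(FitFailureError):
            fit_logistic(df, ModelSpec(level=1, exposure_form="per_10pct"))

    def test_missing_indicator_has_six_levels(self, scored_cohort):
        from sddscore.models import missing_indicator_quintiles

        d = scored_cohort.copy()
        d["quintile_complete"] = missing_indicator_quintiles(d["sdds_complete"])
        t = fit_logistic(
            d,
            ModelSpec(level=1, exposure_form="quintile_with_missing"),
            score_col="sdds_complete",
            quintile_col="quintile_complete",
        )
        assert list(t["contrast"]) == ["Q1", "Q2", "Q3", "Q4", "Q5", "Missing"]
        assert t["n"].sum() == len(d)


class TestFitOrdinal:
    def test_collapsed_two_levels_equals_binary_logistic(self, rng):
        n = 8000
        s = rng.random(n)
        y = (rng.random(n) < expit(-2 + 2.0 * s)).astype(int)
        df = pd.DataFrame(
            {
                "sdds_available": s,
                "count_category": np.where(y == 1, "1", "0"),
                "any_adverse": y,
            }
        )
        t_ord = fit_ordinal(df, ModelSpec(level=1, outcome="count_category"))
        t_bin = fit_logistic(df, ModelSpec(level=1, exposure_form="per_10pct"))
        assert t_ord["or"].iloc[0] == pytest.approx(t_bin["or"].iloc[0], abs=1e-3)

    def test_proportional_odds_simulation_recovers_truth(self):
        """Cumulative-logit data with a planted per-10% OR of 1.3: across
        seeded replicates the estimate is unbiased and the CI covers truth."""
        covered = 0
        estimates = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            n = 20_000
            s = rng.random(n)
            beta = np.log(1.3) / 0.1  # per-unit log-odds on the [0,1] scale
            latent = beta * s + rng.logistic(size=n)
            cuts = [2.2, 3.3, 4.0]  # rare high categories, like condition counts
            yi = np.searchsorted(cuts, latent)
            df = pd.DataFrame(
                {
                    "sdds_available": s,
                    "count_category": np.asarray(COUNT_LEVELS, dtype=object)[yi],
                }
            )
            t = fit_ordinal(df, ModelSpec(level=1, outcome="count_category"))
            estimates.append(t["or"].iloc[0])
            covered += t["ci_low"].iloc[0] <= 1.3 <= t["ci_high"].iloc[0]
        assert covered >= 3
        assert np.mean(estimates) == pytest.approx(1.3, abs=0.03)

    def test_null_effect_or_near_one(self, rng):
        n = 30_000
        df = pd.DataFrame(
            {
                "sdds_available": rng.random(n),
                "count_category": rng.choice(
                    COUNT_LEVELS, size=n, p=[0.9, 0.06, 0.03, 0.01]
                ),
            }
        )
        t = fit_ordinal(df, ModelSpec(level=1, outcome="count_category"))
        assert t["or"].iloc[0] == pytest.approx(1.0, abs=0.04)

    def test_single_level_outcome_fails_loudly(self):
        df = pd.DataFrame(
            {"sdds_available": [0.1, 0.5, 0.9], "count_category": ["0", "0", "0"]}
        )
        with pytest.raises(FitFailureError, match="fewer than 2"):
            fit_ordinal(df, ModelSpec(level=1, outcome="count_category"))


class TestRunBattery:
    @pytest.fixture(scope="class")
    def battery(self, scored_cohort, codebook):
        from sddscore.reduction import FactorReducer

        unit = scored_cohort[[f"score_{n}" for n in codebook.item_names]].rename(
            columns=lambda c: c.removeprefix("score_")
        )
        red = FactorReducer().fit(unit)
        return run_battery(
            scored_cohort,
            codebook,
            selection=red.selection_,
            levels=[1],
            stratify=True,
            conditions=("SLD", "cirrhosis", "HCC"),
        )

    def test_expected_tables_present(self, battery):
        assert set(battery) == {
            "total", "conditions", "selected_variables", "ordinal", "stratified",
        }

    def test_total_table_has_both_treatments(self, battery):
        t = battery["total"]
        assert set(t["treatment"]) == {"available", "missing_indicator"}
        miss = t[(t["treatment"] == "missing_indicator")
                 & (t["exposure"] == "quintile_with_missing")]
        assert "Missing" in set(miss["contrast"])

    def test_hcc_gets_hbv_hcv_adjusted_variant(self, battery):
        t = battery["conditions"]
        assert "available_hbv_hcv_adj" in set(t["treatment"])

    def test_no_missingness_makes_treatments_agree(self, codebook):
        from sddscore import GeneratorConfig, generate_cohort, score_cohort
        from sddscore.outcomes import apply_outcomes, synthetic_condition_map

        coh = generate_cohort(
            GeneratorConfig(n=3000, seed=5, missing_base_rate=0.0)
        )
        data = pd.concat(
            [
                coh,
                score_cohort(coh, codebook),
                apply_outcomes(coh, synthetic_condition_map()),
            ],
            axis=1,
        )
        tables = run_battery(data, codebook, levels=[1], stratify=False,
                             conditions=())
        t = tables["total"]
        avail = t[(t["treatment"] == "available") & (t["exposure"] == "quintile")]
        miss = t[(t["treatment"] == "missing_indicator")
                 & (t["exposure"] == "quintile_with_missing")
                 & (t["contrast"] != "Missing")]
        np.testing.assert_allclose(
            avail["or"].to_numpy(), miss["or"].to_numpy(), rtol=1e-8
        )

    def test_failed_cells_marked_not_fatal(self, codebook, scored_cohort):
        broken = scored_cohort.copy()
        broken["cond_ALD"] = 0  # no cases: fit must fail but be marked
        tables = run_battery(
            broken, codebook, levels=[1], stratify=False, conditions=("ALD",)
        )
        assert (tables["conditions"]["contrast"] == "FIT_FAILED").all()


class TestDescriptiveTables:
    def test_quintile_ns_sum_to_cohort(self, scored_cohort, codebook):
        desc = descriptive_tables(scored_cohort, codebook)
        n_row = desc["characteristics"].iloc[0]
        total = sum(n_row[q] for q in ("Q1", "Q2", "Q3", "Q4", "Q5"))
        assert total == int(scored_cohort["quintile"].notna().sum())

    def test_identical_distributions_t_zero_p_one(self, codebook):
        df = pd.DataFrame(
            {
                "sdds_available": np.linspace(0.1, 0.9, 40),
                "any_adverse": [True, False] * 20,
                **{f"domain_{d}": 0.5 for d in
                   ("economic_stability", "education", "healthcare_access_quality",
                    "neighborhood_built_environment", "social_community_context")},
            }
        )
        desc = descriptive_tables(df, codebook)
        comp = desc["domain_comparison"]
        assert (comp["t_statistic"] == 0).all()
        assert (comp["p_value"] == 1).all()

    def test_single_participant_group_reports_missing_sd(self, codebook):
        df = pd.DataFrame(
            {
                "sdds_available": np.linspace(0, 1, 30),
                "any_adverse": [True] + [False] * 29,
                "domain_economic_stability": np.linspace(0, 1, 30),
            }
        )
        desc = descriptive_tables(df, codebook)
        row = desc["domain_comparison"].iloc[0]
        assert np.isnan(row["sd_with_condition"])
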
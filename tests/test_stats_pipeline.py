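"""Mixed-model layer: fitting, interaction test, contrasts, transforms, AIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import BLACK_ONLY

from camoquant.stats_pipeline import (
    ModelSpec,
    choose_transform,
    coefficient_table,
    compare_models_aic,
    estimated_marginal_means,
    fit_lmm,
    test_interaction as interaction_f_test,
    time_contrasts_within_population,
)
from camoquant.synthetic_data import (
    ExperimentDesign,
    PopulationProfile,
    generate_cone_catch_table,
    null_profiles,
)
from camoquant.visual_model import add_metric_columns


def _toy_table(means, n_fish=4, noise=0.0, seed=0):
    """Balanced toy: populations x times from a cell-mean dict."""
    rng = np.random.default_rng(seed)
    pops = sorted({p for p, _ in means})
    times = sorted({t for _, t in means})
    rows = []
    for pop in pops:
        for f in range(n_fish):
            fid = f"{pop}{f}"
            sex = "M" if f % 2 else "F"
            length = 3.5 + 0.1 * f
            for t in times:
                y = means[(pop, t)] + (rng.normal(0, noise) if noise else 0.0)
                rows.append((fid, pop, sex, length, t, y))
    return pd.DataFrame(rows, columns=["fish_id", "population", "sex",
                                       "length_cm", "time_min", "y"])


class TestFit:
    def test_zero_noise_saturated_model_reproduces_cell_means(self):
        means = {("A", 0): 1.0, ("A", 1): 2.0, ("B", 0): 1.5, ("B", 1): 1.2}
        table = _toy_table(means)
        fit = fit_lmm(table, ModelSpec(response="y", include_length=False,
                                       include_sex=False))
        cells, _, _ = estimated_marginal_means(fit)
        for _, row in cells.iterrows():
            assert row["emmean_link"] == pytest.approx(
                means[(row["population"], row["time_min"])], abs=1e-8)

    def test_single_population_is_informative_error(self, black_metrics_table):
        one_pop = black_metrics_table[black_metrics_table["population"] == "FW1"]
        with pytest.raises(ValueError, match="population"):
            fit_lmm(one_pop, ModelSpec(response="luminance"))

    def test_constant_response_rejected(self, black_metrics_table):
        df = black_metrics_table.copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_lmm(df, ModelSpec(response="flat"))

    def test_variance_components_recovered_without_fish_effects(self):
        """fish_sd=0: random-intercept variance ~ 0, residual SD ~ sigma."""
        sigma = 0.04
        ri_vars, resid_vars = [], []
        for rep in range(20):
            design = ExperimentDesign(backgrounds=BLACK_ONLY, fish_per_cell=10,
                                      seed=3000 + rep)
            prof = null_profiles(design, PopulationProfile(
                fish_sd=0.0,
                resid_sd={"luminance": sigma, "hue": 0.0, "saturation": 0.0}))
            table = add_metric_columns(generate_cone_catch_table(design, prof))
            fit = fit_lmm(table, ModelSpec(response="luminance"))
            ri_vars.append(fit.random_intercept_var)
            resid_vars.append(fit.residual_var)
        assert np.mean(ri_vars) < 0.25 * sigma ** 2
        assert np.sqrt(np.mean(resid_vars)) == pytest.approx(sigma, rel=0.10)


class TestInteraction:
    def test_numerator_df_is_nine_for_four_by_four(self, black_luminance_fit):
        """(4 populations - 1) x (4 times - 1) interaction coefficients."""
        res = interaction_f_test(black_luminance_fit)
        assert res.df_num == 9
        assert res.df_method == "between-within"

    def test_denominator_df_between_within(self, black_luminance_fit):
        """N - #fish - rank(within columns): 80 - 20 - 12 = 48 at 5 fish/cell."""
        assert interaction_f_test(black_luminance_fit).df_den == 48

    def test_strong_interaction_detected(self):
        prof = {p: PopulationProfile(rate_k=1.5) for p in ("FW1", "FW2", "MW1")}
        prof["MW2"] = PopulationProfile(rate_k=0.3)
        design = ExperimentDesign(backgrounds=BLACK_ONLY, fish_per_cell=10,
                                  seed=17, populations=tuple(prof))
        table = add_metric_columns(generate_cone_catch_table(design, prof))
        fit = fit_lmm(table, ModelSpec(response="luminance"))
        assert interaction_f_test(fit).p_value < 1e-4

    def test_no_interaction_terms_errors(self, black_metrics_table):
        fit = fit_lmm(black_metrics_table,
                      ModelSpec(response="luminance", interaction=False))
        with pytest.raises(ValueError, match="interaction"):
            interaction_f_test(fit)


class TestContrasts:
    def test_combinatorics_four_times_four_populations(self, black_luminance_fit):
        con = time_contrasts_within_population(black_luminance_fit)
        assert len(con) == 24  # 4 populations x C(4,2)
        assert (con["family_size"] == 6).all()
        assert set(con["population"]) == {"FW1", "FW2", "MW1", "MW2"}

    def test_adjusted_p_at_least_unadjusted(self, black_luminance_fit):
        con = time_contrasts_within_population(black_luminance_fit)
        assert (con["p_adjusted"] >= con["p_unadjusted"] - 1e-12).all()
        assert con["p_adjusted"].between(0, 1).all()

    def test_identity_transform_regrid_equals_link_scale(self, black_luminance_fit):
        """With no transform the response-scale contrasts are the link-scale
        EMM differences exactly."""
        con = time_contrasts_within_population(black_luminance_fit)
        cells, _, _ = estimated_marginal_means(black_luminance_fit)
        lookup = {(p, t): m for p, t, m in zip(
            cells["population"], cells["time_min"], cells["emmean_link"])}
        for _, row in con.iterrows():
            direct = (lookup[(row["population"], row["time_a"])]
                      - lookup[(row["population"], row["time_b"])])
            assert row["estimate"] == pytest.approx(direct, abs=1e-10)

    def test_tukey_p_matches_studentised_range_oracle(self, black_luminance_fit):
        """Adjusted p recomputed directly from the studentised-range
        distribution; monotone decreasing in |t| within a family."""
        con = time_contrasts_within_population(black_luminance_fit)
        for _, row in con.iterrows():
            expected = stats.studentized_range.sf(
                abs(row["t_ratio"]) * np.sqrt(2), 4, row["df"])
            expected = min(max(expected, row["p_unadjusted"]), 1.0)
            assert row["p_adjusted"] == pytest.approx(expected, rel=1e-9)
        fam = con[con["population"] == "FW1"].sort_values("t_ratio",
                                                          key=np.abs)
        assert (np.diff(fam["p_adjusted"].to_numpy()) <= 1e-12).all()

    def test_log_transform_back_transforms_to_response_scale(self):
        """On log-modelled data the contrast estimates are differences of
        back-transformed means, not log-ratios."""
        means = {("A", 0): 2.0, ("A", 1): 1.0, ("B", 0): 1.5, ("B", 1): 1.4}
        table = _toy_table(means, n_fish=6, noise=0.01, seed=3)
        fit = fit_lmm(table, ModelSpec(response="y", transform="log"))
        con = time_contrasts_within_population(fit)
        row = con[(con["population"] == "A") & (con["time_a"] == 0)].iloc[0]
        assert row["estimate"] == pytest.approx(2.0 - 1.0, abs=0.05)

    def test_missing_cell_names_the_cell(self, black_metrics_table):
        broken = black_metrics_table[
            ~((black_metrics_table["population"] == "FW1")
              & (black_metrics_table["time_min"] == 8))]
        fit = fit_lmm(broken, ModelSpec(response="luminance"))
        with pytest.raises(ValueError, match="FW1"):
            time_contrasts_within_population(fit)

    def test_full_family_adjustment_is_more_conservative(self, black_luminance_fit):
        within = time_contrasts_within_population(black_luminance_fit,
                                                  family="within")
        full = time_contrasts_within_population(black_luminance_fit,
                                                family="all")
        assert (full["p_adjusted"] >= within["p_adjusted"] - 1e-12).all()


class TestTransformChoice:
    def test_identity_chosen_for_normal_homoscedastic_data(self):
        rng = np.random.default_rng(1)
        means = {(p, t): 1.0 + 3.0 * t + {"A": 0.0, "B": 2.0}[p]
                 for p in "AB" for t in (0, 1, 2, 3)}
        table = _toy_table(means, n_fish=12, noise=0.4, seed=21)
        assert choose_transform(table, "y") == "identity"

    def test_log_chosen_for_lognormal_data(self):
        """exp(normal) responses: log should win in (nearly) every dataset."""
        wins = 0
        for rep in range(10):
            design = ExperimentDesign(backgrounds=BLACK_ONLY, fish_per_cell=25,
                                      seed=80000 + rep)
            prof = null_profiles(design, PopulationProfile(
                fish_sd={"luminance": 0.15, "hue": 0.004, "saturation": 0.008},
                resid_sd={"luminance": 0.3, "hue": 0.004, "saturation": 0.008}))
            table = add_metric_columns(generate_cone_catch_table(design, prof))
            table["resp"] = np.exp(table["luminance"])
            wins += choose_transform(table, "resp") == "log"
        assert wins >= 9

    def test_log_skipped_when_zeros_present(self, black_metrics_table):
        df = black_metrics_table.copy()
        df["with_zero"] = df["luminance"].to_numpy()
        df.loc[df.index[0], "with_zero"] = 0.0
        chosen = choose_transform(df, "with_zero")
        assert chosen in ("identity", "sqrt")

    def test_constant_response_errors(self, black_metrics_table):
        df = black_metrics_table.copy()
        df["flat"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            choose_transform(df, "flat")


class TestAic:
    def test_duplicate_specs_identical_aic(self, black_metrics_table):
        spec = ModelSpec(response="luminance")
        out = compare_models_aic(black_metrics_table, [spec, spec])
        assert out["aic"].iloc[0] == pytest.approx(out["aic"].iloc[1], abs=1e-6)

    def test_aic_recomputed_from_loglik_and_k(self, black_metrics_table):
        out = compare_models_aic(black_metrics_table,
                                 [ModelSpec(response="luminance")])
        row = out.iloc[0]
        assert row["aic"] == pytest.approx(-2 * row["loglik"] + 2 * row["k"],
                                           abs=1e-8)

    def test_real_sex_effect_favours_sex_model(self):
        """With an injected sex effect the sex-including model usually wins
        decisively (delta AIC > 2)."""
        wins = 0
        for rep in range(20):
            design = ExperimentDesign(backgrounds=BLACK_ONLY, fish_per_cell=25,
                                      seed=7000 + rep)
            prof = null_profiles(design, PopulationProfile(
                sex_effect={"luminance": 0.05, "hue": 0.0, "saturation": 0.0}))
            table = add_metric_columns(generate_cone_catch_table(design, prof))
            out = compare_models_aic(table, [
                ModelSpec(response="luminance"),
                ModelSpec(response="luminance", include_sex=False)])
            best = out.iloc[0]
            wins += ("sex" in best["model"]) and (out["delta_aic"].iloc[1] > 2)
        assert wins >= 16  # >= 80%

    def test_reml_fit_refuses_aic(self, black_luminance_fit):
        with pytest.raises(ValueError, match="REML|ML"):
            black_luminance_fit.aic()


class TestCoefficients:
    def test_within_and_between_df_assignment(self, black_luminance_fit):
        ct = coefficient_table(black_luminance_fit).set_index("term")
        n, g = black_luminance_fit.n_obs, black_luminance_fit.n_fish
        assert ct.loc["C(time_min)[T.1.0]", "df"] == n - g - 12
        assert ct.loc["C(sex)[T.M]", "df"] == black_luminance_fit.ddf_between
        assert (ct["ci_low"] <= ct["estimate"]).all()
        assert (ct["estimate"] <= ct["ci_high"]).all()
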
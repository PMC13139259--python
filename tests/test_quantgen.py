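"""Mixed-model variance components, heritability and correlations.

The REML path is checked against two independent oracles: the closed-form
balanced-ANOVA method-of-moments estimators (which REML must equal for
interior solutions on balanced designs) and statsmodels' MixedLM.
"""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microgdi import (
    SimulationSpec,
    VarianceComponents,
    diet_effect_test,
    fit_mixed_single_diet,
    fit_mixed_two_diet,
    gdi_test,
    genetic_correlation_cross_env,
    genetic_correlation_yamada,
    heritability,
    heritability_from_components,
    int_transform,
    phenotypic_correlation,
    simulate_trait_table,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def anova_two_diet(obs: pd.DataFrame):
    """Closed-form balanced two-way mixed ANOVA variance components."""
    l = obs["line_id"].nunique()
    d = obs["diet"].nunique()
    r = len(obs) // (l * d)
    grand = obs["value"].mean()
    lm = obs.groupby("line_id")["value"].mean()
    dm = obs.groupby("diet")["value"].mean()
    cm = obs.groupby(["line_id", "diet"])["value"].mean()
    ss_l = d * r * ((lm - grand) ** 2).sum()
    ss_d = l * r * ((dm - grand) ** 2).sum()
    ss_cells = r * ((cm - grand) ** 2).sum()
    ss_lxd = ss_cells - ss_l - ss_d
    resid = obs["value"] - obs.set_index(["line_id", "diet"]).index.map(cm)
    ss_e = (resid**2).sum()
    ms_l = ss_l / (l - 1)
    ms_lxd = ss_lxd / ((l - 1) * (d - 1))
    ms_e = ss_e / (l * d * (r - 1))
    return (ms_l - ms_lxd) / (d * r), (ms_lxd - ms_e) / r, ms_e


def anova_one_way(obs: pd.DataFrame):
    """Closed-form balanced one-way random-effects components."""
    l = obs["line_id"].nunique()
    r = len(obs) // l
    lm = obs.groupby("line_id")["value"].mean()
    grand = obs["value"].mean()
    ms_b = r * ((lm - grand) ** 2).sum() / (l - 1)
    resid = obs["value"] - obs["line_id"].map(lm)
    ms_w = (resid**2).sum() / (l * (r - 1))
    return (ms_b - ms_w) / r, ms_w


# ---------------------------------------------------------------------------
# INT
# ---------------------------------------------------------------------------

class TestIntTransform:
    def test_three_distinct_values(self):
        """Probit of (0.5/3, 1.5/3, 2.5/3), via an independent quantile oracle."""
        nd = statistics.NormalDist()
        expected = [nd.inv_cdf((k - 0.5) / 3) for k in (1, 2, 3)]
        out = int_transform([10.0, -3.0, 7.0])
        np.testing.assert_allclose(sorted(out), expected, atol=1e-9)
        assert expected[1] == 0.0
        assert expected[2] == pytest.approx(0.9674, abs=1e-4)

    def test_ties_get_average_ranks(self):
        out = int_transform([1.0, 1.0, 5.0])
        assert out[0] == out[1] < out[2]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=50, unique=True
        )
    )
    def test_monotone_and_centred(self, values):
        out = int_transform(values)
        order_in = np.argsort(values)
        order_out = np.argsort(out)
        np.testing.assert_array_equal(order_in, order_out)
        assert abs(out.mean()) < 1e-10  # symmetry of the probit grid

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            int_transform([1.0])


# ---------------------------------------------------------------------------
# REML fits
# ---------------------------------------------------------------------------

class TestTwoDietFit:
    def test_matches_balanced_anova(self):
        spec = SimulationSpec(n_lines=50, seed=21)
        obs = simulate_trait_table(spec)
        s_l, s_lxd, s_e = anova_two_diet(obs)
        assert min(s_l, s_lxd, s_e) > 0  # interior solution
        vc = fit_mixed_two_diet(obs)
        assert vc.sigma_line == pytest.approx(s_l, abs=1e-6)
        assert vc.sigma_lxd == pytest.approx(s_lxd, abs=1e-6)
        assert vc.sigma_resid == pytest.approx(s_e, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        obs = simulate_trait_table(SimulationSpec(n_lines=25, seed=3))
        fit = smf.mixedlm(
            "value ~ diet", obs, groups=obs["line_id"],
            re_formula="1", vc_formula={"lxd": "0 + C(diet)"},
        ).fit(reml=True)
        vc = fit_mixed_two_diet(obs)
        assert vc.sigma_line == pytest.approx(float(fit.cov_re.iloc[0, 0]), abs=1e-4)
        assert vc.sigma_lxd == pytest.approx(float(fit.vcomp[0]), abs=1e-4)
        assert vc.sigma_resid == pytest.approx(float(fit.scale), abs=1e-4)

    def test_constant_response_degenerates(self):
        obs = simulate_trait_table(
            SimulationSpec(n_lines=10, sigma_line2=0, sigma_lxd2=0,
                           sigma_resid2=0, diet_effect=0, seed=1)
        )
        vc = fit_mixed_two_diet(obs)
        assert vc.sigma_line == pytest.approx(0.0, abs=1e-10)
        assert vc.sigma_lxd == pytest.approx(0.0, abs=1e-10)
        assert abs(vc.fixed_effects["diet[restricted-control]"]) < 1e-10

    def test_diet_contrast_recovers_injected_effect(self):
        obs = simulate_trait_table(SimulationSpec(n_lines=60, diet_effect=1.5, seed=9))
        vc = fit_mixed_two_diet(obs)
        assert vc.fixed_effects["diet[restricted-control]"] == pytest.approx(1.5, abs=0.2)

    def test_single_diet_data_rejected(self, sim_traits):
        control = sim_traits[sim_traits["diet"] == "control"]
        with pytest.raises(ValueError):
            fit_mixed_two_diet(control)

    def test_vcov_is_symmetric_psd_on_diagonal(self, sim_traits):
        vc = fit_mixed_two_diet(sim_traits)
        v = vc.vcov_components
        np.testing.assert_allclose(v, v.T, atol=1e-8)
        assert (np.diag(v) > 0).all()


class TestSingleDietFit:
    def test_matches_balanced_anova(self):
        obs = simulate_trait_table(SimulationSpec(n_lines=50, seed=13))
        sub = obs[obs["diet"] == "control"]
        s_g, s_e = anova_one_way(sub)
        assert s_g > 0
        vc = fit_mixed_single_diet(sub)
        assert vc.sigma_line == pytest.approx(s_g, abs=1e-6)
        assert vc.sigma_resid == pytest.approx(s_e, abs=1e-6)

    def test_null_lines_shrink_to_zero(self):
        obs = simulate_trait_table(
            SimulationSpec(n_lines=100, n_reps=4, sigma_line2=0.0,
                           sigma_lxd2=0.0, seed=5)
        )
        vc = fit_mixed_single_diet(obs[obs["diet"] == "control"])
        assert vc.sigma_line < 0.05

    def test_single_replicate_rejected(self):
        obs = pd.DataFrame(
            {"line_id": ["a", "b", "c"], "diet": ["control"] * 3,
             "replicate": [1] * 3, "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_mixed_single_diet(obs)


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

class TestHeritability:
    def test_ratio_examples(self):
        assert heritability_from_components(0.12, 0.72).h2 == pytest.approx(
            0.12 / 0.84
        )
        assert heritability_from_components(0.0, 1.0).h2 == 0.0
        assert heritability_from_components(0.5, 0.5).h2 == 0.5

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            heritability_from_components(0.0, 0.0)

    def test_scale_invariance(self, sim_traits):
        sub = sim_traits[sim_traits["diet"] == "control"]
        scaled = sub.assign(value=sub["value"] * 3.7)
        h1 = heritability(fit_mixed_single_diet(sub))
        h2 = heritability(fit_mixed_single_diet(scaled))
        assert h1.h2 == pytest.approx(h2.h2, abs=1e-6)

    def test_ci_is_plus_minus_1p96_se(self, sim_traits):
        h = heritability(fit_mixed_single_diet(sim_traits[sim_traits.diet == "control"]))
        assert h.ci_low == pytest.approx(h.h2 - 1.96 * h.se)
        assert h.ci_high == pytest.approx(h.h2 + 1.96 * h.se)

    def test_delta_se_matches_parametric_bootstrap(self, rng):
        """Delta-method SE vs the SD of closed-form ANOVA H2 over 2,000
        parametric draws on a balanced one-way design (sigma_G = sigma_e)."""
        n_lines, reps = 50, 4
        s_g = s_e = 0.5
        line = np.repeat([f"l{i}" for i in range(n_lines)], reps)
        y = (
            np.repeat(rng.normal(0, np.sqrt(s_g), n_lines), reps)
            + rng.normal(0, np.sqrt(s_e), n_lines * reps)
        )
        obs = pd.DataFrame(
            {"line_id": line, "diet": "control", "replicate": 1, "value": y}
        )
        vc = fit_mixed_single_diet(obs)
        delta_se = heritability(vc).se

        # bootstrap at the fitted components, vectorised ANOVA estimator
        n_boot = 2000
        l_eff = rng.normal(0, np.sqrt(vc.sigma_line), (n_boot, n_lines))
        e_eff = rng.normal(0, np.sqrt(vc.sigma_resid), (n_boot, n_lines, reps))
        cells = l_eff[:, :, None] + e_eff
        lm = cells.mean(axis=2)
        grand = lm.mean(axis=1, keepdims=True)
        ms_b = reps * ((lm - grand) ** 2).sum(axis=1) / (n_lines - 1)
        ms_w = ((cells - lm[:, :, None]) ** 2).sum(axis=(1, 2)) / (
            n_lines * (reps - 1)
        )
        g_hat = (ms_b - ms_w) / reps
        h2_boot = g_hat / (g_hat + ms_w)
        assert delta_se == pytest.approx(h2_boot.std(ddof=1), rel=0.10)


# ---------------------------------------------------------------------------
# GDI and diet tests
# ---------------------------------------------------------------------------

class TestGdiTest:
    def test_nesting_full_at_least_reduced(self):
        for seed in (1, 2, 3):
            obs = simulate_trait_table(SimulationSpec(n_lines=30, seed=seed))
            full = fit_mixed_two_diet(obs, interaction=True)
            reduced = fit_mixed_two_diet(obs, interaction=False)
            assert full.loglik_reml >= reduced.loglik_reml - 1e-6

    def test_detects_strong_interaction(self):
        obs = simulate_trait_table(
            SimulationSpec(n_lines=88, sigma_lxd2=0.5, seed=4)
        )
        res = gdi_test(obs)
        assert res.p_value < 1e-4
        assert res.statistic > 0

    def test_mixture_p_is_half_of_chi2(self):
        obs = simulate_trait_table(SimulationSpec(n_lines=40, sigma_lxd2=0.3, seed=6))
        mix = gdi_test(obs, method="mixture")
        chi = gdi_test(obs, method="chi2")
        assert mix.statistic == pytest.approx(chi.statistic)
        assert mix.p_value == pytest.approx(chi.p_value / 2)


class TestDietEffect:
    def test_identical_diets_give_zero_contrast(self, rng):
        n_lines, reps = 20, 3
        half = pd.DataFrame(
            {
                "line_id": np.repeat([f"l{i}" for i in range(n_lines)], reps),
                "replicate": np.tile(np.arange(1, reps + 1), n_lines),
                "value": rng.normal(size=n_lines * reps),
            }
        )
        obs = pd.concat(
            [half.assign(diet="control"), half.assign(diet="restricted")],
            ignore_index=True,
        )
        contrast, p = diet_effect_test(obs)
        assert contrast == pytest.approx(0.0, abs=1e-6)
        assert p > 0.99

    def test_large_shift_detected(self):
        obs = simulate_trait_table(SimulationSpec(n_lines=88, diet_effect=1.0, seed=8))
        contrast, p = diet_effect_test(obs)
        assert p < 1e-6
        assert contrast == pytest.approx(1.0, abs=0.25)

    def test_f_variant_agrees_in_direction(self):
        obs = simulate_trait_table(SimulationSpec(n_lines=60, diet_effect=0.8, seed=2))
        c_lrt, p_lrt = diet_effect_test(obs, method="lrt")
        c_f, p_f = diet_effect_test(obs, method="f")
        assert np.sign(c_lrt) == np.sign(c_f)
        assert p_f < 0.01 and p_lrt < 0.01


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

class TestYamada:
    def test_hand_value(self):
        vc = VarianceComponents(
            sigma_line=0.3, sigma_resid=0.6, sigma_lxd=0.1, n_lines=88
        )
        assert genetic_correlation_yamada(vc).rho == pytest.approx(0.75)

    def test_no_interaction_gives_one(self):
        vc = VarianceComponents(sigma_line=0.4, sigma_resid=0.6, sigma_lxd=0.0,
                                n_lines=50)
        assert genetic_correlation_yamada(vc).rho == 1.0

    def test_zero_line_variance_gives_zero(self):
        vc = VarianceComponents(sigma_line=0.0, sigma_resid=0.6, sigma_lxd=0.2,
                                n_lines=50)
        assert genetic_correlation_yamada(vc).rho == 0.0


class TestCrossEnvCorrelation:
    def test_sign_antisymmetry(self, rng):
        """Line effects negated on the second diet force a negative rho."""
        n_lines, reps = 30, 3
        l_eff = rng.normal(0, 1.0, n_lines)
        rows = []
        for i in range(n_lines):
            for diet, sign in (("control", 1.0), ("restricted", -1.0)):
                for rep in range(reps):
                    rows.append(
                        {"line_id": f"l{i}", "diet": diet, "replicate": rep + 1,
                         "value": sign * l_eff[i] + rng.normal(0, 0.3)}
                    )
        est = genetic_correlation_cross_env(pd.DataFrame(rows))
        assert est.rho < -0.5

    def test_perfect_correlation_construction(self, rng):
        obs = simulate_trait_table(
            SimulationSpec(n_lines=88, sigma_lxd2=0.0, seed=17)
        )
        est = genetic_correlation_cross_env(obs)
        assert est.rho == pytest.approx(1.0, abs=0.15)
        assert est.kind == "genetic_cross_env"

    def test_too_few_lines_rejected(self):
        obs = simulate_trait_table(SimulationSpec(n_lines=2, seed=1))
        with pytest.raises(ValueError):
            genetic_correlation_cross_env(obs)


class TestPhenotypicCorrelation:
    def test_se_formula_at_zero_rho(self):
        # x,y with exactly zero Spearman correlation; n_override = 103 reads
        # SE = (1 - 0)/sqrt(100) = 0.1
        est = phenotypic_correlation([1, 2, 3, 4], [2, 4, 1, 3], n_override=103)
        assert est.rho == pytest.approx(0.0)
        assert est.se == pytest.approx(0.1)

    def test_fisher_z_ci_at_half(self):
        # ranks constructed for Spearman rho = 0.5 exactly
        est = phenotypic_correlation([1, 2, 3, 4, 5], [3, 1, 4, 2, 5])
        assert est.rho == pytest.approx(0.5)
        z = 0.5 * np.log(1.5 / 0.5)
        assert z == pytest.approx(0.5493, abs=1e-4)
        se = (1 - 0.25) / np.sqrt(5 - 3)
        assert est.ci_low == pytest.approx(np.tanh(z - 1.96 * se))
        assert est.ci_high == pytest.approx(np.tanh(z + 1.96 * se))

    def test_perfect_monotone_flagged(self):
        est = phenotypic_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert est.rho == 1.0
        assert (est.ci_low, est.ci_high) == (1.0, 1.0)
        assert est.flag is not None

    def test_matches_scipy_spearman(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        from scipy.stats import spearmanr

        assert phenotypic_correlation(x, y).rho == pytest.approx(
            spearmanr(x, y).statistic
        )

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            phenotypic_correlation([1, 2, 3], [3, 2, 1])
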
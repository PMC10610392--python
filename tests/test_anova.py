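"""Joint ANOVA, variance components, genetic parameters and BLUPs."""

import numpy as np
import pandas as pd
import pytest

from metsel.anova import (
    JointANOVA,
    VarianceComponents,
    fit_blup,
    genetic_parameters,
    joint_anova,
    pretests,
    reml_components,
    variance_components,
)

from conftest import synthetic_index_table


def anova_from_mean_squares(ms_g, ms_ge, ms_rep, ms_res, g=20, e=6, r=3):
    """Assemble an ANOVA table directly from stratum mean squares."""
    df = {"ENV": e - 1, "REP(ENV)": e * (r - 1), "GEN": g - 1,
          "GEN:ENV": (g - 1) * (e - 1), "Residuals": (g - 1) * e * (r - 1)}
    ms = {"ENV": np.nan, "REP(ENV)": ms_rep, "GEN": ms_g,
          "GEN:ENV": ms_ge, "Residuals": ms_res}
    tab = pd.DataFrame({"df": pd.Series(df), "ms": pd.Series(ms)})
    tab["ss"] = tab["df"] * tab["ms"]
    return tab


def test_degrees_of_freedom_for_study_design():
    table = synthetic_index_table(g=20, e=6, r=3, seed=1)
    tab = joint_anova(table, "GY")
    assert tab.loc["GEN", "df"] == 19
    assert tab.loc["GEN:ENV", "df"] == 95
    assert tab.loc["Residuals", "df"] == 228
    assert tab.loc["REP(ENV)", "df"] == 12
    assert tab["df"].sum() == 20 * 6 * 3 - 1


def test_sum_of_squares_additivity():
    table = synthetic_index_table(g=10, e=4, r=3, sigma_g=1.0,
                                  sigma_ge=0.5, seed=2)
    tab = joint_anova(table, "GY")
    y = table.data["value"]
    total = np.sum((y - y.mean()) ** 2)
    assert tab["ss"].sum() == pytest.approx(total, rel=1e-8)


def test_zero_noise_additive_data_has_zero_interaction_ss():
    table = synthetic_index_table(g=8, e=4, r=2, sigma_g=2.0, sigma_e=0.0,
                                  seed=3)
    tab = joint_anova(table, "GY")
    assert tab.loc["GEN:ENV", "ss"] == pytest.approx(0.0, abs=1e-16)


def test_null_simulation_f_statistic_near_one():
    fs = []
    for seed in range(200):
        table = synthetic_index_table(g=6, e=4, r=2, sigma_e=1.0, seed=seed)
        fs.append(joint_anova(table, "GY").loc["GEN", "f"])
    assert np.mean(fs) == pytest.approx(1.0, abs=0.15)


def test_variance_components_from_worked_mean_squares():
    # components (0.0073, 0.0063, 0.0007) imply these stratum mean squares
    ms_res = 0.0007
    ms_ge = ms_res + 3 * 0.0063
    ms_g = ms_ge + 18 * 0.0073
    tab = anova_from_mean_squares(ms_g, ms_ge, 0.0026, ms_res)
    vc = variance_components(tab, g=20, e=6, r=3)
    assert vc.sigma2_g == pytest.approx(0.0073)
    assert vc.sigma2_ge == pytest.approx(0.0063)
    assert vc.sigma2_e == pytest.approx(0.0007)
    assert vc.sigma2_p == pytest.approx(0.0143)


def test_equal_interaction_and_residual_ms_gives_zero_component():
    tab = anova_from_mean_squares(0.1, 0.02, 0.02, 0.02)
    vc = variance_components(tab, g=20, e=6, r=3)
    assert vc.sigma2_ge == 0.0
    assert not vc.truncated


def test_negative_solution_truncated_and_flagged():
    tab = anova_from_mean_squares(0.1, 0.01, 0.02, 0.03)
    vc = variance_components(tab, g=20, e=6, r=3)
    assert vc.sigma2_ge == 0.0
    assert "sigma2_ge" in vc.truncated


def test_component_recovery_simulation():
    rel_errors = []
    for seed in range(100):
        table = synthetic_index_table(
            g=50, e=6, r=3, sigma_g=4.0, sigma_ge=2.0, sigma_e=1.0,
            seed=1000 + seed,
        )
        tab = joint_anova(table, "GY")
        vc = variance_components(tab, g=50, e=6, r=3)
        rel_errors.append(
            [
                abs(vc.sigma2_g - 4.0) / 4.0,
                abs(vc.sigma2_ge - 2.0) / 2.0,
                abs(vc.sigma2_e - 1.0) / 1.0,
            ]
        )
    med = np.median(rel_errors, axis=0)
    assert (med < 0.25).all()


def test_genetic_parameters_worked_example():
    vc = VarianceComponents(0.0073, 0.0063, 0.0007)
    gp = genetic_parameters(vc, e=6, r=3, grand_mean=0.85)
    assert gp.H2 == pytest.approx(0.51, abs=0.01)
    assert gp.R2gei == pytest.approx(0.441, abs=0.005)
    assert gp.accuracy == pytest.approx(np.sqrt(gp.h2mg))
    assert gp.CV_ratio == pytest.approx(gp.CVg / gp.CVr)


def test_noise_free_limit_heritability_one():
    gp = genetic_parameters(VarianceComponents(2.0, 0.0, 0.0), e=6, r=3,
                            grand_mean=1.0)
    assert gp.H2 == 1.0
    assert gp.h2mg == 1.0
    assert gp.accuracy == 1.0


def test_h2mg_recovery_matches_planted_components():
    # value implied by the planted components
    planted = 4.0 / (4.0 + 2.0 / 6 + 1.0 / 18)
    estimates = []
    for seed in range(50):
        table = synthetic_index_table(
            g=50, e=6, r=3, sigma_g=4.0, sigma_ge=2.0, sigma_e=1.0,
            seed=2000 + seed,
        )
        tab = joint_anova(table, "GY")
        vc = variance_components(tab, g=50, e=6, r=3)
        estimates.append(genetic_parameters(vc, 6, 3, 1.0).h2mg)
    assert np.median(estimates) == pytest.approx(planted, abs=0.05)


def test_mom_and_reml_agree_on_balanced_data():
    diffs = []
    for seed in range(50):
        table = synthetic_index_table(
            g=50, e=6, r=3, sigma_g=4.0, sigma_ge=2.0, sigma_e=1.0,
            seed=3000 + seed,
        )
        tab = joint_anova(table, "GY")
        mom = variance_components(tab, 50, 6, 3)
        reml = reml_components(tab, 50, 6, 3)
        diffs.append(
            [
                abs(mom.sigma2_g - reml.sigma2_g) / mom.sigma2_g,
                abs(mom.sigma2_ge - reml.sigma2_ge) / mom.sigma2_ge,
                abs(mom.sigma2_e - reml.sigma2_e) / mom.sigma2_e,
            ]
        )
    assert (np.median(diffs, axis=0) < 0.10).all()


def test_blup_zero_noise_equals_centered_interaction():
    table = synthetic_index_table(g=8, e=4, r=2, sigma_g=1.0, sigma_ge=2.0,
                                  sigma_e=0.0, seed=4)
    blup = fit_blup(table, "GY", method="mom")
    y = table.data.pivot_table(index="genotype", columns="env",
                               values="value")
    centered = (
        y
        - y.mean(axis=1).to_numpy()[:, None]
        - y.mean(axis=0).to_numpy()[None, :]
        + y.to_numpy().mean()
    )
    assert np.allclose(blup.ge_matrix, centered, atol=1e-10)


def test_blup_shrinkage_never_exceeds_raw_effect():
    table = synthetic_index_table(g=12, e=6, r=3, sigma_g=1.0,
                                  sigma_ge=0.5, sigma_e=1.0, seed=5)
    blup = fit_blup(table, "GY")
    y = table.data.pivot_table(index="genotype", columns="env",
                               values="value")
    raw = y.mean(axis=1) - y.to_numpy().mean()
    assert (blup.genotype_effects.abs() <= raw.abs() + 1e-12).all()
    assert abs(blup.genotype_effects.sum()) < 1e-8
    assert blup.ge_matrix.shape == (12, 6)


def test_blup_all_equal_genotypes_shrinks_to_zero():
    table = synthetic_index_table(g=6, e=4, r=3, sigma_g=0.0, sigma_ge=0.0,
                                  sigma_e=1.0, seed=6)
    blup = fit_blup(table, "GY")
    # no genetic signal: estimated sigma2_g ~ 0, effects fully shrunk
    assert blup.genotype_effects.abs().max() < 0.2
    table0 = synthetic_index_table(g=6, e=4, r=3, sigma_g=0.0,
                                   sigma_ge=0.0, sigma_e=0.0, seed=6)
    blup0 = fit_blup(table0, "GY")
    assert blup0.genotype_effects.abs().max() < 1e-8


def test_blup_recovers_planted_rank_one_interaction():
    rng = np.random.default_rng(7)
    g, e, r = 50, 6, 3
    u = rng.standard_normal(g)
    u -= u.mean()
    v = rng.standard_normal(e)
    v -= v.mean()
    planted = np.outer(u, v) / np.linalg.norm(np.outer(u, v)) * 30.0
    gens = [f"G{i:02d}" for i in range(g)]
    envs = [f"E{j + 1}" for j in range(e)]
    y = 10.0 + planted[:, :, None] + rng.normal(0, 1.0, (g, e, r))
    idx = pd.MultiIndex.from_product(
        [gens, envs, range(1, r + 1)], names=["genotype", "env", "rep"]
    )
    df = pd.DataFrame({"value": y.ravel()}, index=idx).reset_index()
    df["trait"] = "GY"
    from metsel.indices import IndexTable

    table = IndexTable(df[["genotype", "env", "rep", "trait", "value"]],
                       {env: ("drought", "S1") for env in envs})
    blup = fit_blup(table, "GY")
    corr = np.corrcoef(blup.ge_matrix.to_numpy().ravel(),
                       planted.ravel())[0, 1]
    assert corr > 0.9


def test_pretests_normal_residuals_rarely_rejected():
    passed = 0
    for seed in range(100):
        table = synthetic_index_table(g=10, e=6, r=3, sigma_g=1.0,
                                      sigma_e=1.0, seed=4000 + seed)
        sw_p, _ = pretests(table, "GY")
        passed += sw_p > 0.05
    assert passed >= 90


def test_pretests_bartlett_detects_heteroscedastic_environment():
    table = synthetic_index_table(g=20, e=6, r=3, sigma_e=1.0, seed=8)
    data = table.data.copy()
    mask = data["env"] == "E1"
    mu = data.loc[mask, "value"].mean()
    data.loc[mask, "value"] = mu + (data.loc[mask, "value"] - mu) * np.sqrt(10)
    from metsel.indices import IndexTable

    noisy = IndexTable(data, table.env_map)
    _, bart_p = pretests(noisy, "GY")
    assert bart_p < 0.01


def test_pretests_identical_environment_variances():
    table = synthetic_index_table(g=6, e=3, r=2, sigma_e=1.0, seed=9)
    data = table.data.copy()
    # make every environment an exact copy of E1's values
    e1 = data[data["env"] == "E1"]["value"].to_numpy()
    for env in ("E2", "E3"):
        data.loc[data["env"] == env, "value"] = e1
    from metsel.indices import IndexTable

    _, bart_p = pretests(IndexTable(data, table.env_map), "GY")
    assert bart_p == 1.0


def test_model_results_summary_runs():
    table = synthetic_index_table(g=8, e=4, r=3, sigma_g=1.0, sigma_ge=0.5,
                                  sigma_e=1.0, seed=10)
    res = JointANOVA(table, "GY").fit()
    text = res.summary()
    assert "Variance components" in text and "GEN:ENV" in text
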
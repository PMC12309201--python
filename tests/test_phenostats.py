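"""Heritability, ANOVA, loss, Tukey letters, Spearman, QY ratio."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenometab import phenostats
from phenometab.phenostats import (
    VarianceComponents,
    anova_gxt,
    cross_experiment_spearman,
    fit_variance_components,
    heritability,
    loss_of_trait,
    onset_day,
    qy_ratio,
    tukey_letters,
    tukey_letters_from_data,
)


# ---- variance components / heritability ----------------------------------

def _sim_vc_table(rng, n_geno=50, e=2, r=5, s2g=2.0, s2gxe=1.0, s2E=4.0):
    g = rng.normal(0, np.sqrt(s2g), n_geno)
    ge = rng.normal(0, np.sqrt(s2gxe), (n_geno, e))
    rows = []
    for gi in range(n_geno):
        for ei in range(e):
            vals = g[gi] + ge[gi, ei] + rng.normal(0, np.sqrt(s2E), r)
            rows += [{"genotype": f"g{gi}", "experiment": f"e{ei}", "value": v}
                     for v in vals]
    return pd.DataFrame(rows)


def test_all_equal_observations_give_zero_components():
    df = pd.DataFrame({
        "genotype": ["a", "a", "b", "b"] * 2,
        "experiment": ["e1"] * 4 + ["e2"] * 4,
        "value": 3.0,
    })
    vc = fit_variance_components(df)
    assert vc.sigma2_g == pytest.approx(0.0, abs=1e-12)
    assert vc.sigma2_gxe == pytest.approx(0.0, abs=1e-12)
    assert vc.sigma2_E == pytest.approx(0.0, abs=1e-12)


def test_pure_genotype_effect_zero_noise():
    df = pd.DataFrame([
        {"genotype": g, "experiment": e, "value": {"a": 1.0, "b": 5.0}[g]}
        for g in "ab" for e in ("e1", "e2") for _ in range(4)
    ])
    vc = fit_variance_components(df)
    assert vc.sigma2_E == pytest.approx(0.0)
    assert vc.sigma2_g > 0


def test_component_recovery_by_simulation():
    """Method-of-moments estimates are unbiased under the generating model
    (calibrated by simulating the two-way random-effects model itself)."""
    rng = np.random.default_rng(0)
    est = np.array([
        (lambda vc: (vc.sigma2_g, vc.sigma2_gxe, vc.sigma2_E))(
            fit_variance_components(_sim_vc_table(rng)))
        for _ in range(60)
    ])
    truth = np.array([2.0, 1.0, 4.0])
    assert np.all(np.abs(est.mean(axis=0) - truth) / truth < 0.15)


def test_single_experiment_warns_and_zeroes_gxe():
    df = _sim_vc_table(np.random.default_rng(1), n_geno=10, e=1)
    with pytest.warns(UserWarning):
        vc = fit_variance_components(df)
    assert vc.sigma2_gxe == 0.0
    assert vc.e == 1


@pytest.mark.parametrize("vc,expected", [
    (VarianceComponents(0.0, 1.0, 2.0, 2, 5), 0.0),
    (VarianceComponents(3.0, 0.0, 0.0, 2, 5), 1.0),
    (VarianceComponents(2.0, 1.0, 4.0, 2, 5), 2.0 / (2.0 + 0.5 + 0.4)),
])
def test_heritability_formula(vc, expected):
    assert heritability(vc) == pytest.approx(expected, abs=1e-15)


def test_heritability_undefined_for_zero_components():
    with pytest.raises(ValueError):
        heritability(VarianceComponents(0.0, 0.0, 0.0, 2, 5))


def test_heritability_scale_invariant():
    rng = np.random.default_rng(2)
    df = _sim_vc_table(rng, n_geno=20)
    h1 = heritability(fit_variance_components(df))
    df2 = df.assign(value=df["value"] * 7.3)
    h2 = heritability(fit_variance_components(df2))
    assert h1 == pytest.approx(h2, rel=1e-10)


# ---- loss of trait --------------------------------------------------------

@pytest.mark.parametrize("d,c,expected", [
    (5.0, 5.0, 0.0),
    (0.0, 4.0, 100.0),
    (37.6, 100.0, 62.4),
    (120.0, 100.0, -20.0),
])
def test_loss_of_trait(d, c, expected):
    assert loss_of_trait(d, c) == pytest.approx(expected)


def test_loss_of_trait_zero_control_raises():
    with pytest.raises(ValueError):
        loss_of_trait(1.0, 0.0)


# ---- two-way ANOVA ---------------------------------------------------------

def _balanced_2x2():
    # 2 genotypes x 2 treatments x 3 replicates, hand-checkable numbers
    data = {
        ("g1", "c"): [10.0, 11.0, 12.0],
        ("g1", "d"): [7.0, 8.0, 9.0],
        ("g2", "c"): [14.0, 15.0, 16.0],
        ("g2", "d"): [9.0, 10.0, 11.0],
    }
    rows = [{"genotype": g, "treatment": t, "value": v}
            for (g, t), vals in data.items() for v in vals]
    return pd.DataFrame(rows), data


def test_anova_matches_hand_computed_sums_of_squares():
    df, data = _balanced_2x2()
    res = anova_gxt(df)
    # independent oracle: explicit balanced two-way ANOVA arithmetic
    y = np.array([v for vals in data.values() for v in vals])
    grand = y.mean()
    cell_means = {k: np.mean(v) for k, v in data.items()}
    g_means = {g: np.mean([cell_means[(g, t)] for t in "cd"]) for g in ("g1", "g2")}
    t_means = {t: np.mean([cell_means[(g, t)] for g in ("g1", "g2")]) for t in "cd"}
    n, r = len(y), 3
    ss_g = 2 * r * sum((m - grand) ** 2 for m in g_means.values())
    ss_t = 2 * r * sum((m - grand) ** 2 for m in t_means.values())
    ss_cells = r * sum((m - grand) ** 2 for m in cell_means.values())
    ss_int = ss_cells - ss_g - ss_t
    ss_err = sum((v - cell_means[k]) ** 2 for k, vals in data.items() for v in vals)
    ms_err = ss_err / (n - 4)
    f_g, f_t, f_i = ss_g / ms_err, ss_t / ms_err, ss_int / ms_err
    assert res["F_genotype"] == pytest.approx(f_g, rel=1e-10)
    assert res["F_treatment"] == pytest.approx(f_t, rel=1e-10)
    assert res["F_interaction"] == pytest.approx(f_i, rel=1e-10)
    assert res["treatment"] == pytest.approx(stats.f.sf(f_t, 1, n - 4), rel=1e-10)


def test_anova_huge_effect_separates():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "genotype": np.repeat(["a", "b"], 30),
        "treatment": np.tile(np.repeat(["c", "d"], 15), 2),
        "value": rng.normal(0, 0.1, 60),
    })
    df.loc[df["treatment"] == "d", "value"] += 100.0
    assert anova_gxt(df)["treatment"] < 1e-10


def test_anova_requires_two_levels_and_full_cells():
    df = pd.DataFrame({"genotype": ["a"] * 4, "treatment": list("ccdd"),
                       "value": [1.0, 2, 3, 4]})
    with pytest.raises(ValueError):
        anova_gxt(df)
    df2 = pd.DataFrame({"genotype": list("aabb"), "treatment": list("cdcc"),
                        "value": [1.0, 2, 3, 4]})
    with pytest.raises(ValueError):
        anova_gxt(df2)


# ---- onset day -------------------------------------------------------------

def test_onset_day_alpha_one_returns_first_day(default_study):
    _, _, _, series, _ = default_study
    assert onset_day(series, alpha=1.0) == int(series["day"].min())


def test_onset_day_detects_divergence(default_study):
    cfg, _, _, series, _ = default_study
    day = onset_day(series, alpha=0.05)
    assert day is not None
    assert abs(day - cfg.onset_day) <= 1


# ---- Tukey compact letter display -------------------------------------------

def test_tukey_identical_groups_share_letter():
    letters = tukey_letters({"a": 5.0, "b": 5.0}, {"a": 5, "b": 5},
                            mse=1.0, df_resid=8, alpha=0.01)
    assert letters["a"] == letters["b"]


def test_tukey_separated_group_gets_own_letter():
    letters = tukey_letters({"g1": 0.0, "g2": 0.0, "g3": 100.0},
                            {"g1": 5, "g2": 5, "g3": 5},
                            mse=1e-4, df_resid=12, alpha=0.01)
    assert letters["g1"] == letters["g2"]
    assert set(letters["g3"]) != set(letters["g1"])


def test_tukey_alpha_zero_limit_all_share():
    letters = tukey_letters({"a": 0.0, "b": 50.0, "c": 100.0},
                            {"a": 3, "b": 3, "c": 3},
                            mse=1.0, df_resid=6, alpha=1e-12)
    assert letters["a"] == letters["b"] == letters["c"]


def test_tukey_letter_sharing_matches_pairwise_hsd():
    """Letter sharing reproduces the pairwise studentized-range decisions
    (oracle: scipy.stats.tukey_hsd on the raw data)."""
    rng = np.random.default_rng(5)
    groups = {f"g{i}": rng.normal(mu, 1.0, 8)
              for i, mu in enumerate([0.0, 0.5, 3.0, 3.2, 8.0])}
    table = pd.DataFrame([
        {"group": g, "value": v} for g, vals in groups.items() for v in vals
    ])
    alpha = 0.05
    letters = tukey_letters_from_data(table, group="group", alpha=alpha)
    res = stats.tukey_hsd(*groups.values())
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            share = bool(set(letters[names[i]]) & set(letters[names[j]]))
            not_significant = res.pvalue[i, j] >= alpha
            assert share == not_significant, (names[i], names[j])


def test_tukey_single_group():
    assert tukey_letters({"only": 1.0}, {"only": 4}, 1.0, 3) == {"only": "a"}


# ---- Spearman and QY ratio ---------------------------------------------------

def test_cross_experiment_spearman_values():
    a = pd.Series([1.0, 2, 3, 4], index=list("wxyz"))
    assert cross_experiment_spearman(a, a) == pytest.approx(1.0)
    assert cross_experiment_spearman(a, a.iloc[::-1].set_axis(a.index)) == pytest.approx(-1.0)
    b = pd.Series([2.0, 1, 4, 3], index=list("wxyz"))
    # hand-derived: d^2 = 4 -> rho = 1 - 6*4/(4*15) = 0.6
    assert cross_experiment_spearman(a, b) == pytest.approx(0.6)


def test_cross_experiment_spearman_needs_three_pairs():
    a = pd.Series([1.0, 2], index=["x", "y"])
    with pytest.raises(ValueError):
        cross_experiment_spearman(a, a)


def test_qy_ratio():
    assert qy_ratio(0.5, 0.5) == 1.0
    assert qy_ratio(0.4, 0.8) == 0.5
    with pytest.raises(ValueError):
        qy_ratio(0.4, 0.0)


def test_loss_table(default_study):
    _, _, _, _, post = default_study
    losses = phenostats.loss_table(post)
    assert {"genotype", "trait", "loss_percent"} <= set(losses.columns)
    bio = losses[losses["trait"] == "Biomass22"]["loss_percent"]
    assert (bio > 20).all()  # drought reduces biomass for every genotype
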
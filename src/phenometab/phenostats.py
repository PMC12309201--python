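"""Phenotype statistics: heritability, ANOVA, trait loss, Tukey letters.

Broad-sense heritability across experiments uses the variance-component form

    H2 = sigma2_g / (sigma2_g + sigma2_gxe / e + sigma2_E / (r * e))

with sigma2_g the genetic variance, sigma2_gxe the genotype-by-experiment
interaction, sigma2_E the error variance, e the number of experiments and r
the number of replicates. Components are estimated by equating two-way ANOVA
mean squares to their expectations (method of moments); negative estimates
are truncated at zero.

Trait stability under drought is summarized by the relative loss

    loss[%] = 100 * (1 - trait_drought / trait_control).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_gxe: float
    sigma2_E: float
    e: int
    r: float

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_gxe, self.sigma2_E) < 0:
            raise ValueError("variance components must be non-negative")
        if self.e < 1 or self.r < 1:
            raise ValueError("e and r must be >= 1")


@dataclass
class LossRecord:
    genotype: str
    trait: str
    loss_percent: float


def fit_variance_components(table: pd.DataFrame, value: str = "value",
                            genotype: str = "genotype",
                            experiment: str = "experiment") -> VarianceComponents:
    """Method-of-moments components from a genotype x experiment layout.

    Expected mean squares of the balanced two-way random model with r
    replicates per cell:

        E[MS_error] = s2E
        E[MS_GxE]   = s2E + r * s2gxe
        E[MS_G]     = s2E + r * s2gxe + r * e * s2g

    For near-balanced data r is the harmonic mean cell size. With a single
    experiment the interaction is inestimable and returned as 0.
    """
    df = table[[genotype, experiment, value]].dropna().copy()
    g_levels = df[genotype].unique()
    e_levels = df[experiment].unique()
    n_g, n_e = len(g_levels), len(e_levels)
    if n_g < 2:
        raise ValueError("need >= 2 genotypes")
    cell_sizes = df.groupby([genotype, experiment])[value].size()
    r_h = stats.hmean(cell_sizes.to_numpy())

    if n_e < 2:
        warnings.warn("single experiment: sigma2_gxe set to 0", stacklevel=2)
        grand = df[value].mean()
        means = df.groupby(genotype)[value].mean()
        counts = df.groupby(genotype)[value].size()
        ss_g = float((counts * (means - grand) ** 2).sum())
        ms_g = ss_g / (n_g - 1)
        ss_e = float(((df[value] - df[genotype].map(means)) ** 2).sum())
        dfe = len(df) - n_g
        ms_err = ss_e / dfe if dfe > 0 else 0.0
        s2g = max((ms_g - ms_err) / r_h, 0.0)
        return VarianceComponents(s2g, 0.0, ms_err, 1, r_h)

    model = smf.ols(
        f"{value} ~ C({genotype}) * C({experiment})", data=df
    ).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ms = aov["sum_sq"] / aov["df"]
    ms_g = float(ms[f"C({genotype})"])
    ms_ge = float(ms[f"C({genotype}):C({experiment})"])
    ms_err = float(ms["Residual"]) if aov.loc["Residual", "df"] > 0 else 0.0
    s2E = max(ms_err, 0.0)
    s2gxe = max((ms_ge - ms_err) / r_h, 0.0)
    s2g = max((ms_g - ms_ge) / (r_h * n_e), 0.0)
    return VarianceComponents(s2g, s2gxe, s2E, n_e, r_h)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability across experiments (exact formula)."""
    denom = vc.sigma2_g + vc.sigma2_gxe / vc.e + vc.sigma2_E / (vc.r * vc.e)
    if denom <= 0:
        raise ValueError("all variance components are zero: H2 undefined")
    return vc.sigma2_g / denom


def loss_of_trait(drought_mean: float, control_mean: float) -> float:
    """Relative trait loss under drought, in percent. Negative = gain."""
    if control_mean == 0:
        raise ValueError("control mean is zero: loss undefined")
    return 100.0 * (1.0 - drought_mean / control_mean)


def loss_table(post_harvest: pd.DataFrame, trait_cols: list[str] | None = None,
               ) -> pd.DataFrame:
    """Per-genotype loss of each trait (drought vs control genotype means)."""
    if trait_cols is None:
        trait_cols = [
            c for c in post_harvest.columns
            if c not in ("plant", "genotype", "treatment")
            and pd.api.types.is_numeric_dtype(post_harvest[c])
        ]
    means = post_harvest.groupby(["genotype", "treatment"])[trait_cols].mean()
    rows = []
    for geno in means.index.get_level_values(0).unique():
        for trait in trait_cols:
            try:
                c = means.loc[(geno, "control"), trait]
                d = means.loc[(geno, "drought"), trait]
            except KeyError:
                continue
            if pd.isna(c) or c == 0:
                continue
            rows.append({"genotype": geno, "trait": trait,
                         "loss_percent": loss_of_trait(d, c)})
    return pd.DataFrame(rows)


def anova_gxt(table: pd.DataFrame, value: str = "value",
              genotype: str = "genotype", treatment: str = "treatment",
              ) -> dict[str, float]:
    """Two-way fixed-effects ANOVA with interaction, Type II SS.

    Returns p-values for genotype, treatment and their interaction.
    """
    df = table[[genotype, treatment, value]].dropna()
    if df[genotype].nunique() < 2 or df[treatment].nunique() < 2:
        raise ValueError("need >= 2 levels for both factors")
    cells = df.groupby([genotype, treatment]).size()
    full_grid = df[genotype].nunique() * df[treatment].nunique()
    if len(cells) < full_grid:
        raise ValueError("empty genotype x treatment cells: interaction inestimable")
    model = smf.ols(f"{value} ~ C({genotype}) * C({treatment})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    return {
        "genotype": float(aov.loc[f"C({genotype})", "PR(>F)"]),
        "treatment": float(aov.loc[f"C({treatment})", "PR(>F)"]),
        "interaction": float(aov.loc[f"C({genotype}):C({treatment})", "PR(>F)"]),
        "F_genotype": float(aov.loc[f"C({genotype})", "F"]),
        "F_treatment": float(aov.loc[f"C({treatment})", "F"]),
        "F_interaction": float(aov.loc[f"C({genotype}):C({treatment})", "F"]),
    }


def onset_day(series: pd.DataFrame, alpha: float = 0.05,
              trait: str = "biomass") -> int | None:
    """First day whose per-day treatment effect is significant.

    Runs a two-way genotype + treatment ANOVA per day, pooling genotypes,
    and returns the first day with treatment p < alpha (None if never).
    """
    sub = series[series["trait"] == trait]
    for day in sorted(sub["day"].unique()):
        d = sub[sub["day"] == day]
        if d["treatment"].nunique() < 2:
            continue
        p = anova_gxt(d)["treatment"]
        if p < alpha:
            return int(day)
    return None


# ---------------------------------------------------------------------------
# Tukey HSD compact letter display
# ---------------------------------------------------------------------------

def tukey_pairwise_p(means: np.ndarray, ns: np.ndarray, mse: float,
                     df_resid: float) -> np.ndarray:
    """All-pairs studentized-range p-values (Tukey-Kramer for unequal n)."""
    k = means.size
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                pij = 0.0 if means[i] != means[j] else 1.0
            else:
                q = np.abs(means[i] - means[j]) / se
                pij = float(stats.studentized_range.sf(q, k, df_resid))
            p[i, j] = p[j, i] = pij
    return p


def _insert_absorb(sig: np.ndarray, order: np.ndarray) -> list[set]:
    """Insert-and-absorb letter assignment.

    ``sig[i, j]`` True means groups i and j differ significantly. Returns a
    list of letter-columns (sets of group indices); groups share a letter iff
    they are not significantly different.
    """
    columns: list[set] = [set(order)]
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            if not sig[i, j]:
                continue
            for col in list(columns):
                if i in col and j in col:
                    columns.remove(col)
                    c1, c2 = col - {j}, col - {i}
                    for c in (c1, c2):
                        if not any(c <= other for other in columns):
                            columns.append(c)
    # absorb columns contained in others
    columns = [c for c in columns if not any(c < o for o in columns)]
    return columns


def tukey_letters(means: dict, ns: dict, mse: float, df_resid: float,
                  alpha: float = 0.01) -> dict[str, str]:
    """Compact letter display from group means and a residual variance.

    Groups sharing at least one letter are not significantly different under
    the Tukey HSD test at ``alpha``.
    """
    names = list(means)
    if len(names) == 1:
        return {names[0]: "a"}
    m = np.array([means[g] for g in names], dtype=float)
    n = np.array([ns[g] for g in names], dtype=float)
    p = tukey_pairwise_p(m, n, mse, df_resid)
    sig = p < alpha
    order = np.argsort(-m, kind="stable")  # letters assigned from largest mean
    columns = _insert_absorb(sig, order)
    # order letter columns by the best (largest) mean they contain
    columns.sort(key=lambda col: min(np.argsort(-m, kind="stable").tolist().index(i)
                                     for i in col))
    letters = {g: "" for g in names}
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li) if li < 26 else f"a{li}"
        for i in sorted(col):
            letters[names[i]] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def tukey_letters_from_data(table: pd.DataFrame, value: str = "value",
                            group: str = "group", alpha: float = 0.01
                            ) -> dict[str, str]:
    """Convenience wrapper computing means/MSE from raw replicate data."""
    grp = table.groupby(group)[value]
    means = grp.mean().to_dict()
    ns = grp.size().to_dict()
    resid = table[value] - table[group].map(grp.mean())
    df_resid = len(table) - len(means)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = float((resid**2).sum() / df_resid)
    return tukey_letters(means, ns, mse, df_resid, alpha=alpha)


def cross_experiment_spearman(means_exp1: pd.Series, means_exp2: pd.Series
                              ) -> float:
    """Spearman rank correlation of paired genotype means (average ranks)."""
    joined = pd.concat([means_exp1, means_exp2], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired genotype means")
    rho, _ = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(rho)


def qy_ratio(qy_high: float, qy_low: float) -> float:
    """PSII plasticity: quantum yield under high light over low light."""
    if qy_low == 0:
        raise ValueError("qy_low is zero: ratio undefined")
    return qy_high / qy_low
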
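"""Metabolite-phenotype biomarker screening at peak stress.

Four paired genotype-level datasets are assembled from the 22 DAD slice:

* CC - metabolite intensities under control vs phenotypes under control
* DD - drought vs drought
* LC - metabolites under control vs per-genotype loss of trait
* LD - metabolites under drought vs loss of trait

The screen reports Spearman's rho (t-approximation p, BH FDR within the
dataset) and a Pearson-based R2 per feature x trait. Predictive ranking uses
leave-3-genotypes-out PLS regression: for each of 4 disjoint test folds the
model is trained on the remaining 9 genotypes with the component count chosen
by inner 4-fold cross-validated RMSEP, features are ranked by |regression
coefficient| (1 = largest), and the per-feature rank product across the 4
folds gives the final ordering (low = consistently predictive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

TAGS = ("CC", "DD", "LC", "LD")


@dataclass
class PairedDataset:
    tag: str
    X: pd.DataFrame          # genotype x feature means
    y: pd.DataFrame          # genotype x trait means (or losses)

    def __post_init__(self) -> None:
        if self.tag not in TAGS:
            raise ValueError(f"tag must be one of {TAGS}")
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must be aligned on the same genotypes")


def build_paired_datasets(metab_values: pd.DataFrame, metab_meta: pd.DataFrame,
                          phenotypes: pd.DataFrame,
                          trait_cols: list[str] | None = None,
                          ) -> dict[str, PairedDataset]:
    """Assemble the CC/DD/LC/LD genotype-mean datasets.

    ``metab_values``/``metab_meta`` is the processed 22 DAD metabolite slice
    (samples x features plus genotype/treatment metadata); ``phenotypes`` is
    a per-plant table (plant, genotype, treatment, trait columns). Genotypes
    missing from either side are dropped with the intersection retained.
    """
    if trait_cols is None:
        trait_cols = [
            c for c in phenotypes.columns
            if c not in ("plant", "genotype", "treatment")
            and pd.api.types.is_numeric_dtype(phenotypes[c])
        ]
    x_means = {
        cond: metab_values[metab_meta["treatment"] == cond]
        .groupby(metab_meta.loc[metab_meta["treatment"] == cond, "genotype"])
        .mean()
        for cond in ("control", "drought")
    }
    y_means = {
        cond: phenotypes[phenotypes["treatment"] == cond]
        .groupby("genotype")[trait_cols].mean()
        for cond in ("control", "drought")
    }
    common = sorted(
        set(x_means["control"].index) & set(x_means["drought"].index)
        & set(y_means["control"].index) & set(y_means["drought"].index)
    )
    losses = 100.0 * (1.0 - y_means["drought"].loc[common] / y_means["control"].loc[common])
    datasets = {
        "CC": PairedDataset("CC", x_means["control"].loc[common],
                            y_means["control"].loc[common]),
        "DD": PairedDataset("DD", x_means["drought"].loc[common],
                            y_means["drought"].loc[common]),
        "LC": PairedDataset("LC", x_means["control"].loc[common], losses),
        "LD": PairedDataset("LD", x_means["drought"].loc[common], losses),
    }
    return datasets


def correlate_metab_pheno(ds: PairedDataset, p_cut: float = 0.001
                          ) -> pd.DataFrame:
    """Spearman/R2 screen of every feature x trait pair in one dataset.

    BH FDR is applied within the dataset across all tested pairs. Constant
    features are skipped. R2 is the squared Pearson correlation (equivalently
    the OLS coefficient of determination of y on the single feature).
    """
    if len(ds.X) < 5:
        raise ValueError("need >= 5 genotypes for the correlation screen")
    rows = []
    for feat in ds.X.columns:
        x = ds.X[feat].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        for trait in ds.y.columns:
            yv = ds.y[trait].to_numpy(dtype=float)
            if np.std(yv) == 0:
                continue
            rho, p = stats.spearmanr(x, yv)
            r = stats.pearsonr(x, yv)[0]
            rows.append({"feature": feat, "trait": trait, "tag": ds.tag,
                         "rho": float(rho), "p": float(p), "r2": float(r**2)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p"] < p_cut
    return out


def _inner_cv_ncomp(X: np.ndarray, y: np.ndarray, ncomp_max: int,
                    inner_folds: int, rng: np.random.Generator) -> int:
    """Component count minimizing inner-CV RMSEP."""
    n = X.shape[0]
    idx = rng.permutation(n)
    folds = np.array_split(idx, inner_folds)
    best, best_rmsep = 1, np.inf
    for ncomp in range(1, ncomp_max + 1):
        sse, cnt = 0.0, 0
        for f in folds:
            train = np.setdiff1d(idx, f)
            if train.size <= ncomp:
                continue
            m = PLSRegression(n_components=ncomp, scale=False)
            m.fit(X[train], y[train])
            pred = m.predict(X[f]).ravel()
            sse += float(np.sum((y[f] - pred) ** 2))
            cnt += f.size
        if cnt == 0:
            continue
        rmsep = np.sqrt(sse / cnt)
        if rmsep < best_rmsep - 1e-12:
            best, best_rmsep = ncomp, rmsep
    return best


def plsr_rank_product(ds: PairedDataset, trait: str, fold_size: int = 3,
                      ncomp_max: int = 5, inner_folds: int = 4,
                      seed: int = 0) -> pd.DataFrame:
    """Leave-``fold_size``-genotypes-out PLSR coefficient rank product.

    Genotypes are partitioned by a seeded shuffle into disjoint test folds of
    ``fold_size``. Per fold: fit NIPALS PLS regression (centred, no
    autoscaling) on the training genotypes with the inner-CV component count,
    rank features by |coefficient| (1 = largest), and predict the held-out
    genotypes. The final ordering is ascending in the product of per-fold
    ranks. Returns a frame with per-fold ranks, the rank product, the final
    rank, and held-out predictions.
    """
    genos = list(ds.X.index)
    n = len(genos)
    if n < 2 * fold_size:
        raise ValueError("need at least two folds' worth of genotypes")
    y = ds.y[trait].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError(f"trait {trait!r} has no variance")
    X = ds.X.to_numpy(dtype=float)
    feats = list(ds.X.columns)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_folds = n // fold_size
    folds = [order[i * fold_size:(i + 1) * fold_size] for i in range(n_folds)]
    leftover = order[n_folds * fold_size:]
    if leftover.size:
        folds[-1] = np.concatenate([folds[-1], leftover])

    ranks = np.zeros((len(feats), len(folds)))
    preds = pd.Series(index=ds.X.index, dtype=float)
    for fi, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        ncomp_cap = min(ncomp_max, train.size - 1, len(feats))
        ncomp = _inner_cv_ncomp(X[train], y[train], ncomp_cap, inner_folds, rng)
        m = PLSRegression(n_components=ncomp, scale=False)
        m.fit(X[train], y[train])
        coef = np.abs(np.asarray(m.coef_).reshape(-1))
        # rank 1 = largest |coefficient|; average ranks on ties
        ranks[:, fi] = stats.rankdata(-coef, method="average")
        preds.iloc[test] = m.predict(X[test]).ravel()

    rank_product = ranks.prod(axis=1)
    final = stats.rankdata(rank_product, method="average")
    out = pd.DataFrame(
        {"feature": feats, "rank_product": rank_product, "pls_rank": final}
    )
    for fi in range(len(folds)):
        out[f"rank_fold{fi + 1}"] = ranks[:, fi]
    out = out.sort_values("pls_rank").reset_index(drop=True)
    out.attrs["predictions"] = preds
    out.attrs["trait"] = trait
    return out
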
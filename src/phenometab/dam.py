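"""Differential metabolite accumulation between conditions.

Significance comes from an equal-variance (pooled) two-sample t-test per
feature with Benjamini-Hochberg FDR control across the features of one
timepoint/contrast; effect size is the log2 fold change of the drought mean
over the control mean computed on the normalized, pre-log intensities.
Volcano gating combines FDR < alpha with |log2 FC| > fc_cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import IntensityMatrix
from .multivariate import oplsda_fit, vip_scores


@dataclass
class DamRecord:
    feature: str
    timepoint: object
    mean_drought: float
    mean_control: float
    log2_fc: float
    t_stat: float
    p: float
    fdr: float
    direction: str = "ns"


def ttest_dam(group_a: pd.DataFrame, group_b: pd.DataFrame,
              timepoint=None) -> pd.DataFrame:
    """Pooled-variance t-tests per feature (columns), BH-FDR across features.

    ``group_a`` is the drought (or numerator) group. Features with zero
    pooled variance get t=0, p=1 and a flag. Returns a tidy frame with one
    row per feature.
    """
    feats = list(group_a.columns)
    if list(group_b.columns) != feats:
        raise ValueError("both groups must share the same feature columns")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    zero_var = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    t = np.where(zero_var | ~np.isfinite(t), 0.0, t)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "feature": feats,
        "timepoint": timepoint,
        "mean_drought": a.mean(axis=0),
        "mean_control": b.mean(axis=0),
        "t_stat": t,
        "p": p,
        "fdr": fdr,
        "zero_variance": zero_var,
    })


def log2_fold_change(mean_drought: float, mean_control: float) -> float:
    """log2(drought / control) on positive pre-log normalized means."""
    if mean_drought <= 0 or mean_control <= 0:
        raise ValueError("fold change requires positive group means")
    return float(np.log2(mean_drought / mean_control))


def add_fold_changes(records: pd.DataFrame, normalized: IntensityMatrix,
                     labels: pd.Series, numerator: str = "drought",
                     denominator: str = "control") -> pd.DataFrame:
    """Attach log2 FCs computed on pre-log normalized intensities."""
    num = normalized.values.loc[labels == numerator]
    den = normalized.values.loc[labels == denominator]
    mn, md = num.mean(axis=0), den.mean(axis=0)
    out = records.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(mn / md)
    out["log2_fc"] = out["feature"].map(fc)
    return out


def classify_volcano(records: pd.DataFrame, alpha: float = 0.05,
                     fc_cut: float = 1.0) -> pd.DataFrame:
    """Direction gate: up iff fdr<alpha and log2_fc>fc_cut; down mirrored."""
    out = records.copy()
    sig = out["fdr"] < alpha
    out["direction"] = np.where(
        sig & (out["log2_fc"] > fc_cut), "up",
        np.where(sig & (out["log2_fc"] < -fc_cut), "down", "ns"),
    )
    return out


def overlap_counts(dam_sets: dict[object, set]) -> dict[tuple, int]:
    """Counts of every non-empty intersection region across the given sets.

    Keys are tuples of set labels; the value counts elements belonging to
    exactly those sets (Venn regions, 2^k - 1 of them for k sets).
    """
    labels = list(dam_sets)
    regions: dict[tuple, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(dam_sets[l] for l in combo)) if combo else set()
            outside = set.union(*(dam_sets[l] for l in labels if l not in combo),
                                set())
            regions[combo] = len(inside - outside)
    return regions


def genotype_dam(scaled: IntensityMatrix, normalized: IntensityMatrix,
                 genotype: str, alpha: float = 0.05, vip_cut: float = 1.0,
                 n_ortho: int = 1) -> pd.DataFrame:
    """Per-genotype drought-vs-control selection: t-test FDR and OPLS-DA VIP.

    Features pass when FDR < alpha AND VIP > vip_cut on the same contrast;
    the result is split by effect sign (``direction`` up/down from the sign
    of the t statistic on the scaled data).
    """
    meta = scaled.meta
    mask = (meta["genotype"] == genotype) & ~meta["is_blank"].astype(bool)
    sub = scaled.values.loc[mask]
    labels = meta.loc[mask, "treatment"]
    a = sub.loc[labels == "drought"]
    b = sub.loc[labels == "control"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"genotype {genotype}: fewer than 2 samples per group")
    rec = ttest_dam(a, b)
    model = oplsda_fit(sub.to_numpy(dtype=float),
                       (labels == "drought").to_numpy(), n_ortho=n_ortho)
    rec["vip"] = vip_scores(model)
    rec = add_fold_changes(
        rec, IntensityMatrix(normalized.values.loc[mask], meta.loc[mask]), labels
    )
    rec["selected"] = (rec["fdr"] < alpha) & (rec["vip"] > vip_cut)
    rec["direction"] = np.where(
        ~rec["selected"], "ns", np.where(rec["t_stat"] > 0, "up", "down")
    )
    return rec


def pairwise_consensus(dam_frames: list[pd.DataFrame], k: int
                       ) -> pd.DataFrame:
    """Features selected with a consistent sign in >= k of the comparisons.

    ``dam_frames`` are per-pair selection frames with ``feature``,
    ``selected`` and ``direction`` columns (e.g. four tolerant-vs-non-tolerant
    genotype contrasts). Sign-inconsistent features (up in some pairs, down
    in others) are excluded.
    """
    n = len(dam_frames)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available comparisons")
    votes: dict[str, list[str]] = {}
    for frame in dam_frames:
        sel = frame[frame["selected"]]
        for _, row in sel.iterrows():
            votes.setdefault(row["feature"], []).append(row["direction"])
    rows = []
    for feat, dirs in votes.items():
        ups, downs = dirs.count("up"), dirs.count("down")
        if ups and downs:
            continue
        count = max(ups, downs)
        if count >= k:
            rows.append({"feature": feat,
                         "direction": "up" if ups else "down",
                         "n_comparisons": count})
    return pd.DataFrame(rows, columns=["feature", "direction", "n_comparisons"])
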
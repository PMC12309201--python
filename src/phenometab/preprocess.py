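"""GC-MS metabolite preprocessing chain.

Order of operations (run independently per sampling timepoint):

raw normalization -> blank filter (>2-fold over blanks) -> presence filter
(quantified in >= 80% of samples) -> 1/5-minimum imputation -> RSD filter
(drop the 25% most variable features) -> median normalization ->
log10 transform -> Pareto scaling.

Zeros are treated as missing ("quantified" means a non-missing, positive
intensity). The RSD is computed on post-imputation, pre-normalization
intensities. Blank comparison uses means with a strict > 2-fold rule; the
presence boundary keeps features observed in exactly 80% of samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix, PreprocessReport

logger = logging.getLogger(__name__)


def _as_missing(values: pd.DataFrame) -> pd.DataFrame:
    """Zeros count as unquantified."""
    return values.mask(values == 0)


def normalize_raw(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide out per-sample fresh weight, internal-standard response and a
    multiplicative batch/detector factor.

    The batch factor is each batch's mean sample-median intensity relative to
    the grand mean, a simple correction that equalizes batch levels. Samples
    with a zero factor are excluded with a warning.
    """
    meta = matrix.meta
    values = _as_missing(matrix.values.astype(float))
    factor = pd.Series(1.0, index=values.index)
    for col in ("fresh_weight", "is_response"):
        if col in meta.columns:
            factor = factor * meta[col].astype(float)
    if "batch" in meta.columns and meta["batch"].nunique() > 1:
        sample_med = values.median(axis=1, skipna=True)
        batch_mean = sample_med.groupby(meta["batch"]).transform("mean")
        factor = factor * (batch_mean / sample_med.mean())
    bad = (factor == 0) | factor.isna()
    if bad.any():
        logger.warning("excluding %d samples with zero normalization factor",
                       int(bad.sum()))
    keep = ~bad
    out = values.loc[keep].div(factor.loc[keep], axis=0)
    return IntensityMatrix(out, meta.loc[keep])


def blank_filter(matrix: IntensityMatrix) -> tuple[IntensityMatrix, PreprocessReport]:
    """Keep features whose mean leaf intensity exceeds 2x the blank mean.

    Features absent from all blanks are always kept. Without blank samples
    the step is skipped (logged).
    """
    report = PreprocessReport()
    leaf = matrix.biological()
    blanks = matrix.blanks()
    if blanks.n_samples == 0:
        logger.warning("no blank samples: blank filter skipped")
        report.add("blank_filter", matrix.n_features, [], {"skipped": True})
        return leaf, report
    leaf_mean = _as_missing(leaf.values).mean(axis=0, skipna=True)
    blank_mean = _as_missing(blanks.values).mean(axis=0, skipna=True)
    keep = blank_mean.isna() | (leaf_mean > 2.0 * blank_mean)
    removed = [f for f, k in keep.items() if not k]
    report.add("blank_filter", matrix.n_features, removed, {"fold": 2.0})
    return leaf.subset_features([f for f in leaf.feature_ids if keep[f]]), report


def presence_filter(matrix: IntensityMatrix, min_frac: float = 0.8,
                    report: PreprocessReport | None = None
                    ) -> tuple[IntensityMatrix, PreprocessReport]:
    """Keep features quantified in at least ``min_frac`` of samples."""
    report = report if report is not None else PreprocessReport()
    obs = _as_missing(matrix.values).notna().mean(axis=0)
    keep = obs >= min_frac
    removed = [f for f, k in keep.items() if not k]
    report.add("presence_filter", matrix.n_features, removed,
               {"min_frac": min_frac})
    return matrix.subset_features([f for f in matrix.feature_ids if keep[f]]), report


def impute_min_fraction(matrix: IntensityMatrix, frac: float = 0.2
                        ) -> IntensityMatrix:
    """Replace missing entries by ``frac`` x the feature's minimum observed
    value (column-wise over the processed slice)."""
    values = _as_missing(matrix.values.astype(float))
    col_min = values.min(axis=0, skipna=True)
    if col_min.isna().any():
        bad = list(col_min.index[col_min.isna()])
        raise ValueError(f"features with no observed values cannot be imputed: {bad}")
    out = values.fillna(col_min * frac)
    return IntensityMatrix(out, matrix.meta)


def rsd_filter(matrix: IntensityMatrix, top_frac: float = 0.25,
               report: PreprocessReport | None = None
               ) -> tuple[IntensityMatrix, PreprocessReport]:
    """Drop the ``floor(n * top_frac)`` features with the highest RSD.

    RSD = sd/mean on current intensities; a zero mean maps to +inf (removed
    first). Ties break by feature ID order for determinism.
    """
    report = report if report is not None else PreprocessReport()
    n_drop = int(np.floor(matrix.n_features * top_frac))
    values = matrix.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = (sd / mean).where(mean != 0, np.inf)
    order = sorted(matrix.feature_ids, key=lambda f: (-rsd[f], f))
    removed = order[:n_drop]
    report.add("rsd_filter", matrix.n_features, removed, {"top_frac": top_frac})
    keep = [f for f in matrix.feature_ids if f not in set(removed)]
    return matrix.subset_features(keep), report


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide each sample by its own median intensity."""
    med = matrix.values.median(axis=1, skipna=True)
    if (med == 0).any():
        bad = list(med.index[med == 0])
        raise ValueError(f"samples with zero median cannot be normalized: {bad}")
    out = matrix.values.div(med, axis=0)
    return IntensityMatrix(out, matrix.meta)


def log10_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log10; any non-positive cell is an error."""
    arr = matrix.values.to_numpy(dtype=float)
    bad = ~(arr > 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            "non-positive intensity at sample "
            f"{matrix.values.index[i]!r}, feature {matrix.values.columns[j]!r}"
        )
    return IntensityMatrix(np.log10(matrix.values), matrix.meta)


def pareto_scale(matrix: IntensityMatrix) -> IntensityMatrix:
    """Per-feature centring and division by sqrt(sd) (sample sd, n-1).

    Constant features are left centred (all zeros) and logged; the Pareto
    identity post-variance == pre-sd holds for every non-constant feature.
    """
    if matrix.n_samples < 2:
        raise ValueError("Pareto scaling needs >= 2 samples")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    centred = matrix.values.sub(mean, axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning("constant features left centred: %s",
                       list(sd.index[zero]))
    scale = np.sqrt(sd.where(~zero, 1.0))
    return IntensityMatrix(centred.div(scale, axis=1), matrix.meta)


def row_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Per-feature z-score across samples (heatmap/row-normalized form).

    Note: rows in the display convention are features; constant features map
    to zeros.
    """
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    out = matrix.values.sub(mean, axis=1).div(sd.where(sd != 0, 1.0), axis=1)
    return IntensityMatrix(out, matrix.meta)


def preprocess_timepoint(matrix: IntensityMatrix, min_frac: float = 0.8,
                         impute_frac: float = 0.2, rsd_top_frac: float = 0.25,
                         ) -> tuple[IntensityMatrix, IntensityMatrix, PreprocessReport]:
    """Full chain for one timepoint slice.

    Returns ``(scaled, normalized, report)`` where ``scaled`` is the
    median-normalized/log10/Pareto matrix used by multivariate models and
    ``normalized`` is the pre-log median-normalized matrix used for fold
    changes.
    """
    m, report = blank_filter(matrix)
    m, report = presence_filter(m, min_frac=min_frac, report=report)
    m = impute_min_fraction(m, frac=impute_frac)
    m, report = rsd_filter(m, top_frac=rsd_top_frac, report=report)
    normalized = median_normalize(m)
    scaled = pareto_scale(log10_transform(normalized))
    report.validate()
    return scaled, normalized, report


def preprocess_pipeline(matrix: IntensityMatrix, min_frac: float = 0.8,
                        impute_frac: float = 0.2, rsd_top_frac: float = 0.25,
                        ) -> dict:
    """Run the chain independently per sampling timepoint.

    Returns ``{timepoint: (scaled, normalized, report)}``.
    """
    out = {}
    for tp in sorted(matrix.meta["timepoint"].unique()):
        out[tp] = preprocess_timepoint(
            matrix.at_timepoint(tp), min_frac=min_frac,
            impute_frac=impute_frac, rsd_top_frac=rsd_top_frac,
        )
    return out
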
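"""Outlier removal for image-based phenotype time series.

Mirrors the imaging-trait cleaning rules of automated phenotyping pipelines:

1. per plant x trait, a local-regression confidence band flags single-day
   outliers; the flag-exclude-refit cycle is run for a configurable number of
   rounds so that a large spike cannot mask a second one;
2. per genotype x trait x day x treatment cell, values beyond ``sd_k`` sample
   standard deviations of the cell mean are excluded;
3. plant x trait series with more than a fraction ``drop_fraction`` of their
   days flagged are dropped entirely for that trait.

Filtering is restricted to days up to ``last_qc_day``: the rewatering phase
produces genuine sudden changes that must not be mistaken for outliers.

The local fit is a leave-one-out local quadratic with tricube weights over
the ``nn_span`` nearest neighbours, robustified by an L1 (least absolute
deviations) reweighting stage so that a second outlier inside the
neighbourhood cannot drag the prediction. Strictly positive series are fit
on the log scale (growth-trait noise is multiplicative) and residuals taken
on the relative scale. The noise scale is pooled across all plants of the
same trait (imaging noise is instrument-driven, so plants share it), using
a leverage-standardized trimmed RMS that outliers cannot inflate; a point
is flagged when its residual exceeds ``conf_int_size`` times that scale,
removing the worst point and refitting until the band is clean, for
``rounds`` cumulative rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_DAYS = 6  # series shorter than this are skipped, never an error


@dataclass
class QcParams:
    """Tuning of the time-series flagger.

    Defaults follow common practice for image-derived traits
    (``conf_int_size=5``, span 0.5); biomass, being noisier, conventionally
    uses a wider band (7) and span 0.55.
    """

    conf_int_size: float = 5.0
    nn_span: float = 0.5
    rounds: int = 2
    sd_k: float = 2.0
    drop_fraction: float = 0.20
    last_qc_day: int = 22
    #: fit strictly positive series on the log scale (variance-stabilizing
    #: for size traits with multiplicative noise); mixed-sign series are
    #: always fit on the raw scale
    log_scale: bool = True

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.sd_k <= 0 or self.conf_int_size <= 0:
            raise ValueError("sd_k and conf_int_size must be positive")
        if not (0 < self.nn_span <= 1):
            raise ValueError("nn_span must lie in (0, 1]")
        if not (0 < self.drop_fraction < 1):
            raise ValueError("drop_fraction must lie in (0, 1)")


@dataclass
class QcFlags:
    """Cumulative QC flags with per-point reasons."""

    flagged_points: set = field(default_factory=set)  # (plant, day, trait)
    dropped_plant_traits: set = field(default_factory=set)  # (plant, trait)
    reasons: dict = field(default_factory=dict)  # (plant, day, trait) -> reason

    def add(self, plant, day, trait, reason: str) -> None:
        key = (plant, int(day), trait)
        if key not in self.flagged_points:
            self.flagged_points.add(key)
            self.reasons[key] = reason

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"plant": p, "day": d, "trait": t, "reason": self.reasons[(p, d, t)]}
            for (p, d, t) in sorted(self.flagged_points)
        ]
        return pd.DataFrame(rows, columns=["plant", "day", "trait", "reason"])


def local_polynomial_fit(days: np.ndarray, values: np.ndarray, span: float,
                         degree: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Robust leave-one-out local polynomial predictions, tricube weights.

    For each point i, fit a weighted polynomial (default quadratic, which
    tracks sigmoidal growth without curvature bias) to the ``ceil(span*n)``
    nearest neighbours of day_i, excluding i itself, and predict at day_i.
    The fit is robustified by an L1 (least absolute deviations) IRLS stage
    followed by a hard trim of neighbours beyond 4 x MAD, so a gross
    outlier inside the neighbourhood cannot drag the prediction.

    Returns ``(pred, vfac)`` where ``vfac[i]`` is the prediction-variance
    factor of the final weighted fit (Var[pred_i] = vfac[i] * sigma^2),
    used to leverage-standardize residuals for noise-scale estimation.
    """
    n = days.size
    k = max(degree + 2, int(np.ceil(span * n)))
    pred = np.empty(n)
    vfac = np.empty(n)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        dist = np.abs(days[others] - days[i])
        order = np.argsort(dist, kind="stable")
        nb = others[order[:k]]
        d = np.abs(days[nb] - days[i])
        dmax = d.max() * 1.0001 if d.max() > 0 else 1.0
        w = (1 - (d / dmax) ** 3) ** 3
        t = days[nb] - days[i]
        X = np.vander(t, degree + 1, increasing=True)
        y = values[nb]
        wi = w.copy()
        beta = np.zeros(degree + 1)
        for _ in range(4):  # IRLS towards the weighted L1 fit
            W = np.sqrt(wi)
            beta, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
            resid = y - X @ beta
            s0 = np.median(np.abs(resid))
            if s0 == 0:
                break
            wi = w / np.maximum(np.abs(resid), 0.1 * s0)
        resid = y - X @ beta
        mad = 1.4826 * np.median(np.abs(resid))
        wf = w.copy()
        if mad > 0:
            keep = np.abs(resid) <= 4.0 * mad
            if keep.sum() >= degree + 2:
                wf = w * keep
        W = np.sqrt(wf)
        beta, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
        pred[i] = beta[0]
        XtW = X.T * wf
        try:
            a_inv = np.linalg.inv(XtW @ X)
            vfac[i] = max(float((a_inv @ (X.T * wf**2) @ X @ a_inv)[0, 0]), 0.0)
        except np.linalg.LinAlgError:
            vfac[i] = 1.0
    return pred, vfac


def robust_noise_scale(values: np.ndarray) -> float:
    """Trend-robust noise sd from second differences of an ordered series.

    Pseudo-residuals e_j = (y_{j-1} - 2 y_j + y_{j+1}) / sqrt(6) cancel any
    locally linear trend; the scale is the normal-consistent 40th percentile
    of |e|, which stays clean even when several spikes contaminate up to
    ~half of the triples (each spike touches three), so outliers cannot
    mask themselves by inflating the estimate.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        return 0.0
    pseudo = (y[:-2] - 2 * y[1:-1] + y[2:]) / np.sqrt(6.0)
    # 0.5244 = 40th percentile of |Z| for standard normal Z
    return float(np.percentile(np.abs(pseudo), 40.0) / 0.5244)


#: E[z^2 | |z| below its 70th percentile] for standard normal z — the
#: consistency factor of the 30%-trimmed RMS estimator below
_TRIM_FACTOR = 0.30956


def trimmed_noise_scale(values: np.ndarray) -> float:
    """Trimmed-RMS second-difference noise sd (ordered series).

    More statistically efficient than the median-based estimator (uses the
    lowest 70% of |pseudo-residuals|), at the price of more sensitivity to
    smooth-curve curvature. Used by the synthetic spike injector, where a
    slight upward bias is harmless.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        return 0.0
    pseudo = (y[:-2] - 2 * y[1:-1] + y[2:]) / np.sqrt(6.0)
    a = np.sort(np.abs(pseudo))
    m = max(3, int(np.floor(0.7 * a.size)))
    return float(np.sqrt(np.mean(a[:m] ** 2) / _TRIM_FACTOR))


#: E[z^2 | |z| below its 75th percentile] for standard normal z: the
#: consistency constant of the 25%-trimmed RMS scale estimator
_TRIM75_FACTOR = 0.3679


def _series_residuals(st: dict, span: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LOO residuals (relative scale where applicable) of the active points."""
    idx = np.flatnonzero(st["active"])
    pred, v = local_polynomial_fit(st["days"][idx], st["work"][idx], span)
    if st["relative"]:
        resid = st["vals"][idx] / np.exp(pred) - 1.0
    else:
        resid = st["work"][idx] - pred
    return idx, resid, resid / np.sqrt(1.0 + v)


def _trimmed_rms(rstd: np.ndarray) -> float:
    a = np.sort(np.abs(rstd))
    m = max(4, int(np.floor(0.75 * a.size)))
    return float(np.sqrt(np.mean(a[:m] ** 2) / _TRIM75_FACTOR))


def detect_timeseries_outliers(series: pd.DataFrame, params: QcParams,
                               flags: QcFlags | None = None) -> QcFlags:
    """Multi-round local-fit confidence-band flagging per plant x trait.

    Only days <= ``params.last_qc_day`` are ever inspected. Series with
    fewer than six observed days are skipped with a logged warning. Flags
    accumulate; within each round the worst point beyond the band is
    removed and the series refit until the band is clean (so one spike
    cannot mask another), and the next round starts from the cleaned data.

    The noise scale of relative-residual (strictly positive) series is
    pooled per trait across plants; raw-scale series fall back to their own
    per-series scale.
    """
    flags = flags if flags is not None else QcFlags()
    sub = series[series["day"] <= params.last_qc_day]
    state: dict[tuple, dict] = {}
    for (plant, trait), grp in sub.groupby(["plant", "trait"], sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=float)
        vals = grp["value"].to_numpy(dtype=float)
        if days.size < MIN_DAYS:
            logger.warning("series %s/%s has %d days (<%d): skipped",
                           plant, trait, days.size, MIN_DAYS)
            continue
        relative = params.log_scale and bool((vals > 0).all())
        state[(plant, trait)] = {
            "days": days, "vals": vals,
            "work": np.log(vals) if relative else vals,
            "relative": relative,
            "active": np.ones(days.size, dtype=bool),
        }

    for rnd in range(params.rounds):
        cache = {}
        for key, st in state.items():
            if st["active"].sum() >= MIN_DAYS:
                cache[key] = _series_residuals(st, params.nn_span)
        # pooled per-trait scale over relative series
        pooled: dict[str, float] = {}
        for trait in {k[1] for k in cache}:
            rstd_all = np.concatenate([
                cache[k][2] for k in cache if k[1] == trait and state[k]["relative"]
            ] or [np.empty(0)])
            if rstd_all.size >= MIN_DAYS:
                pooled[trait] = _trimmed_rms(rstd_all)

        any_flag = False
        for (plant, trait), st in state.items():
            if (plant, trait) not in cache:
                continue
            idx, resid, rstd = cache[(plant, trait)]
            for _ in range(idx.size):  # peel worst-first until clean
                if idx.size < MIN_DAYS:
                    break
                if st["relative"] and trait in pooled:
                    scale = pooled[trait]
                else:
                    scale = _trimmed_rms(rstd)
                stat = np.abs(resid)
                # numerically-zero scales (constant/noise-free series) fall
                # through to the deterministic branch
                floor = 1e-12 * max(1.0, float(np.max(stat)) if stat.size else 1.0)
                if scale > floor:
                    over = stat > params.conf_int_size * scale
                    j = int(np.argmax(stat)) if over.any() else -1
                else:
                    # noise-free series: trust only the maximum deviation
                    tol = 1e-10 * max(float(np.max(np.abs(st["work"]))), 1.0)
                    j = int(np.argmax(stat)) if np.max(stat) > tol else -1
                if j < 0:
                    break
                flags.add(plant, st["days"][idx[j]], trait,
                          f"local_fit_round{rnd + 1}")
                st["active"][idx[j]] = False
                any_flag = True
                if st["active"].sum() < MIN_DAYS:
                    break
                idx, resid, rstd = _series_residuals(st, params.nn_span)
        if not any_flag:
            break
    return flags


def filter_group_sd(series: pd.DataFrame, sd_k: float = 2.0,
                    flags: QcFlags | None = None,
                    group_cols=("genotype", "trait", "day", "treatment"),
                    ) -> QcFlags:
    """Flag values beyond ``sd_k`` sample SDs of their cell mean.

    The cell is genotype x trait x day x treatment; cells with fewer than
    three values are left untouched (logged). Mean and sd are computed on
    this step's own inputs, ignoring flags from other steps.
    """
    flags = flags if flags is not None else QcFlags()
    for key, grp in series.groupby(list(group_cols), sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        if vals.size < 3:
            logger.info("cell %s has %d values (<3): no SD filtering", key, vals.size)
            continue
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0:
            continue
        bad = np.abs(vals - mu) > sd_k * sd
        for _, row in grp[bad].iterrows():
            flags.add(row["plant"], row["day"], row["trait"], "group_sd")
    return flags


def drop_plants_by_flag_fraction(flags: QcFlags, series: pd.DataFrame,
                                 threshold: float = 0.20,
                                 last_qc_day: int = 22) -> QcFlags:
    """Drop plant x trait pairs with flag fraction strictly above threshold.

    Fractions are computed over the observed days <= ``last_qc_day``.
    """
    sub = series[series["day"] <= last_qc_day]
    n_days = sub.groupby(["plant", "trait"])["day"].nunique()
    counts: dict[tuple, int] = {}
    for (plant, day, trait) in flags.flagged_points:
        if day <= last_qc_day:
            counts[(plant, trait)] = counts.get((plant, trait), 0) + 1
    for (plant, trait), n_flag in counts.items():
        total = n_days.get((plant, trait), 0)
        if total and n_flag / total > threshold:
            flags.dropped_plant_traits.add((plant, trait))
    return flags


def post_harvest_sd_filter(table: pd.DataFrame, sd_k: float = 2.0,
                           trait_cols: list[str] | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SD filter for scalar post-harvest traits.

    Grouping is genotype x treatment per trait column; filtered entries are
    set to NaN. Returns ``(filtered table, tidy flag table)``.
    """
    out = table.copy()
    if trait_cols is None:
        trait_cols = [
            c for c in table.columns
            if c not in ("plant", "genotype", "treatment")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    flag_rows = []
    for trait in trait_cols:
        for key, grp in table.groupby(["genotype", "treatment"], sort=True):
            vals = grp[trait].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() < 3:
                logger.info("post-harvest cell %s/%s too small: skipped", key, trait)
                continue
            mu = vals[ok].mean()
            sd = vals[ok].std(ddof=1)
            if sd == 0:
                continue
            bad = ok & (np.abs(vals - mu) > sd_k * sd)
            for idx in grp.index[bad]:
                out.loc[idx, trait] = np.nan
                flag_rows.append(
                    {"plant": table.loc[idx, "plant"], "trait": trait,
                     "reason": "post_harvest_sd"}
                )
    return out, pd.DataFrame(flag_rows, columns=["plant", "trait", "reason"])


def apply_flags(series: pd.DataFrame, flags: QcFlags) -> pd.DataFrame:
    """Remove flagged points and dropped plant x trait series."""
    key = list(zip(series["plant"], series["day"].astype(int), series["trait"]))
    keep = np.array([k not in flags.flagged_points for k in key])
    pt = list(zip(series["plant"], series["trait"]))
    keep &= np.array([k not in flags.dropped_plant_traits for k in pt])
    return series[keep].reset_index(drop=True)
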
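"""Synthetic study generator with a ground-truth ledger.

Emulates the structure of a twelve-genotype spring-wheat drought experiment in
a high-throughput phenotyping facility: GC-MS metabolite intensities sampled
at four timepoints (7/13/22/28 days after onset of drought, DAD) under control
and drought, daily growth curves that diverge after a configurable onset day,
and post-harvest yield traits linearly coupled to designated "causal"
metabolite markers through a latent per-genotype tolerance score.

Model summary (all effects additive on the log2-intensity scale):

``log2 x = b_f + g_{f,geno} + d_{f,t}·[drought] + eps``

where ``b_f`` is a feature baseline, ``g`` a genotype effect, ``d`` the
treatment-by-timepoint shift carried only by the designated drought-responsive
features, and ``eps`` replicate noise. Causal-marker features additionally
load on a latent genotype tolerance score ``tau`` that also drives drought
performance of post-harvest traits — the premise that makes metabolite-based
tolerance prediction recoverable by design.

Growth is three-parameter logistic per plant; under drought, growth
increments after ``onset_day`` are multiplied by a suppression factor chosen
so that genotype-average biomass loss at the end of the drought phase is
around 62%, the magnitude typical of severe early-season drought in this
design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

DEFAULT_TIMEPOINTS = (7, 13, 22, 28)
#: replicates per genotype at each sampling timepoint
DEFAULT_REPS_CONTROL = {7: 5, 13: 5, 22: 5, 28: 5}
DEFAULT_REPS_DROUGHT = {7: 5, 13: 6, 22: 7, 28: 5}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults reproduce the study design: 12 genotypes x {control, drought} x
    4 sampling timepoints with 5 control replicates throughout and 5/6/7/5
    drought replicates, ~200 metabolite features of which a configurable
    subset responds to drought.
    """

    n_genotypes: int = 12
    timepoints: tuple = DEFAULT_TIMEPOINTS
    replicates_control: dict = field(default_factory=lambda: dict(DEFAULT_REPS_CONTROL))
    replicates_drought: dict = field(default_factory=lambda: dict(DEFAULT_REPS_DROUGHT))
    n_features: int = 200
    n_drought_responsive: int = 40
    #: feature index -> {timepoint: signed log2 shift}; auto-filled if None
    effect_sizes: dict | None = None
    n_causal_markers: int = 3
    #: trait units per unit latent tolerance score
    coupling_strength: float = 1.0
    #: replicate noise sd on the log2 scale (well-behaved features)
    noise_sd: float = 0.3
    #: fraction of intrinsically noisy features (populate the RSD-filter
    #: tail, as low-abundance GC-MS peaks do) and their log2 noise sd range
    noisy_frac: float = 0.3
    noisy_sd_range: tuple = (1.3, 2.2)
    #: genotype effect sd on the log2 scale (non-causal features)
    genotype_sd: float = 0.2
    #: loading of causal markers on the latent tolerance score (log2 units)
    causal_loading: float = 0.9
    missing_rate: float = 0.05
    #: mean blank intensity (features are ~2^10 = 1024 in leaf samples)
    blank_mean: float = 50.0
    #: fraction of features contaminated in blanks (fail the 2-fold filter)
    blank_contaminated_frac: float = 0.05
    n_blanks: int = 6
    onset_day: int = 9
    n_days: int = 28
    #: relative daily measurement noise of image-derived traits
    meas_noise_sd: float = 0.03
    #: drought growth-increment multiplier after onset (calibrated for ~62%
    #: genotype-average biomass loss at end of drought, day 23)
    drought_growth_factor: float = 0.27
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_genotypes, self.n_features, self.n_drought_responsive,
            self.n_causal_markers, self.n_blanks,
        ]
        if any(c <= 0 for c in counts[:2]) or any(c < 0 for c in counts[2:]):
            raise ConfigError("counts must be positive")
        if not (0 <= self.missing_rate < 0.2):
            raise ConfigError("missing_rate must lie in [0, 0.2)")
        if self.n_drought_responsive > self.n_features:
            raise ConfigError("n_drought_responsive exceeds n_features")
        for tp in self.timepoints:
            if tp not in self.replicates_control or tp not in self.replicates_drought:
                raise ConfigError(f"replicate scheme missing timepoint {tp}")
        if any(r < 2 for r in self.replicates_control.values()):
            raise ConfigError("need >= 2 control replicates per timepoint")
        if self.effect_sizes is not None:
            if len(self.effect_sizes) != self.n_drought_responsive:
                raise ConfigError(
                    "effect_sizes must cover exactly n_drought_responsive features"
                )
        if not (0 < self.onset_day < self.n_days):
            raise ConfigError("onset_day outside the experiment's day range")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("replicates_control", "replicates_drought"):
            if key in d:
                d[key] = {int(k): int(v) for k, v in d[key].items()}
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        if d.get("effect_sizes") is not None:
            d["effect_sizes"] = {
                str(k): {int(t): float(v) for t, v in tv.items()}
                for k, tv in d["effect_sizes"].items()
            }
        return cls(**d)


@dataclass
class TruthLedger:
    """Ground truth of a simulated dataset, for recovery tests."""

    drought_responsive: dict = field(default_factory=dict)  # feature -> {tp: shift}
    causal_markers: dict = field(default_factory=dict)      # trait -> [features]
    genotype_tolerance: dict = field(default_factory=dict)  # genotype -> tau
    injected_outliers: list = field(default_factory=list)   # (plant, day, trait)
    seed: int = 0

    @property
    def drought_responsive_ids(self) -> list[str]:
        return list(self.drought_responsive)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["injected_outliers"] = [list(t) for t in self.injected_outliers]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)


def _genotype_names(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def _default_effects(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Signed per-timepoint log2 shifts for the responsive features.

    Effects ramp up towards peak stress (22 DAD) and partially persist into
    recovery (28 DAD), mirroring the temporal DAM pattern of severe
    early-season drought.
    """
    ramp = {7: 0.25, 13: 0.5, 22: 1.0, 28: 0.75}
    effects = {}
    for i in range(cfg.n_drought_responsive):
        feat = f"F{i + 1:04d}"
        sign = 1.0 if rng.random() < 0.5 else -1.0
        size = rng.uniform(1.2, 2.2)
        effects[feat] = {
            tp: sign * size * ramp.get(tp, 1.0) for tp in cfg.timepoints
        }
    return effects


def simulate_metabolome(cfg: SimConfig) -> tuple[IntensityMatrix, TruthLedger]:
    """Draw the full multi-timepoint intensity matrix plus blanks.

    Returns the raw (unnormalized, un-filtered) matrix: leaf samples with
    MCAR missingness at ``cfg.missing_rate`` and ``cfg.n_blanks`` blank
    samples per timepoint at ``cfg.blank_mean``.
    """
    rng = np.random.default_rng(cfg.seed)
    genos = _genotype_names(cfg.n_genotypes)
    feats = [f"F{i + 1:04d}" for i in range(cfg.n_features)]

    if cfg.effect_sizes is None:
        effects = _default_effects(cfg, rng)
    else:
        effects = {str(k): {int(t): float(v) for t, v in tv.items()}
                   for k, tv in cfg.effect_sizes.items()}

    # latent genotype tolerance, standardized
    tau = rng.normal(size=cfg.n_genotypes)
    tau = (tau - tau.mean()) / (tau.std() if tau.std() > 0 else 1.0)
    tolerance = dict(zip(genos, tau))

    # causal markers: last features, disjoint from the responsive block
    causal = feats[cfg.n_features - cfg.n_causal_markers:] if cfg.n_causal_markers else []

    base = rng.normal(10.0, 1.5, size=cfg.n_features)            # log2 baselines
    # intrinsically noisy features: drawn from the plain pool only, so the
    # RSD filter's tail is technical noise, not the designed signal
    designed = set(effects) | set(causal)
    plain_pool = np.array([j for j, f in enumerate(feats) if f not in designed])
    n_noisy = min(int(round(cfg.noisy_frac * cfg.n_features)), plain_pool.size)
    noisy_idx = rng.choice(plain_pool, size=n_noisy, replace=False)
    feat_noise = np.full(cfg.n_features, cfg.noise_sd)
    feat_noise[noisy_idx] = rng.uniform(*cfg.noisy_sd_range, size=n_noisy)
    geno_eff = rng.normal(0.0, cfg.genotype_sd,
                          size=(cfg.n_genotypes, cfg.n_features))
    # causal markers load on tau plus an independent residual, total genotype
    # variance ~ causal_loading^2 + (0.45)^2 on the log2 scale
    for feat in causal:
        j = feats.index(feat)
        geno_eff[:, j] = cfg.causal_loading * tau + rng.normal(0.0, 0.45, cfg.n_genotypes)

    feat_pos = {f: j for j, f in enumerate(feats)}
    rows, meta_rows = [], []
    for tp in cfg.timepoints:
        drought_shift = np.zeros(cfg.n_features)
        for feat, shifts in effects.items():
            drought_shift[feat_pos[feat]] = shifts.get(tp, 0.0)
        for treatment, reps_map in (("control", cfg.replicates_control),
                                    ("drought", cfg.replicates_drought)):
            n_rep = reps_map[tp]
            n_rows = cfg.n_genotypes * n_rep
            block = base[None, :] + np.repeat(geno_eff, n_rep, axis=0)
            if treatment == "drought":
                block = block + drought_shift[None, :]
            block = block + rng.normal(size=(n_rows, cfg.n_features)) * feat_noise
            rows.append(np.exp2(block))
            for geno in genos:
                for rep in range(1, n_rep + 1):
                    meta_rows.append(
                        dict(sample=f"{geno}_{treatment[:1].upper()}{rep}_T{tp}",
                             genotype=geno, treatment=treatment, timepoint=tp,
                             replicate=rep, is_blank=False,
                             fresh_weight=1.0, is_response=1.0, batch="B1")
                    )
        # blanks: low background, a contaminated subset near leaf level
        # (contamination hits only plain, quiet features so the designed
        # signal and the RSD tail are preserved)
        contaminated = rng.random(cfg.n_features) < cfg.blank_contaminated_frac
        quiet_plain = np.setdiff1d(plain_pool, noisy_idx)
        contaminated &= np.isin(np.arange(cfg.n_features), quiet_plain)
        for b in range(1, cfg.n_blanks + 1):
            blank = rng.gamma(4.0, cfg.blank_mean / 4.0, size=cfg.n_features)
            leafish = np.exp2(base + rng.normal(0.0, cfg.noise_sd, cfg.n_features))
            blank = np.where(contaminated, leafish, blank)
            rows.append(blank[None, :])
            meta_rows.append(
                dict(sample=f"BLANK{b}_T{tp}", genotype="blank",
                     treatment="blank", timepoint=tp, replicate=b,
                     is_blank=True, fresh_weight=1.0, is_response=1.0, batch="B1")
            )

    values = pd.DataFrame(np.vstack(rows), columns=feats,
                          index=[m["sample"] for m in meta_rows])
    meta = pd.DataFrame(meta_rows).set_index("sample")

    # MCAR missingness on leaf samples only
    if cfg.missing_rate > 0:
        leaf = ~meta["is_blank"].to_numpy()
        mask = rng.random(values.shape) < cfg.missing_rate
        mask[~leaf, :] = False
        arr = values.to_numpy()
        arr[mask] = np.nan
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)

    ledger = TruthLedger(
        drought_responsive=effects,
        causal_markers={"GrainWeight": list(causal)},
        genotype_tolerance=tolerance,
        seed=cfg.seed,
    )
    return IntensityMatrix(values, meta), ledger


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _logistic(day, A, k=0.25, t0=18.0):
    return A / (1.0 + np.exp(-k * (day - t0)))


def simulate_phenotypes(
    cfg: SimConfig,
    truth: TruthLedger,
    metab: IntensityMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plant daily growth curves and a post-harvest trait table.

    Returns ``(series, post_harvest)``. ``series`` is tidy
    (plant, genotype, treatment, day, trait, value) with traits ``biomass``
    and ``height``; drought curves diverge from control strictly after
    ``cfg.onset_day``. ``post_harvest`` carries yield traits whose drought
    performance tracks the latent tolerance score, plus the causal-coupled
    target trait built from genotype-mean causal-marker log2 intensities when
    ``metab`` is given.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genos = _genotype_names(cfg.n_genotypes)
    days = np.arange(1, cfg.n_days + 1)
    tau = truth.genotype_tolerance

    # noise partition: genotype >> plant >> daily measurement (see docs)
    geno_scale = {g: 1.0 + rng.normal(0.0, 0.15) for g in genos}
    n_plants = 10  # per genotype x treatment, tracked daily

    records = []
    plant_registry = []
    for geno in genos:
        A_g = 6.0e6 * geno_scale[geno]  # voxel-scale biomass asymptote
        rho_g = np.clip(cfg.drought_growth_factor + 0.08 * tau[geno], 0.05, 0.9)
        for treatment in ("control", "drought"):
            for p in range(1, n_plants + 1):
                plant = f"{geno}_{treatment[:1].upper()}P{p}"
                A_p = A_g * (1.0 + rng.normal(0.0, 0.06))
                ctrl = _logistic(days, A_p)
                if treatment == "drought":
                    # growth increments after onset are suppressed towards
                    # rho_g with a 1-day ramp (stomatal closure is fast but
                    # not instantaneous), keeping the curve kink-free
                    incr = np.diff(np.concatenate([[0.0], ctrl]))
                    ramp = np.where(
                        days <= cfg.onset_day, 1.0,
                        rho_g + (1.0 - rho_g) * np.exp(-(days - cfg.onset_day)),
                    )
                    curve = np.cumsum(incr * ramp)
                else:
                    curve = ctrl
                meas = curve * (1.0 + rng.normal(0.0, cfg.meas_noise_sd, size=days.size))
                hgt = 60.0 * geno_scale[geno] * (curve / A_p) ** 0.5
                hgt = hgt * (1.0 + rng.normal(0.0, cfg.meas_noise_sd, size=days.size))
                for trait, vals in (("biomass", meas), ("height", hgt)):
                    for d, v in zip(days, vals):
                        records.append((plant, geno, treatment, int(d), trait, float(v)))
                plant_registry.append((plant, geno, treatment, rho_g))

    series = pd.DataFrame(
        records, columns=["plant", "genotype", "treatment", "day", "trait", "value"]
    )

    # --- post-harvest traits -------------------------------------------
    causal_feats = truth.causal_markers.get("GrainWeight", [])
    zbar = {}
    if metab is not None and causal_feats:
        leaf = metab.biological()
        # couple at peak stress (22 DAD) when sampled, else the last timepoint
        tp = 22 if 22 in cfg.timepoints else cfg.timepoints[-1]
        sel = leaf.meta["timepoint"] == tp
        vals = np.log2(leaf.values.loc[sel, causal_feats])
        grp = vals.groupby(
            [leaf.meta.loc[sel, "genotype"], leaf.meta.loc[sel, "treatment"]]
        ).mean()
        zbar = {idx: row.to_numpy() for idx, row in grp.iterrows()}

    trait_bases = {
        "GrainNumber": 120.0, "SpikeNumber": 8.0, "TillerNumberGain": 6.0,
        "GrainWeight": 5.0, "Biomass22": 4.5e6,
    }
    ph_rows = []
    for plant, geno, treatment, rho_g in plant_registry:
        stress = 1.0 if treatment == "control" else 0.45 + 0.10 * tau[geno]
        row = {"plant": plant, "genotype": geno, "treatment": treatment}
        for trait, base_v in trait_bases.items():
            v = base_v * geno_scale[geno] * stress * (1.0 + rng.normal(0.0, 0.08))
            row[trait] = float(v)
        # causal-coupled target: linear in causal-marker log2 intensities
        key = (geno, treatment)
        if key in zbar:
            coupled = cfg.coupling_strength * float(np.sum(zbar[key]))
            row["GrainWeight"] = float(
                coupled + 0.2 * rng.normal() + (0.0 if treatment == "control" else -1.0)
            )
        ph_rows.append(row)
    post_harvest = pd.DataFrame(ph_rows)
    return series, post_harvest


def inject_outliers(
    series: pd.DataFrame,
    rate: float,
    magnitude: float,
    seed: int,
    truth: TruthLedger | None = None,
    rel_noise_sd: float | None = None,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Shift a random fraction of points by +-magnitude x local noise sd.

    When the generator's own relative measurement noise ``rel_noise_sd`` is
    supplied, the local sd at a point of a positive series is exactly
    ``rel_noise_sd * value`` (ground-truth spikes of known size). Otherwise
    the noise sd is estimated per plant x trait series with a trend-robust
    second-difference estimator, on the log scale for strictly positive
    series (growth-trait noise is multiplicative). Returns the modified
    copy and the list of injected (plant, day, trait) positions; the
    positions are also appended to ``truth.injected_outliers`` when a
    ledger is given.
    """
    from .qc import trimmed_noise_scale

    if series.empty:
        raise ValueError("cannot inject outliers into an empty series")
    if not (0 <= rate <= 0.1):
        raise ValueError("rate must lie in [0, 0.1]")
    out = series.copy()
    if rate == 0:
        return out, []
    rng = np.random.default_rng(seed)
    positions = []
    for (plant, trait), grp in out.groupby(["plant", "trait"], sort=True):
        grp = grp.sort_values("day")
        vals = grp["value"].to_numpy(dtype=float)
        if vals.size < 3:
            continue
        positive = bool((vals > 0).all())
        if rel_noise_sd is not None and positive:
            rel_sd = float(rel_noise_sd)
        elif positive:
            rel_sd = trimmed_noise_scale(np.log(vals))
        else:
            rel_sd = 0.0
        abs_sd = trimmed_noise_scale(vals)
        n_pick = rng.binomial(len(grp), rate)
        if n_pick == 0:
            continue
        pick_pos = rng.choice(len(grp), size=n_pick, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_pick)
        for ppos, sign in zip(pick_pos, signs):
            local_sd = rel_sd * vals[ppos] if positive else abs_sd
            if local_sd == 0:
                continue
            idx = grp.index[ppos]
            out.loc[idx, "value"] = vals[ppos] + sign * magnitude * local_sd
            positions.append(
                (out.loc[idx, "plant"], int(out.loc[idx, "day"]), out.loc[idx, "trait"])
            )
    if truth is not None:
        truth.injected_outliers.extend(positions)
    return out, positions
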
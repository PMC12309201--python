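"""End-to-end pipeline runner.

Stage order: simulate (when no input tables are given) -> phenotype QC ->
phenotype statistics -> metabolite preprocessing -> differential accumulation
-> multivariate models -> biomarker screen -> tolerance ranking ->
enrichment (when a pathway map is given). Every run echoes its effective
configuration and seed into the output directory; stages write tidy TSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import biomarker, dam, enrichment, phenostats, preprocess, qc, ranking, simulate
from .io import PipelineConfig, write_table
from .matrix import IntensityMatrix

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config_echo.yaml")

    # --- inputs ----------------------------------------------------------
    truth = None
    if config.metabolite_table is None:
        logger.info("stage simulate")
        cfg = simulate.SimConfig.from_dict({"seed": config.seed, **config.simulate})
        matrix, truth = simulate.simulate_metabolome(cfg)
        series, post_harvest = simulate.simulate_phenotypes(cfg, truth, matrix)
        truth.to_json(outdir / "truth_ledger.json")
        write_table(matrix.to_long(), outdir / "metabolites_raw.tsv")
        write_table(series, outdir / "phenotypes_timeseries.tsv")
        write_table(post_harvest, outdir / "post_harvest.tsv")
    else:
        from .io import read_long_table, PHENO_SCHEMA, METAB_LONG_SCHEMA, POST_HARVEST_SCHEMA
        matrix = IntensityMatrix.from_long(
            read_long_table(config.metabolite_table, METAB_LONG_SCHEMA)
        ).check_nonnegative()
        series = read_long_table(config.phenotype_table, PHENO_SCHEMA)
        post_harvest = read_long_table(config.post_harvest_table, POST_HARVEST_SCHEMA)

    # --- phenotype QC -----------------------------------------------------
    logger.info("stage qc")
    params = qc.QcParams(
        conf_int_size=config.conf_int_size, nn_span=config.nn_span,
        rounds=config.qc_rounds, sd_k=config.sd_k,
        drop_fraction=config.drop_fraction, last_qc_day=config.last_qc_day,
    )
    flags = qc.detect_timeseries_outliers(series, params)
    # onset testing uses the locally-flagged series only: trimming 2-SD
    # tails inside the tested groups would bias the per-day ANOVA null
    onset_series = qc.apply_flags(series, flags)
    flags = qc.filter_group_sd(
        series[series["day"] <= params.last_qc_day], sd_k=params.sd_k, flags=flags
    )
    flags = qc.drop_plants_by_flag_fraction(
        flags, series, threshold=params.drop_fraction, last_qc_day=params.last_qc_day
    )
    clean_series = qc.apply_flags(series, flags)
    write_table(flags.to_frame(), outdir / "qc_flags.tsv")
    post_harvest_clean, ph_flags = qc.post_harvest_sd_filter(post_harvest, sd_k=config.sd_k)
    write_table(ph_flags, outdir / "qc_post_harvest_flags.tsv")

    # --- phenotype statistics --------------------------------------------
    logger.info("stage pheno_stats")
    anova_rows = []
    for trait in sorted(post_harvest_clean.columns):
        if trait in ("plant", "genotype", "treatment"):
            continue
        try:
            res = phenostats.anova_gxt(
                post_harvest_clean.dropna(subset=[trait]), value=trait
            )
        except ValueError:
            continue
        anova_rows.append({"trait": trait, **res})
    write_table(pd.DataFrame(anova_rows), outdir / "anova.tsv")
    losses = phenostats.loss_table(post_harvest_clean)
    write_table(losses, outdir / "loss_of_trait.tsv")
    onset = phenostats.onset_day(onset_series, alpha=config.alpha)

    # --- metabolite preprocessing ----------------------------------------
    logger.info("stage preprocess")
    matrix_norm = preprocess.normalize_raw(matrix)
    # re-attach blanks (normalize_raw keeps all samples incl. blanks)
    per_tp = preprocess.preprocess_pipeline(
        matrix_norm, min_frac=config.presence_min_frac,
        impute_frac=config.impute_frac, rsd_top_frac=config.rsd_top_frac,
    )
    report_frames = []
    for tp, (_scaled, _norm, report) in per_tp.items():
        frame = report.to_frame()
        frame.insert(0, "timepoint", tp)
        report_frames.append(frame)
    write_table(pd.concat(report_frames), outdir / "preprocess_report.tsv")

    # --- differential accumulation ---------------------------------------
    logger.info("stage dam")
    dam_frames, up_sets, down_sets = [], {}, {}
    for tp, (scaled, norm, _report) in per_tp.items():
        labels = scaled.meta["treatment"]
        rows = preprocess.row_normalize(scaled)
        rec = dam.ttest_dam(
            rows.values[labels == "drought"], rows.values[labels == "control"],
            timepoint=tp,
        )
        rec = dam.add_fold_changes(rec, norm, labels)
        rec = dam.classify_volcano(rec, alpha=config.alpha, fc_cut=config.fc_cut)
        dam_frames.append(rec)
        sig = rec[rec["fdr"] < config.alpha]
        up_sets[tp] = set(sig.loc[sig["t_stat"] > 0, "feature"])
        down_sets[tp] = set(sig.loc[sig["t_stat"] < 0, "feature"])
    dam_all = pd.concat(dam_frames)
    write_table(dam_all, outdir / "dam.tsv")
    venn = {
        "up": {" & ".join(map(str, k)): v
               for k, v in dam.overlap_counts(up_sets).items()},
        "down": {" & ".join(map(str, k)): v
                 for k, v in dam.overlap_counts(down_sets).items()},
    }

    # --- biomarker screen at 22 DAD --------------------------------------
    logger.info("stage biomarker")
    tp22 = 22 if 22 in per_tp else sorted(per_tp)[-1]
    scaled22, _norm22, _ = per_tp[tp22]
    datasets = biomarker.build_paired_datasets(
        scaled22.values, scaled22.meta, post_harvest_clean
    )
    corr_frames = [biomarker.correlate_metab_pheno(ds, p_cut=config.p_cut)
                   for ds in datasets.values()]
    corr = pd.concat(corr_frames, ignore_index=True)
    write_table(corr, outdir / "correlations.tsv")
    pls = biomarker.plsr_rank_product(
        datasets["DD"], config.target_trait, fold_size=config.fold_size,
        ncomp_max=config.ncomp_max, inner_folds=config.inner_folds,
        seed=config.seed,
    )
    write_table(pls, outdir / "plsr_rank_product.tsv")

    # --- tolerance ranking ------------------------------------------------
    logger.info("stage rank")
    drought_means = (
        post_harvest_clean[post_harvest_clean["treatment"] == "drought"]
        .groupby("genotype")
        .mean(numeric_only=True)
    )
    ranks = ranking.rank_traits(drought_means.dropna(axis=1))
    totals = ranking.rank_product_total(ranks)
    write_table(totals, outdir / "tolerance_ranking.tsv", index=True)

    # --- enrichment (optional) -------------------------------------------
    if config.pathway_map is not None:
        from .io import read_long_table
        pmap_table = read_long_table(config.pathway_map, ("feature_id", "pathway_id"))
        universe = set(per_tp[tp22][0].feature_ids) | set(pmap_table["feature_id"])
        pmap = enrichment.PathwayMap.from_table(pmap_table, universe=universe)
        dam22 = up_sets.get(tp22, set()) | down_sets.get(tp22, set())
        ora = enrichment.ora_hypergeometric(dam22 & pmap.universe, pmap,
                                            alpha=config.alpha)
        write_table(ora, outdir / "enrichment.tsv")

    # --- summary + truth recovery ----------------------------------------
    summary = {
        "seed": config.seed,
        "onset_day": onset,
        "dam_counts": {str(tp): int(len(up_sets[tp]) + len(down_sets[tp]))
                       for tp in up_sets},
        "venn": venn,
        "retained_features": {str(tp): per_tp[tp][0].n_features for tp in per_tp},
        "top_genotypes": list(totals.index[:4]),
    }
    if truth is not None:
        resp = set(truth.drought_responsive_ids)
        found = up_sets.get(tp22, set()) | down_sets.get(tp22, set())
        present = resp & set(per_tp[tp22][0].feature_ids)
        summary["truth_recovery"] = {
            "responsive_present_after_filtering": len(present),
            "responsive_recovered_as_dam": len(present & found),
            "causal_markers": truth.causal_markers,
            "causal_top10": [
                f for f in pls["feature"].head(10)
                if f in set(truth.causal_markers.get(config.target_trait, []))
            ],
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return outdir
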
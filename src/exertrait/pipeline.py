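"""End-to-end orchestration: generate -> landscape -> standardize ->
enrichment and direction models -> GSEA -> consolidated triplet report.

``run_pipeline`` executes every stage in dependency order from a single
:class:`~exertrait.config.RunConfig`; all randomness flows from seeded
per-stage substreams of the master seed, so a fixed config reproduces the
report byte-for-byte.  The consolidated report lists one row per (trait,
tissue, gene) triplet in the DEG x TWAS-hit intersect, with DE state,
sign product, standardized effect sizes and gene-disease evidence score.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from exertrait import direction as direction_mod
from exertrait import gsea as gsea_mod
from exertrait import intersect as intersect_mod
from exertrait import landscape as landscape_mod
from exertrait import simulate, standardize
from exertrait.config import RunConfig, SamplerConfig
from exertrait.hmc import write_draws_csv

logger = logging.getLogger("exertrait")


@dataclass
class PipelineResult:
    config: RunConfig
    config_hash: str
    de: simulate.DEStudy
    cohort: simulate.HumanCohort
    twas: simulate.TwasTable
    evidence: simulate.EvidenceTable
    gsnp: simulate.GSnpMatrix
    degs: landscape_mod.DegSetCollection
    concordance: pd.DataFrame
    jaccard: pd.DataFrame
    specificity: pd.DataFrame
    evidence_triplets: pd.DataFrame
    evidence_summary: pd.DataFrame
    standardized: pd.DataFrame
    counts: intersect_mod.IntersectCounts
    corr: object
    enrich_fit: object
    enrich_summary: pd.DataFrame | None
    dir_counts: direction_mod.DirectionCounts
    dir_fit: object
    dir_summary: pd.DataFrame | None
    gsea_results: pd.DataFrame
    gsea_aggregates: dict
    multi_gsea: pd.DataFrame | None
    triplets: pd.DataFrame
    log: list[dict] = field(default_factory=list)


def _hash_config(config: RunConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def build_triplet_report(
    dir_counts: direction_mod.DirectionCounts,
    de: simulate.DEStudy,
    standardized: pd.DataFrame,
    evidence: simulate.EvidenceTable,
) -> pd.DataFrame:
    """One row per (trait, tissue, gene) in the DEG x hit intersect."""
    detail = dir_counts.detail
    if detail.empty:
        return pd.DataFrame(
            columns=[
                "trait", "tissue", "gene", "de_sign", "twas_sign", "sign_product",
                "sd_pheno_F", "sd_pheno_M", "sd_geno_F", "sd_geno_M",
                "evidence_score",
            ]
        )
    std = standardized.pivot_table(
        index=["gene", "tissue"],
        columns="sex",
        values=["sd_pheno_units", "sd_geno_units"],
        aggfunc="first",
    )
    std.columns = [f"{a.replace('_units', '')}_{b}" for a, b in std.columns]
    ev = evidence.table.set_index(["gene", "trait"])["score"]
    rows = detail.rename(columns={"product": "sign_product"}).copy()
    rows = rows.join(std, on=["gene", "tissue"])
    rows["evidence_score"] = [
        ev.get((g, t), np.nan) for g, t in zip(rows["gene"], rows["trait"])
    ]
    cols = [
        "trait", "tissue", "gene", "de_sign", "twas_sign", "sign_product",
        "sd_pheno_F", "sd_pheno_M", "sd_geno_F", "sd_geno_M", "evidence_score",
    ]
    for c in cols:
        if c not in rows.columns:
            rows[c] = np.nan
    return rows[cols].sort_values(["trait", "tissue", "gene"]).reset_index(drop=True)


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute the full analysis on freshly generated synthetic data.

    MCMC diagnostic failure does not halt the run: the affected posterior
    summaries are set to None and the failure is recorded in the log, so
    downstream consumers cannot silently use an unconverged fit.
    """
    stage_log: list[dict] = []

    def _stage(name):
        t0 = time.time()

        def done(**extra):
            entry = {"stage": name, "seconds": round(time.time() - t0, 3), **extra}
            stage_log.append(entry)
            logger.info("stage %s finished in %.2fs", name, entry["seconds"])
            return entry

        return done

    cfg_hash = _hash_config(config)
    sim = config.sim

    done = _stage("generate")
    de = simulate.generate_de_study(sim)
    cohort = simulate.generate_human_cohort(sim)
    twas = simulate.generate_twas(sim, de)
    evidence = simulate.generate_evidence(sim)
    gsnp = simulate.generate_gsnp(sim)
    done(seed=sim.seed)

    done = _stage("landscape")
    degs = landscape_mod.deg_sets(de)
    zmat = landscape_mod.zscore_matrix(de)
    concord = landscape_mod.concordance_matrix(zmat)
    jac = landscape_mod.jaccard_matrix(degs)
    spec_counts = landscape_mod.tissue_specificity_counts(degs)
    ev_triplets, ev_summary = landscape_mod.evidence_intersect(
        degs, evidence, config.evidence_threshold, list(config.exclude_tissues)
    )
    done()

    done = _stage("standardize")
    std = standardize.standardize_study(cohort, de, alpha=config.h2_filter_alpha)
    done()

    done = _stage("intersect_counts")
    counts = intersect_mod.build_intersect_counts(degs, twas, alpha=config.hit_fdr)
    corr = intersect_mod.intersect_correlation(degs, counts)
    done(n_traits_nonzero=counts.n_traits_nonzero_intersect)

    done = _stage("enrichment_model")
    enrich_mcmc = SamplerConfig(
        **{**config.sampler.to_dict(), "seed": config.seed * 10 + 1}
    )
    enrich_fit = intersect_mod.fit_intersect_model(counts, corr, enrich_mcmc)
    enrich_summary = None
    if enrich_fit.passed:
        enrich_summary = intersect_mod.summarize_enrichment(
            enrich_fit, config.enrich_mass_rule
        )
    done(diagnostics_passed=enrich_fit.passed, divergences=enrich_fit.n_divergent)

    done = _stage("direction_model")
    dir_counts = direction_mod.build_direction_counts(degs, twas, counts.hits)
    dir_mcmc = SamplerConfig(
        **{**config.sampler.to_dict(), "seed": config.seed * 10 + 2}
    )
    dir_fit = direction_mod.fit_direction_model(dir_counts, gsnp, dir_mcmc)
    dir_summary = None
    if dir_fit.passed:
        dir_summary = direction_mod.summarize_direction(
            dir_fit,
            confident_rule=config.direction_mass_rule,
        )
    done(diagnostics_passed=dir_fit.passed, divergences=dir_fit.n_divergent)

    done = _stage("gsea")
    gsea_results = gsea_mod.cellwise_gsea(
        degs, twas, n_perm=config.gsea_n_perm, seed=config.seed * 10 + 3
    )
    gsea_agg = gsea_mod.aggregate_levels(gsea_results, twas.trait_category)
    try:
        multi = gsea_mod.multi_tissue_gsea(
            degs, twas, min_tissues=config.min_tissues_shared,
            n_perm=config.gsea_n_perm, seed=config.seed * 10 + 4,
        )
    except ValueError:
        multi = None
    done()

    done = _stage("report")
    triplets = build_triplet_report(dir_counts, de, std, evidence)
    done(n_triplets=len(triplets))

    result = PipelineResult(
        config=config,
        config_hash=cfg_hash,
        de=de,
        cohort=cohort,
        twas=twas,
        evidence=evidence,
        gsnp=gsnp,
        degs=degs,
        concordance=concord,
        jaccard=jac,
        specificity=spec_counts,
        evidence_triplets=ev_triplets,
        evidence_summary=ev_summary,
        standardized=std,
        counts=counts,
        corr=corr,
        enrich_fit=enrich_fit,
        enrich_summary=enrich_summary,
        dir_counts=dir_counts,
        dir_fit=dir_fit,
        dir_summary=dir_summary,
        gsea_results=gsea_results,
        gsea_aggregates=gsea_agg,
        multi_gsea=multi,
        triplets=triplets,
        log=stage_log,
    )
    if outdir is not None:
        write_pipeline_outputs(result, outdir)
    return result


def write_pipeline_outputs(result: PipelineResult, outdir) -> None:
    """Persist stage artifacts as TSV/CSV/JSON under a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "run_config.yaml")
    simulate.write_study(
        outdir / "data", result.config.sim, result.de, result.twas,
        result.evidence, result.gsnp,
    )

    def _tsv(df, name, index=False):
        if df is not None:
            df.to_csv(outdir / name, sep="\t", index=index)

    _tsv(result.concordance, "concordance.tsv", index=True)
    _tsv(result.jaccard, "jaccard.tsv", index=True)
    _tsv(result.specificity, "tissue_specificity.tsv")
    _tsv(result.evidence_triplets, "evidence_triplets.tsv")
    _tsv(result.evidence_summary, "evidence_summary.tsv")
    _tsv(result.standardized, "standardized_effects.tsv")
    _tsv(result.enrich_summary, "enrichment_summary.tsv")
    _tsv(result.dir_summary, "direction_summary.tsv")
    _tsv(result.gsea_results, "gsea_cells.tsv")
    for level, frame in result.gsea_aggregates.items():
        _tsv(frame, f"gsea_{level}_level.tsv")
    if result.multi_gsea is not None:
        _tsv(result.multi_gsea, "gsea_multi_tissue.tsv")
    _tsv(result.triplets, "triplet_report.tsv")
    write_draws_csv(result.enrich_fit, outdir / "enrichment_draws.csv")
    write_draws_csv(result.dir_fit, outdir / "direction_draws.csv")
    meta = {
        "config_hash": result.config_hash,
        "stages": result.log,
        "fdr_method": result.counts.meta.get("fdr_method"),
        "enrich_diagnostics_passed": bool(result.enrich_fit.passed),
        "direction_diagnostics_passed": bool(result.dir_fit.passed),
        "n_triplets": int(len(result.triplets)),
    }
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def validate_against_truth(
    result: PipelineResult,
    sign_accuracy_min: float = 0.9,
    hit_sensitivity_min: float = 0.5,
    hit_specificity_min: float = 0.98,
    h2_rmse_max: float = 0.25,
    alpha_bias_max: float = 0.3,
) -> pd.DataFrame:
    """Recovery metrics of the pipeline report against generator truth.

    Reads planted truth only from generator records.  Returns a metrics
    table with a per-metric pass/fail verdict against the supplied
    envelopes.
    """
    twas_truth = result.twas.truth.set_index(["gene", "tissue", "trait"])
    detail = result.dir_counts.detail
    if len(detail):
        keys = list(zip(detail["gene"], detail["tissue"], detail["trait"]))
        truth_sign = np.array(
            [twas_truth.loc[k, "sign_true"] for k in keys], dtype=float
        )
        called_sign = detail["twas_sign"].to_numpy(float)
        informative = truth_sign != 0
        sign_acc = (
            float(np.mean(called_sign[informative] == truth_sign[informative]))
            if informative.any()
            else np.nan
        )
    else:
        sign_acc = np.nan

    merged = result.counts.hits.merge(
        result.twas.truth, on=["gene", "tissue", "trait"], how="left"
    )
    hit_true = merged["hit_true"].to_numpy(bool)
    hit_called = merged["hit"].to_numpy(bool)
    sens = float(hit_called[hit_true].mean()) if hit_true.any() else np.nan
    spec = float((~hit_called[~hit_true]).mean()) if (~hit_true).any() else np.nan

    errs = []
    std = result.standardized.drop_duplicates(["gene", "tissue"]).set_index(
        ["gene", "tissue"]
    )
    for tissue in result.cohort.tissues:
        tc = result.cohort.per_tissue[tissue]
        est = std.loc[
            [(g, tissue) for g in result.cohort.genes], "h2"
        ].to_numpy(float)
        errs.append(est - tc.h2_true)
    h2_rmse = float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))

    alpha_true, *_ = result.config.sim.planted_effects.resolve(
        result.config.sim.n_tissues, result.config.sim.n_traits
    )
    alpha_post = float(result.enrich_fit.stacked("alpha").mean())
    alpha_bias = alpha_post - alpha_true

    rows = [
        ("sign_accuracy", sign_acc, f">= {sign_accuracy_min}",
         bool(sign_acc >= sign_accuracy_min) if np.isfinite(sign_acc) else False),
        ("hit_sensitivity", sens, f">= {hit_sensitivity_min}",
         bool(sens >= hit_sensitivity_min) if np.isfinite(sens) else False),
        ("hit_specificity", spec, f">= {hit_specificity_min}",
         bool(spec >= hit_specificity_min) if np.isfinite(spec) else False),
        ("h2_rmse", h2_rmse, f"<= {h2_rmse_max}", bool(h2_rmse <= h2_rmse_max)),
        ("alpha_recovery_bias", alpha_bias, f"|.| <= {alpha_bias_max}",
         bool(abs(alpha_bias) <= alpha_bias_max)),
    ]
    return pd.DataFrame(rows, columns=["metric", "value", "envelope", "passed"])
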
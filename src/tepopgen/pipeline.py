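"""End-to-end orchestration: files in, result tables out.

Stages run in a fixed order (load -> annotate-te -> popgen -> scan -> models
-> crosslineage -> enrich); each writes its tab-separated outputs into the
run directory and a machine-readable ``run_log.json`` records the seed,
package versions and completed stages.  A failure anywhere aborts with the
stage name.  Analyses are per lineage; the first lineage (alphabetically, or
``config.paths['primary_lineage']``) drives the model ladder and the second,
if present, provides the independent-lineage comparison and the Model-3
subsets.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .het_models import LadderInputs, build_observations, model_ladder
from .io_formats import (PipelineConfig, read_annotations, read_genotypes,
                         read_te_gff, write_table)
from .popgen_stats import (allele_counts_by_population, locus_stats,
                           relatedness_clusters, sample_fis, wc_fst)
from .selection_scan import (MCMCSettings, ScanThresholds, classify_selection,
                             fst_decomposition_mcmc, pca_scan, purifying_rule)
from .lineage_enrichment import (cross_lineage_correlation, essentiality_anova,
                                 fisher_enrichment, outlier_profiles,
                                 shared_outliers)
from .te_proximity import annotate_all

logger = logging.getLogger("tepopgen")

STAGES = ("load", "annotate-te", "popgen", "scan", "models",
          "crosslineage", "enrich")


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 last_stage: str = "enrich") -> dict:
    """Run the pipeline through ``last_stage`` and write all outputs."""
    if last_stage not in STAGES:
        raise ValueError(f"unknown stage {last_stage!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {"config": config}
    log = {"seed": config.seed, "config": config.to_dict(), "stages": [],
           "versions": _versions()}
    stage = "load"
    try:
        for stage in STAGES[: STAGES.index(last_stage) + 1]:
            _STAGE_FUNCS[stage](state, out)
            log["stages"].append(stage)
    except Exception as exc:
        log["failed_stage"] = stage
        log["error"] = str(exc)
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    if "mcmc_diag" in state:
        log["mcmc_converged"] = {lin: d["converged"]
                                 for lin, d in state["mcmc_diag"].items()}
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return state


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels
    return {"tepopgen": __version__, "python": platform.python_version(),
            "numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_load(state: dict, out: Path) -> None:
    cfg: PipelineConfig = state["config"]
    paths = cfg.paths
    table, report = read_genotypes(paths["genotypes"], paths["metadata"],
                                   maf_min=cfg.maf_min)
    state["catalog"] = read_te_gff(paths["te_gff"], cfg.superfamily_key)
    state["annotations"] = read_annotations(
        paths.get("codon_fold"), paths.get("snp_gene"),
        paths.get("gene_go"), paths.get("gene_essentiality"))
    lineages = sorted(pd.unique(table.lineage))
    primary = paths.get("primary_lineage", lineages[0])
    state["tables"] = {lin: table.subset_samples(table.lineage == lin)
                       for lin in lineages}
    state["primary"] = primary
    state["filter_report"] = report
    write_table(pd.DataFrame([vars(report)]), out / "filter_report.tsv")


def _stage_annotate(state: dict, out: Path) -> None:
    cfg = state["config"]
    state["contexts"], state["te_summary"] = {}, {}
    for lin, table in state["tables"].items():
        ctx, summary = annotate_all(table, state["catalog"], cfg.sense_mode)
        state["contexts"][lin] = ctx
        state["te_summary"][lin] = summary
        write_table(ctx, out / f"te_context_{lin}.tsv")
        write_table(summary, out / f"te_summary_{lin}.tsv")


def _stage_popgen(state: dict, out: Path) -> None:
    cfg = state["config"]
    state["fis"], state["clusters"], state["locus"] = {}, {}, {}
    for lin, table in state["tables"].items():
        fis = sample_fis(table)
        clusters = relatedness_clusters(table, cfg.n_pcs, cfg.n_clusters,
                                        seed=cfg.seed)
        state["fis"][lin] = fis
        state["clusters"][lin] = clusters
        state["locus"][lin] = locus_stats(table, clusters)
        write_table(fis, out / f"fis_{lin}.tsv")
        write_table(state["locus"][lin], out / f"locus_stats_{lin}.tsv")


def _stage_scan(state: dict, out: Path) -> None:
    cfg = state["config"]
    thresholds = ScanThresholds(cfg.q_cutoff, cfg.log10_po_cutoff, cfg.fdr)
    settings = MCMCSettings(seed=cfg.seed, **cfg.mcmc)
    state["calls"], state["mcmc_diag"] = {}, {}
    for lin, table in state["tables"].items():
        pca_frame, _scores = pca_scan(table, cfg.n_pcs, seed=cfg.seed)
        _pops, alt, tot = allele_counts_by_population(table)
        locus, pops, diag = fst_decomposition_mcmc(alt, tot, settings,
                                                   snp_ids=table.snp_ids,
                                                   fdr=cfg.fdr)
        calls = classify_selection(pca_frame, locus, wc_fst(table),
                                   thresholds, cfg.classify_mode)
        fold = state["annotations"].fold_for_snps(table.chrom, table.pos0)
        calls = purifying_rule(calls, table.maf(), fold)
        state["calls"][lin] = calls
        state["mcmc_diag"][lin] = diag
        write_table(calls, out / f"selection_calls_{lin}.tsv")
        write_table(pops, out / f"mcmc_beta_{lin}.tsv")


def _stage_models(state: dict, out: Path) -> None:
    cfg = state["config"]
    lin = state["primary"]
    table = state["tables"][lin]
    fis = state["fis"][lin]
    fvals = fis.set_index("sample").loc[list(table.samples), "fis"].to_numpy()

    def obs(mask):
        return build_observations(table, state["contexts"][lin],
                                  state["clusters"][lin], fis,
                                  sample_mask=mask, calls=state["calls"][lin])

    inputs = LadderInputs(
        obs_high=obs(fvals > cfg.fis_split_high),
        obs_low=obs(fvals < cfg.fis_split_high),
        obs_all=obs(None),
    )
    others = [l for l in state["tables"] if l != lin]
    if others:
        eu = others[0]
        eu_table = state["tables"][eu]
        eu_f = state["fis"][eu].set_index("sample").loc[
            list(eu_table.samples), "fis"].to_numpy()

        def eu_obs(mask):
            return build_observations(eu_table, state["contexts"][eu],
                                      state["clusters"][eu], state["fis"][eu],
                                      sample_mask=mask, calls=state["calls"][eu])

        if (eu_f > cfg.fis_split_europe).any():
            inputs.obs_europe_above = eu_obs(eu_f > cfg.fis_split_europe)
        if (eu_f < cfg.fis_split_europe).any():
            inputs.obs_europe_below = eu_obs(eu_f < cfg.fis_split_europe)

    result = model_ladder(inputs, reference=cfg.reference_superfamily)
    state["ladder"] = result
    write_table(pd.DataFrame({"superfamily": sorted(result.te_effect_set)}),
                out / "te_effect_set.tsv")
    anovas = []
    for mid, fit in result.fits.items():
        write_table(fit.coef_frame(), out / f"model_{mid}_coefficients.tsv")
        if fit.anova is not None:
            anovas.append(fit.anova.assign(model=mid))
    if anovas:
        write_table(pd.concat(anovas, ignore_index=True),
                    out / "analysis_of_deviance.tsv")
    if result.skipped:
        write_table(pd.DataFrame(result.skipped, columns=["model", "reason"]),
                    out / "skipped_models.tsv")


def _stage_crosslineage(state: dict, out: Path) -> None:
    lins = sorted(state["tables"])
    if len(lins) < 2:
        logger.info("single lineage; skipping cross-lineage comparison")
        return
    a, b = lins[0], lins[1]
    prof_a = outlier_profiles(state["contexts"][a], state["calls"][a])
    prof_b = outlier_profiles(state["contexts"][b], state["calls"][b])
    corr = cross_lineage_correlation(prof_a, prof_b)
    shared = shared_outliers(state["calls"][a], state["calls"][b],
                             state["contexts"][a], state["contexts"][b])
    state["crosslineage"] = {"profiles": {a: prof_a, b: prof_b},
                             "correlation": corr, "shared": shared}
    write_table(prof_a, out / f"outlier_profiles_{a}.tsv")
    write_table(prof_b, out / f"outlier_profiles_{b}.tsv")
    write_table(corr, out / "crosslineage_correlation.tsv")
    write_table(shared, out / "shared_outliers.tsv")


def _stage_enrich(state: dict, out: Path) -> None:
    ann = state["annotations"]
    if ann.snp_gene is None or ann.gene_go is None:
        logger.info("no gene / GO tables; skipping enrichment")
        return
    lin = state["primary"]
    calls = state["calls"][lin]
    background = calls["snp_id"]
    for cls in ("balancing", "divergent"):
        fg = calls.loc[calls["class"] == cls, "snp_id"]
        if fg.empty:
            continue
        enr = fisher_enrichment(fg, background, ann.snp_gene, ann.gene_go)
        write_table(enr, out / f"enrichment_{cls}_{lin}.tsv")
    if ann.gene_essentiality is not None:
        tables = essentiality_anova(ann.gene_essentiality, calls,
                                    state["contexts"][lin], ann.snp_gene)
        for measure, tab in tables.items():
            write_table(tab, out / f"essentiality_anova_{measure}_{lin}.tsv")


_STAGE_FUNCS = {
    "load": _stage_load,
    "annotate-te": _stage_annotate,
    "popgen": _stage_popgen,
    "scan": _stage_scan,
    "models": _stage_models,
    "crosslineage": _stage_crosslineage,
    "enrich": _stage_enrich,
}
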
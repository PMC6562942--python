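"""End-to-end orchestration of the integration pipeline.

The reference run mirrors the full analysis sequence on synthetic data:
simulate inputs with planted effects, test all disease pairs for
pathway-space overlap, compute pathway loads, derive matched comorbidity
ratios from the discharge cohort, correlate load against ratio per
pathway, test the planted pathway for expression dysregulation in two
simulated studies (plus their merge and cross-study concordance), and
quantify qPCR fold changes. A single JSON-like run report collects every
intermediate count and test statistic; the whole run is reproducible from
one seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

from . import __version__
from .catalog import DiseaseGeneCatalog, PathwayAnnotation
from .comorbidity import (
    comorbidity_ratios,
    correlate_load_vs_ratio,
    correlations_to_frame,
    match_controls,
    pathway_load,
    select_ad_cases,
)
from .expression import (
    cross_dataset_concordance,
    merge_studies,
    pathway_enrichment,
    per_gene_glm,
    results_to_frame,
)
from .io import (
    config_hash,
    file_header,
    write_catalog,
    write_cohort,
    write_expression,
    write_gmt,
    write_json,
    write_qpcr,
    write_table,
)
from .overlap import all_pairs_overlap, build_shared_matrix
from .qpcr import quantify_targets
from .simulate import (
    SimulationConfig,
    comorbidity_effects_from_pathway,
    disease_code_map,
    simulate_catalog_and_pathways,
    simulate_discharge_cohort,
    simulate_expression_study,
    simulate_qpcr_plate,
    stage_rng,
)

log = logging.getLogger("comopath")

DEFAULT_QPCR_FOLDS = {"Jak1": 2.0, "Jak2": 2.0, "Jak3": 1.0, "Tyk2": 2.0}


@dataclass
class PipelineConfig:
    """Thresholds, toggles and paths for a full pipeline run."""

    outdir: str = "comopath_run"
    seed: int = 0
    # analysis thresholds
    top_k: int = 25
    min_genes: int = 25
    alpha: float = 0.05
    correction: str = "bonferroni"
    min_patients: int = 15
    min_age: int = 60
    p0: float = 0.05
    gene_rule: str = "raw"
    # synthetic scenario
    n_shared_genes: int = 20
    comorbidity_strength: float = 3.0
    effect_size: float = 1.0
    effect_heterogeneity: float = 0.5
    qpcr_folds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_QPCR_FOLDS))
    # stage toggles
    run_overlap: bool = True
    run_comorbidity: bool = True
    run_expression: bool = True
    run_qpcr: bool = True
    simulation: SimulationConfig | None = None

    def sim_config(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        ids = [f"D{i + 1:02d}" for i in range(20)]
        return SimulationConfig(
            n_diseases=len(ids),
            planted_disease_pairs=[(ids[0], ids[1], self.n_shared_genes)],
            plant_comorbidity_gradient=True,
            effect_size=self.effect_size,
            effect_heterogeneity=self.effect_heterogeneity,
            seed=self.seed,
        )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; write outputs and return the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_digest = config_hash(
        {k: v for k, v in asdict(config).items() if k != "outdir"}
    )
    header = file_header(seed=config.seed, cfg_hash=cfg_digest)
    report: dict[str, Any] = {
        "tool": f"comopath v{__version__}",
        "config_hash": cfg_digest,
        "seed": config.seed,
        "stages": {},
    }

    sim = config.sim_config()
    log.info("simulating catalog and pathway annotation")
    catalog, annotation = simulate_catalog_and_pathways(sim)
    planted_pathway = None
    if "comorbidity" in annotation.planted:
        planted_pathway = annotation.planted["comorbidity"][0]
    elif annotation.planted:
        planted_pathway = sorted(annotation.planted.values())[0][0]
    write_catalog(catalog, outdir / "catalog.tsv", header=header)
    write_gmt(annotation, outdir / "pathways.gmt", header=header)
    report["stages"]["simulate"] = {
        "n_diseases": len(catalog),
        "n_pathways": len(annotation),
        "planted_pairs": sorted(annotation.planted),
        "planted_pathway": planted_pathway,
    }

    if config.run_overlap:
        report["stages"]["overlap"] = _overlap_stage(
            config, catalog, annotation, outdir, header
        )
    if config.run_comorbidity:
        report["stages"]["comorbidity"] = _comorbidity_stage(
            config, sim, catalog, annotation, planted_pathway, outdir, header
        )
    if config.run_expression:
        report["stages"]["expression"] = _expression_stage(
            config, sim, annotation, planted_pathway, outdir, header
        )
    if config.run_qpcr:
        report["stages"]["qpcr"] = _qpcr_stage(config, outdir, header)

    write_json(report, outdir / "run_report.json")
    return report


def _overlap_stage(config, catalog, annotation, outdir, header):
    log.info("all-pairs pathway-space overlap")
    matrix = build_shared_matrix(catalog, annotation)
    summary = all_pairs_overlap(
        catalog, matrix, alpha=config.alpha, correction=config.correction
    )
    write_table(summary.to_frame(), outdir / "overlap_pairs.tsv", header=header)
    write_table(
        summary.adjacency, outdir / "overlap_adjacency.tsv", header=header, index=True
    )
    best = min(summary.results, key=lambda r: r.p_value)
    components = [sorted(c) for c in summary.components() if len(c) > 1]
    return {
        "n_pairs_tested": summary.n_pairs,
        "n_significant": len(summary.significant_pairs),
        "most_significant_pair": sorted([best.disease_a, best.disease_b]),
        "most_significant_p_adj": best.p_bonferroni,
        "components": components,
        "neighbour_counts": {
            d: int(c) for d, c in summary.neighbour_counts().items() if c
        },
    }


def _comorbidity_stage(config, sim, catalog, annotation, planted_pathway, outdir, header):
    log.info("pathway loads, matched comorbidity ratios, correlation")
    loads = pathway_load(catalog, annotation)
    write_table(loads.loads, outdir / "pathway_loads.tsv", header=header, index=True)

    effects = (
        comorbidity_effects_from_pathway(
            catalog, annotation, planted_pathway, strength=config.comorbidity_strength
        )
        if planted_pathway is not None
        else {}
    )
    sim_cfg = SimulationConfig(**{**asdict(sim), "comorbidity_effects": effects})
    cohort, codes = simulate_discharge_cohort(sim_cfg)
    write_cohort(cohort, outdir / "cohort.csv", header=header)

    cases = select_ad_cases(cohort, min_age=config.min_age)
    matched = match_controls(cases, cohort, seed=config.seed)
    ratios = comorbidity_ratios(matched, codes, min_patients=config.min_patients)
    write_table(_ratio_frame(ratios), outdir / "comorbidity_ratios.tsv", header=header)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-load pathways are routine
        correlations = correlate_load_vs_ratio(loads, ratios)
    write_table(
        correlations_to_frame(correlations),
        outdir / "load_ratio_correlations.tsv",
        header=header,
    )
    top = correlations[0]
    return {
        "n_cases": int(len(cases)),
        "n_matched": int(len(matched)),
        "n_dropped_cases": matched.n_dropped,
        "n_diseases_with_ratio": len(ratios),
        "n_pathways_tested": len(correlations),
        "top_pathway": top.pathway,
        "top_pathway_r": top.r,
        "top_pathway_p": top.p_value,
        "top_pathway_p_adj": top.p_bonferroni,
        "planted_pathway_is_top": top.pathway == planted_pathway,
    }


def _ratio_frame(ratios):
    import pandas as pd

    return pd.DataFrame(
        {
            "disease": [r.disease for r in ratios],
            "case_count": [r.case_count for r in ratios],
            "control_count": [r.control_count for r in ratios],
            "ratio": [r.ratio for r in ratios],
        }
    )


def _expression_stage(config, sim, annotation, planted_pathway, outdir, header):
    log.info("per-gene GLM and pathway enrichment on two simulated studies")
    sim_cfg = SimulationConfig(
        **{**asdict(sim), "dysregulated_pathway": planted_pathway}
    )
    rng = stage_rng(sim_cfg.seed, "expression")
    study_a = simulate_expression_study(sim_cfg, annotation, rng=rng)
    study_b = simulate_expression_study(sim_cfg, annotation, rng=rng)
    write_expression(
        study_a, outdir / "expression_1.tsv", outdir / "samples_1.tsv", header=header
    )

    pathway_genes = (
        sorted(annotation.pathways[planted_pathway])
        if planted_pathway is not None
        else list(study_a.genes[:50])
    )
    measured = [g for g in pathway_genes if g in set(study_a.genes)]

    out: dict[str, Any] = {}
    results_a = per_gene_glm(study_a, ("AD", "control"), genes=measured)
    results_b = per_gene_glm(study_b, ("AD", "control"), genes=measured)
    write_table(results_to_frame(results_a), outdir / "glm_results_1.tsv", header=header)

    for label, results in (("study_1", results_a), ("study_2", results_b)):
        enr = pathway_enrichment(
            results,
            planted_pathway or "background",
            method=config.gene_rule,
            alpha=config.alpha,
            p0=config.p0,
        )
        out[label] = {
            "n_measured": enr.n_measured,
            "k_significant": enr.k_significant,
            "binomial_p": enr.p_value,
        }
    rho, sp_p, n_shared = cross_dataset_concordance(results_a, results_b)
    out["concordance"] = {"spearman_rho": rho, "p": sp_p, "n_shared_genes": n_shared}

    merged = merge_studies([study_a, study_b], labels=["S1", "S2"])
    results_m = per_gene_glm(merged, ("AD", "control"), genes=measured)
    enr_m = pathway_enrichment(
        results_m,
        planted_pathway or "background",
        method=config.gene_rule,
        alpha=config.alpha,
        p0=config.p0,
    )
    out["merged"] = {
        "n_measured": enr_m.n_measured,
        "k_significant": enr_m.k_significant,
        "binomial_p": enr_m.p_value,
    }
    out["mci"] = _mci_block(config, study_a, measured, planted_pathway)
    return out


def _mci_block(config, study, measured, planted_pathway):
    results = per_gene_glm(study, ("MCI", "control"), genes=measured)
    enr = pathway_enrichment(
        results,
        planted_pathway or "background",
        method=config.gene_rule,
        alpha=config.alpha,
        p0=config.p0,
    )
    return {
        "n_measured": enr.n_measured,
        "k_significant": enr.k_significant,
        "binomial_p": enr.p_value,
    }


def _qpcr_stage(config, outdir, header):
    log.info("qPCR fold-change quantification")
    plate = simulate_qpcr_plate(config.qpcr_folds, seed=config.seed)
    write_qpcr(plate, outdir / "qpcr_plate.csv", header=header)
    table = quantify_targets(
        plate,
        targets=sorted(config.qpcr_folds),
        housekeeping=("Hprt1", "Actb"),
        control_group="PBS",
    )
    write_table(table, outdir / "qpcr_results.tsv", header=header)
    return {
        row["gene"]: {
            "true_fold": config.qpcr_folds[row["gene"]],
            "mean_fold": row["mean_fold"],
            "sem": row["sem"],
            "t": row["t"],
            "p": row["p"],
        }
        for _, row in table.iterrows()
    }
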
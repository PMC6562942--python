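"""Synthetic inputs with known planted structure.

Every downstream stage of the pipeline (pathway-space disease overlap,
comorbidity-load correlation, expression enrichment, qPCR quantification)
is exercised against data generated here, so each stage has a
parameter-recovery test with a known ground truth instead of an external
snapshot:

* a disease-gene association catalog plus KEGG-style pathway annotation,
  where chosen disease pairs share a configurable number of genes placed
  in common pathways (the genes themselves stay disjoint between the two
  diseases, so the signal is shared *pathways*, not shared genes);
* a hospital-discharge cohort with demographic fields and ICD-9-CM-style
  code lists, where chosen diseases carry an elevated relative risk among
  index-condition (code 331.0) patients aged over 60;
* expression studies in which the genes of one pathway are mean-shifted
  in cases by a configurable effect size;
* qPCR plates whose CT values encode requested fold changes exactly in
  expectation.

All randomness flows from the single configured seed; each stage draws
from an independent, deterministically derived stream so stages can be
regenerated in isolation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import DiseaseGeneCatalog, PathwayAnnotation
from .comorbidity import AD_CODE, DischargeCohort
from .expression import ExpressionStudy
from .qpcr import QpcrPlate

# stage offsets for deriving independent rng streams from the master seed
_STAGE = {"catalog": 1, "cohort": 2, "expression": 3, "qpcr": 4}

N_LINKER_PATHWAYS = 3  # common pathways carrying each planted disease pair


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one pipeline stage, derived from the seed."""
    return np.random.default_rng([int(seed), _STAGE[stage]])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults describe the reference study conditions: a 1000-gene
    universe annotated to 200 pathways of 10-20 genes (about three
    memberships per gene, a typical curated-pathway density), a panel of
    20 diseases with 25 retained susceptibility genes each, a
    50 000-patient discharge cohort (index-condition and per-disease
    coding prevalences of 5%, keeping per-disease counts informative at
    this cohort size), and expression studies of 100 samples per
    diagnostic group.
    """

    n_genes: int = 1000
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (10, 20)
    n_diseases: int = 20
    genes_per_disease: int = 25
    planted_disease_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    n_patients: int = 50_000
    comorbidity_effects: dict[str, float] = field(default_factory=dict)
    ad_prevalence: float = 0.05  # among patients aged > 60
    disease_prevalence: float = 0.05  # baseline per synthetic disease
    plant_comorbidity_gradient: bool = False
    n_samples_per_group: int = 100
    dysregulated_pathway: str | None = None
    effect_size: float = 0.0  # standardised mean shift in cases
    effect_heterogeneity: float = 0.0  # per-gene spread of the shift, in [0, 1)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pathways", "n_diseases", "genes_per_disease",
                     "n_patients", "n_samples_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.pathway_size_range
        if not 0 < lo <= hi:
            raise ValueError("pathway_size_range must satisfy 0 < min <= max")
        if hi > self.n_genes:
            raise ValueError("largest pathway exceeds gene universe")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.effect_heterogeneity < 1:
            raise ValueError("effect_heterogeneity must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.ad_prevalence < 1 or not 0 < self.disease_prevalence < 1:
            raise ValueError("prevalences must lie in (0, 1)")
        for _, _, k in self.planted_disease_pairs:
            if k > self.genes_per_disease:
                raise ValueError(
                    f"planted pair requests {k} shared genes but diseases "
                    f"have only {self.genes_per_disease}"
                )

    def disease_ids(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_diseases)]


def disease_code_map(diseases: Sequence[str]) -> dict[str, str]:
    """Synthetic ICD-9-CM-style code per disease (never the reserved 331.0)."""
    return {d: f"{200 + i}.0" for i, d in enumerate(sorted(diseases))}


# ---------------------------------------------------------------------------
# catalog + pathways


def simulate_catalog_and_pathways(
    config: SimulationConfig,
) -> tuple[DiseaseGeneCatalog, PathwayAnnotation]:
    """Disease-gene catalog and pathway annotation with planted overlap.

    Pathway sizes are uniform on ``pathway_size_range`` with members drawn
    uniformly from the gene universe, giving independent memberships of
    realistic density. For each planted pair (A, B, k), k fresh genes are
    assigned to A and k disjoint fresh genes to B, and all 2k are added to
    :data:`N_LINKER_PATHWAYS` common pathways; every other gene-to-disease
    assignment is an independent uniform draw. Per-disease association
    p-values are strictly increasing sorted uniforms.
    """
    rng = stage_rng(config.seed, "catalog")
    genes = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)])
    pathway_ids = [f"PW{i + 1:04d}" for i in range(config.n_pathways)]

    lo, hi = config.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    pathways: dict[str, set[str]] = {
        pid: set(rng.choice(genes, size=s, replace=False))
        for pid, s in zip(pathway_ids, sizes)
    }

    diseases = config.disease_ids()
    planted_genes: dict[str, list[str]] = {d: [] for d in diseases}
    reserved: set[str] = set()
    planted_info: dict[str, tuple[str, ...]] = {}
    for da, db, k in config.planted_disease_pairs:
        for d in (da, db):
            if d not in planted_genes:
                raise ValueError(f"planted disease {d!r} not among {diseases}")
        free = np.array(sorted(set(genes) - reserved))
        chosen = rng.choice(free, size=2 * k, replace=False)
        ga, gb = list(chosen[:k]), list(chosen[k:])
        reserved.update(chosen)
        planted_genes[da].extend(ga)
        planted_genes[db].extend(gb)
        linkers = rng.choice(pathway_ids, size=N_LINKER_PATHWAYS, replace=False)
        for pid in linkers:
            pathways[pid].update(chosen)
        planted_info[f"{da}|{db}"] = tuple(sorted(linkers))

    associations: dict[str, list[tuple[str, float]]] = {}
    unreserved = np.array(sorted(set(genes) - reserved))
    disease_members: dict[str, list[str]] = {}
    for d in diseases:
        fixed = planted_genes[d]
        n_free = config.genes_per_disease - len(fixed)
        drawn = rng.choice(unreserved, size=n_free, replace=False)
        members = list(fixed) + list(drawn)
        disease_members[d] = members
        pvals = np.sort(rng.uniform(1e-12, 5e-2, size=len(members)))
        pvals = pvals + np.arange(len(pvals)) * 1e-15  # enforce strict increase
        order = rng.permutation(len(members))  # gene identity ⟂ association rank
        associations[d] = [(members[i], float(p)) for i, p in zip(order, pvals)]

    if config.plant_comorbidity_gradient:
        # dedicate one pathway whose per-disease gene count rises linearly
        # across diseases, so its load (and any relative risk derived from
        # it) varies over the whole disease panel, not just a planted pair
        free_pids = [p for p in pathway_ids
                     if p not in {x for v in planted_info.values() for x in v}]
        grad_pid = str(rng.choice(free_pids))
        denom = max(1, config.n_diseases - 1)
        for i, d in enumerate(diseases):
            n_in = round(0.5 * config.genes_per_disease * i / denom)
            # prefer the disease's non-pair-planted genes to keep plantings orthogonal
            own = [g for g in disease_members[d] if g not in reserved][:n_in]
            pathways[grad_pid].update(own)
        planted_info["comorbidity"] = (grad_pid,)

    catalog = DiseaseGeneCatalog.from_associations(
        associations,
        min_genes=min(25, config.genes_per_disease),
        top_k=config.genes_per_disease,
    )
    annotation = PathwayAnnotation(
        {p: frozenset(g) for p, g in pathways.items()}, planted=planted_info
    )
    return catalog, annotation


# ---------------------------------------------------------------------------
# discharge cohort

_FILLER_CODES = [f"7{i:02d}.9" for i in range(40)]
_RACES = np.array(["white", "black", "asian", "other"])
_RACE_P = np.array([0.6, 0.2, 0.1, 0.1])


def simulate_discharge_cohort(
    config: SimulationConfig,
    disease_codes: Mapping[str, str] | None = None,
) -> tuple[DischargeCohort, dict[str, str]]:
    """Synthetic hospital-discharge records with planted comorbidity.

    Ages put most mass above 60 (an in-patient, late-life-heavy mix); the
    index condition (code 331.0) occurs only above age 60, at
    ``ad_prevalence``. Each synthetic disease occurs at its baseline
    prevalence, multiplied by its configured relative risk in
    index-condition patients, so the expected comorbidity ratio after
    exact matching equals that relative risk. Every record carries at
    least one filler code, so code lists are never empty.
    """
    if disease_codes is None:
        disease_codes = disease_code_map(config.disease_ids())
    if AD_CODE in disease_codes.values():
        raise ValueError(f"code {AD_CODE} is reserved for the index condition")
    unknown = set(config.comorbidity_effects) - set(disease_codes)
    if unknown:
        raise ValueError(f"comorbidity_effects for unknown diseases: {sorted(unknown)}")

    rng = stage_rng(config.seed, "cohort")
    n = config.n_patients
    old = rng.random(n) < 0.6
    age = np.where(old, rng.integers(61, 96, size=n), rng.integers(0, 61, size=n))
    sex = np.where(rng.random(n) < 0.55, "F", "M")
    race = _RACES[rng.choice(len(_RACES), size=n, p=_RACE_P)]
    year = rng.integers(1979, 2007, size=n)
    ad = (age > 60) & (rng.random(n) < config.ad_prevalence)
    if (age > 60).sum() * config.ad_prevalence < 1:
        warnings.warn(
            "cohort too small to expect any index-condition case at the "
            "configured prevalence",
            stacklevel=2,
        )

    carrier: dict[str, np.ndarray] = {}
    for disease, code in disease_codes.items():
        rho = config.comorbidity_effects.get(disease, 1.0)
        prob = np.where(
            ad, min(1.0, config.disease_prevalence * rho), config.disease_prevalence
        )
        carrier[code] = rng.random(n) < prob

    n_filler = 1 + rng.poisson(1.5, size=n)
    filler_idx = rng.integers(0, len(_FILLER_CODES), size=(n, n_filler.max()))
    code_order = sorted(disease_codes.values())
    dx_codes: list[tuple[str, ...]] = []
    for i in range(n):
        codes = [_FILLER_CODES[j] for j in filler_idx[i, : n_filler[i]]]
        codes.extend(c for c in code_order if carrier[c][i])
        if ad[i]:
            codes.append(AD_CODE)
        dx_codes.append(tuple(dict.fromkeys(codes)))

    records = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:07d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": race,
            "survey_year": year,
            "dx_codes": dx_codes,
        }
    )
    return DischargeCohort(records), dict(disease_codes)


def comorbidity_effects_from_pathway(
    catalog: DiseaseGeneCatalog,
    annotation: PathwayAnnotation,
    pathway: str,
    strength: float = 2.0,
) -> dict[str, float]:
    """Relative risks that make one pathway drive comorbidity.

    Each disease's relative risk with the index condition is set to
    1 + strength * load(A, pathway) / max_load, so the planted pathway's
    load is, by construction, linearly related to the true comorbidity
    ratio. Used to plant a recoverable load-ratio correlation.
    """
    from .comorbidity import pathway_load

    loads = pathway_load(catalog, annotation).loads
    if pathway not in loads.columns:
        raise KeyError(f"pathway {pathway!r} not in annotation")
    col = loads[pathway]
    peak = col.max()
    if peak == 0:
        raise ValueError(f"no disease loads on pathway {pathway!r}")
    return {d: float(1.0 + strength * col[d] / peak) for d in loads.index}


# ---------------------------------------------------------------------------
# expression studies

EXPRESSION_GROUPS = ("AD", "MCI", "control")
_MCI_ATTENUATION = 0.5  # intermediate phenotype: half the case shift


def _gene_effect_factor(gene: str, heterogeneity: float) -> float:
    """Deterministic per-gene effect multiplier in [1-h, 1+h]."""
    if heterogeneity == 0:
        return 1.0
    u = zlib.crc32(gene.encode()) % 10_000 / 10_000  # stable across runs
    return 1.0 + heterogeneity * (2.0 * u - 1.0)


def simulate_expression_study(
    config: SimulationConfig,
    annotation: PathwayAnnotation,
    rng: np.random.Generator | None = None,
) -> ExpressionStudy:
    """Expression matrix over the gene universe with one dysregulated pathway.

    Genes of ``config.dysregulated_pathway`` are shifted upward by
    ``effect_size * noise_sd`` in AD samples (MCI samples get half the
    shift, emulating an intermediate phenotype); all other expression is
    baseline plus Gaussian noise. Covariates (age, sex, centre) are drawn
    independently of diagnosis, so under the null the per-gene GLM is
    exercised without confounding.

    With ``effect_heterogeneity`` h > 0 each pathway gene's shift is
    scaled by a factor in [1-h, 1+h] that is a deterministic function of
    the gene name: independently simulated studies then share the same
    per-gene dysregulation profile, the way two cohorts measuring the
    same biology would, which is what makes cross-study p-value
    concordance recoverable.
    """
    if rng is None:
        rng = stage_rng(config.seed, "expression")
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    n_per = config.n_samples_per_group
    n_total = n_per * len(EXPRESSION_GROUPS)
    diagnosis = np.repeat(EXPRESSION_GROUPS, n_per)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]

    baseline = rng.normal(8.0, 2.0, size=config.n_genes)
    expr = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_total)
    )
    if config.dysregulated_pathway is not None:
        if config.dysregulated_pathway not in annotation:
            raise KeyError(
                f"dysregulated pathway {config.dysregulated_pathway!r} "
                "not in annotation"
            )
        members = annotation.pathways[config.dysregulated_pathway]
        g_idx = [i for i, g in enumerate(genes) if g in members]
        base_shift = config.effect_size * config.noise_sd
        shifts = np.array(
            [base_shift * _gene_effect_factor(genes[i], config.effect_heterogeneity)
             for i in g_idx]
        )
        expr[np.ix_(g_idx, np.flatnonzero(diagnosis == "AD"))] += shifts[:, None]
        expr[np.ix_(g_idx, np.flatnonzero(diagnosis == "MCI"))] += (
            shifts[:, None] * _MCI_ATTENUATION
        )

    samples = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "age": np.clip(rng.normal(75, 7, size=n_total), 55, 95).round(1),
            "sex": np.where(rng.random(n_total) < 0.5, "F", "M"),
            "centre": rng.integers(1, 4, size=n_total).astype(str),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expression = pd.DataFrame(expr, index=genes, columns=sample_ids)
    return ExpressionStudy(expression, samples)


# ---------------------------------------------------------------------------
# qPCR plates

HOUSEKEEPING_GENES = ("Hprt1", "Actb")
_BASE_CT = {"housekeeping": 20.0, "target": 25.0}


def simulate_qpcr_plate(
    fold_changes: Mapping[str, float],
    n_replicates: int = 3,
    seed: int = 0,
    n_samples_per_group: int = 5,
    replicate_sd: float = 0.05,
    sample_sd: float = 0.3,
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
    control_group: str = "PBS",
    treated_group: str = "Abeta",
) -> QpcrPlate:
    """CT table encoding the requested fold changes exactly in expectation.

    Each biological sample carries an RNA-input offset (``sample_sd``
    cycles) applied to every gene, which the housekeeping normalisation
    must cancel; replicate noise (``replicate_sd`` cycles) sits on top.
    A target with fold change f has its treated-group CT lowered by
    log2(f) cycles, so expected 2^-ddCT equals f; housekeeping genes are
    unaffected by treatment (fold 1 by construction).
    """
    if any(f <= 0 for f in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng([int(seed), _STAGE["qpcr"]])
    rows = []
    for group in (control_group, treated_group):
        for s in range(n_samples_per_group):
            sample = f"{group}_{s + 1}"
            input_offset = rng.normal(0.0, sample_sd)
            for gene in housekeeping:
                base = _BASE_CT["housekeeping"] + input_offset
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        (sample, group, gene, rep,
                         base + rng.normal(0.0, replicate_sd))
                    )
            for gene, fold in fold_changes.items():
                base = _BASE_CT["target"] + input_offset
                if group == treated_group:
                    base -= np.log2(fold)
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        (sample, group, gene, rep,
                         base + rng.normal(0.0, replicate_sd))
                    )
    data = pd.DataFrame(
        rows, columns=["sample", "group", "gene", "replicate", "ct"]
    )
    return QpcrPlate(data)
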
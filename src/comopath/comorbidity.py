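"""Pathway load, matched comorbidity ratios, and their correlation.

The *pathway load* of disease A on pathway p is the fraction of A's
gene-pathway membership incidences that fall on p:

    load(A, p) = m(A, p) / sum_rho m(A, rho)

where m(A, p) counts A's retained susceptibility genes annotated to p.
The denominator counts incidences, not genes — a gene annotated to three
pathways contributes three — which normalises away how thoroughly a
disease's genes have been annotated.

The *comorbidity ratio* of disease A with the index condition (Alzheimer's
disease, ICD-9-CM 331.0, cases aged strictly over 60) is the count of
A-coded patients among the cases divided by the count among 1:1
exactly-matched controls (matched on sex, age, race and survey year).
Finally, for each pathway, Pearson correlation asks whether load(A, p)
tracks ratioAD(A) across diseases: a pathway whose genetic burden predicts
real-world co-occurrence with the index condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import DiseaseGeneCatalog, PathwayAnnotation

AD_CODE = "331.0"


@dataclass
class DischargeCohort:
    """Hospital-discharge style patient records.

    ``records`` requires columns patient_id, age, sex, race, survey_year
    and dx_codes (a list/tuple of ICD-9-CM-style code strings per row).
    """

    records: pd.DataFrame

    REQUIRED = ("patient_id", "age", "sex", "race", "survey_year", "dx_codes")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"cohort missing columns: {missing}")
        if (self.records["age"] < 0).any():
            raise ValueError("negative ages in cohort")
        if self.records["dx_codes"].map(len).eq(0).any():
            raise ValueError("patients with empty diagnosis code list")

    def __len__(self) -> int:
        return len(self.records)

    def has_code(self, code: str, prefix: bool = True) -> pd.Series:
        """Boolean mask: patient carries ``code`` among their diagnoses.

        With ``prefix=True`` a recorded code matches if it equals ``code``
        or extends it (ICD-9-CM hierarchy, e.g. query "250" matches
        "250.1"); otherwise matching is exact.
        """
        if prefix:
            return self.records["dx_codes"].map(
                lambda codes: any(c == code or c.startswith(code) for c in codes)
            )
        return self.records["dx_codes"].map(lambda codes: code in codes)


@dataclass
class PathwayLoadTable:
    """load(A, p) per disease x pathway, with the raw counts m(A, p).

    ``loads`` and ``gene_counts`` are DataFrames indexed by disease with
    pathway columns; each disease's loads sum to one.
    """

    loads: pd.DataFrame
    gene_counts: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.loads.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise AssertionError("pathway loads do not sum to 1 per disease")
        if ((self.loads < 0) | (self.loads > 1)).any().any():
            raise AssertionError("pathway load outside [0, 1]")


def pathway_load(
    catalog: DiseaseGeneCatalog, annotation: PathwayAnnotation
) -> PathwayLoadTable:
    """Compute the pathway-load table for every disease in the catalog.

    Diseases none of whose retained genes carry any pathway annotation
    have an undefined load and are excluded with a warning.
    """
    pathway_ids = sorted(annotation.pathways)
    rows: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    pid_index = {p: i for i, p in enumerate(pathway_ids)}
    for disease in sorted(catalog.diseases):
        m = np.zeros(len(pathway_ids), dtype=np.int64)
        for gene in catalog.gene_set(disease):
            for p in annotation.pathways_of(gene):
                m[pid_index[p]] += 1
        if m.sum() == 0:
            skipped.append(disease)
            continue
        rows[disease] = m
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} disease(s) with no pathway-annotated genes",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no disease has pathway-annotated genes")
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=pathway_ids)
    loads = counts.div(counts.sum(axis=1), axis=0)
    return PathwayLoadTable(loads=loads, gene_counts=counts)


# ---------------------------------------------------------------------------
# case selection and matching


def select_ad_cases(
    cohort: DischargeCohort,
    ad_code: str = AD_CODE,
    min_age: int = 60,
    prefix: bool = True,
) -> pd.DataFrame:
    """Patients carrying the index-condition code and aged strictly over
    ``min_age`` (late-onset restriction)."""
    mask = cohort.has_code(ad_code, prefix=prefix) & (cohort.records["age"] > min_age)
    return cohort.records[mask]


@dataclass
class MatchedCohort:
    """1:1 matched case-control sample.

    ``cases`` and ``controls`` are row-aligned: ``controls.iloc[k]`` is the
    match of ``cases.iloc[k]``. ``n_dropped`` counts cases for which no
    eligible control remained.
    """

    cases: pd.DataFrame
    controls: pd.DataFrame
    keys: tuple[str, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.cases) != len(self.controls):
            raise ValueError("cases and controls not 1:1")

    def __len__(self) -> int:
        return len(self.cases)


def match_controls(
    cases: pd.DataFrame,
    cohort: DischargeCohort,
    keys: Sequence[str] = ("sex", "age", "race", "survey_year"),
    seed: int = 0,
    ad_code: str = AD_CODE,
    age_caliper: int = 0,
    prefix: bool = True,
) -> MatchedCohort:
    """Find one control per case, matched exactly on ``keys``.

    Controls are cohort patients without the index-condition code.
    Matching is without replacement: cases are processed in a seeded random
    order and each draws a uniformly random eligible control, so ties for
    scarce controls are broken reproducibly. Cases with no remaining exact
    match are dropped and counted. ``age_caliper`` > 0 relaxes the age
    component of the key to +/- that many years.
    """
    if cases.empty:
        raise ValueError("no cases to match")
    pool = cohort.records[~cohort.has_code(ad_code, prefix=prefix)]
    rng = np.random.default_rng(seed)

    non_age_keys = tuple(k for k in keys if k != "age")
    use_age = "age" in keys

    # bucket control row labels by non-age key, then by age, for caliper lookup
    buckets: dict[tuple, dict[int, list]] = {}
    pool_keys = zip(*(pool[k].to_numpy() for k in non_age_keys))
    pool_ages = pool["age"].to_numpy() if use_age else np.zeros(len(pool), int)
    for idx, key, age in zip(pool.index, pool_keys, pool_ages):
        buckets.setdefault(key, {}).setdefault(int(age), []).append(idx)

    case_keys = list(zip(*(cases[k].to_numpy() for k in non_age_keys)))
    case_ages = cases["age"].to_numpy() if use_age else np.zeros(len(cases), int)
    order = rng.permutation(len(cases))
    matched_case_pos: list[int] = []
    matched_control_idx: list = []
    taken: set = set()
    n_dropped = 0
    for pos in order:
        by_age = buckets.get(case_keys[pos])
        eligible: list = []
        if by_age is not None:
            age = int(case_ages[pos])
            for a in range(age - age_caliper, age + age_caliper + 1):
                eligible.extend(i for i in by_age.get(a, ()) if i not in taken)
        if not eligible:
            n_dropped += 1
            continue
        pick = eligible[rng.integers(len(eligible))]
        taken.add(pick)
        matched_case_pos.append(pos)
        matched_control_idx.append(pick)
    if not matched_case_pos:
        raise ValueError("no case could be matched to a control")
    if n_dropped:
        warnings.warn(f"{n_dropped} case(s) dropped: no eligible control", stacklevel=2)
    matched_cases = cases.iloc[matched_case_pos].reset_index(drop=True)
    matched_controls = pool.loc[matched_control_idx].reset_index(drop=True)
    return MatchedCohort(matched_cases, matched_controls, tuple(keys), n_dropped)


# ---------------------------------------------------------------------------
# comorbidity ratios and the load-ratio correlation


@dataclass
class ComorbidityResult:
    """ratioAD for one disease: case count over matched-control count."""

    disease: str
    case_count: int
    control_count: int

    @property
    def total(self) -> int:
        return self.case_count + self.control_count

    @property
    def ratio(self) -> float:
        if self.control_count == 0:
            raise ZeroDivisionError("ratio undefined with zero control count")
        return self.case_count / self.control_count


def comorbidity_ratios(
    matched: MatchedCohort,
    disease_codes: Mapping[str, str],
    min_patients: int = 15,
    prefix: bool = True,
) -> list[ComorbidityResult]:
    """ratioAD(A) for each disease with adequate support in the matched sample.

    A disease enters only if strictly more than ``min_patients`` patients
    carry its code across cases and matched controls combined. Diseases
    whose matched controls contain no carrier have an undefined ratio and
    are excluded with a warning.
    """

    def count(frame: pd.DataFrame, code: str) -> int:
        if prefix:
            m = frame["dx_codes"].map(
                lambda cs: any(c == code or c.startswith(code) for c in cs)
            )
        else:
            m = frame["dx_codes"].map(lambda cs: code in cs)
        return int(m.sum())

    out: list[ComorbidityResult] = []
    for disease, code in sorted(disease_codes.items()):
        res = ComorbidityResult(
            disease,
            case_count=count(matched.cases, code),
            control_count=count(matched.controls, code),
        )
        if res.total <= min_patients:
            continue
        if res.control_count == 0:
            warnings.warn(
                f"disease {disease!r}: no carriers among matched controls; "
                "ratio undefined, excluded",
                stacklevel=2,
            )
            continue
        out.append(res)
    return out


@dataclass
class LoadRatioCorrelation:
    """Pearson correlation of load(A, p) against ratioAD(A) for one pathway."""

    pathway: str
    n_diseases: int
    r: float
    p_value: float
    p_bonferroni: float = float("nan")

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def correlate_load_vs_ratio(
    loads: PathwayLoadTable,
    ratios: Iterable[ComorbidityResult],
    subset: Sequence[str] | None = None,
) -> list[LoadRatioCorrelation]:
    """Per-pathway Pearson correlation of pathway load against ratioAD.

    Diseases must appear in both tables (and in ``subset`` when given);
    at least three are required. Pathways whose load vector is constant
    across the entering diseases carry no information and are skipped.
    Bonferroni correction is over the pathways actually tested; output is
    sorted by p-value.
    """
    ratio_map = {r.disease: r.ratio for r in ratios}
    diseases = [d for d in loads.loads.index if d in ratio_map]
    if subset is not None:
        keep = set(subset)
        diseases = [d for d in diseases if d in keep]
    if len(diseases) < 3:
        raise ValueError(
            f"need >=3 diseases in both tables, have {len(diseases)}"
        )
    y = np.array([ratio_map[d] for d in diseases])
    results: list[LoadRatioCorrelation] = []
    n_constant = 0
    for pathway in loads.loads.columns:
        x = loads.loads.loc[diseases, pathway].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_constant += 1
            continue
        r, p = stats.pearsonr(x, y)
        results.append(
            LoadRatioCorrelation(pathway, len(diseases), float(r), float(p))
        )
    if n_constant:
        warnings.warn(
            f"{n_constant} pathway(s) skipped with constant load vector",
            stacklevel=2,
        )
    m = len(results)
    for res in results:
        res.p_bonferroni = min(1.0, res.p_value * m)
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def correlations_to_frame(results: Iterable[LoadRatioCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "n": [r.n_diseases for r in results],
            "r": [r.r for r in results],
            "p": [r.p_value for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
        }
    )
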
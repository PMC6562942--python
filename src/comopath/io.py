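"""Readers and writers for the pipeline's plain-text formats.

Formats: GMT for pathway annotations; TSV for the disease-gene catalog,
expression matrices, sample sheets and stage results; CSV for discharge
cohorts (semicolon-separated diagnosis codes) and qPCR plates. Every file
written here starts with a comment header naming the tool version, the
configuration hash and the seed, and every reader validates rather than
coercing: malformed lines raise with their line number.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from . import __version__
from .catalog import DiseaseGeneCatalog, PathwayAnnotation
from .comorbidity import DischargeCohort
from .expression import ExpressionStudy
from .qpcr import QpcrPlate

COMMENT = "#"


def config_hash(config: Mapping[str, Any] | Any) -> str:
    """Short deterministic digest of a configuration mapping/dataclass."""
    if hasattr(config, "__dataclass_fields__"):
        from dataclasses import asdict

        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def file_header(seed: int | None = None, cfg_hash: str | None = None) -> str:
    parts = [f"{COMMENT} comopath v{__version__}"]
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " | ".join(parts)


def _open_lines(path: str | Path) -> list[tuple[int, str]]:
    """Non-comment, non-blank lines with their 1-based line numbers."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(COMMENT):
                continue
            out.append((lineno, line))
    return out


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> PathwayAnnotation:
    """Read a GMT pathway file: pathway id, description, then member genes.

    Duplicate genes within a line are deduplicated; a duplicate pathway id
    across lines or a line with fewer than three fields is an error
    reported with its line number.
    """
    pathways: dict[str, frozenset[str]] = {}
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                f"(id, description, genes...), got {len(fields)}"
            )
        pid = fields[0]
        if pid in pathways:
            raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no genes")
        pathways[pid] = genes
    return PathwayAnnotation(pathways)


def write_gmt(
    annotation: PathwayAnnotation,
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
    header: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for pid in sorted(annotation.pathways):
            desc = (descriptions or {}).get(pid, "na")
            genes = "\t".join(sorted(annotation.pathways[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# disease-gene catalog TSV

CATALOG_COLUMNS = ("disease_id", "gene", "p_value")


def read_catalog(
    path: str | Path, min_genes: int = 25, top_k: int = 25
) -> DiseaseGeneCatalog:
    """Read a (disease_id, gene, p_value) TSV and apply the catalog filter."""
    lines = _open_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty catalog file")
    first = lines[0][1].split("\t")
    if tuple(first) != CATALOG_COLUMNS:
        raise ValueError(
            f"{path}:{lines[0][0]}: expected header {CATALOG_COLUMNS}, got {first}"
        )
    assoc: dict[str, list[tuple[str, float]]] = {}
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        disease, gene, p_raw = fields
        try:
            p = float(p_raw)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad p-value {p_raw!r}") from exc
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{path}:{lineno}: p-value {p} outside [0, 1]")
        assoc.setdefault(disease, []).append((gene, p))
    return DiseaseGeneCatalog.from_associations(assoc, min_genes=min_genes, top_k=top_k)


def write_catalog(
    catalog: DiseaseGeneCatalog, path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for disease in sorted(catalog.diseases):
            for gene, p in catalog.diseases[disease]:
                fh.write(f"{disease}\t{gene}\t{p:.6g}\n")


# ---------------------------------------------------------------------------
# discharge cohort CSV

COHORT_COLUMNS = ("patient_id", "age", "sex", "race", "survey_year", "dx_codes")


def read_cohort(path: str | Path) -> DischargeCohort:
    """Read a cohort CSV; dx_codes is a semicolon-separated code list."""
    frame = pd.read_csv(path, comment=COMMENT, dtype=str)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: cohort missing columns {missing}")
    try:
        frame["age"] = frame["age"].astype(int)
        frame["survey_year"] = frame["survey_year"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer age or survey_year") from exc
    if frame["dx_codes"].isna().any():
        raise ValueError(f"{path}: records with empty dx_codes")
    frame["dx_codes"] = frame["dx_codes"].map(
        lambda s: tuple(c for c in s.split(";") if c)
    )
    return DischargeCohort(frame)


def write_cohort(
    cohort: DischargeCohort, path: str | Path, header: str | None = None
) -> None:
    out = cohort.records.copy()
    out["dx_codes"] = out["dx_codes"].map(";".join)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        out.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# expression TSV + sample sheet

SAMPLE_COLUMNS = ("sample_id", "diagnosis", "age", "sex", "centre")


def read_expression(matrix_path: str | Path, samples_path: str | Path) -> ExpressionStudy:
    """Read a genes x samples TSV plus its sample sheet."""
    expr = pd.read_csv(matrix_path, sep="\t", comment=COMMENT, index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", comment=COMMENT, dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"{samples_path}: sample sheet missing columns {missing}")
    samples = samples.set_index("sample_id")
    samples["age"] = samples["age"].astype(float)
    if set(expr.columns) != set(samples.index):
        raise ValueError("expression matrix and sample sheet name different samples")
    return ExpressionStudy(expr, samples.loc[expr.columns])


def write_expression(
    study: ExpressionStudy,
    matrix_path: str | Path,
    samples_path: str | Path,
    header: str | None = None,
) -> None:
    with open(matrix_path, "w") as fh:
        if header:
            fh.write(header + "\n")
        study.expression.to_csv(fh, sep="\t", float_format="%.6g")
    with open(samples_path, "w") as fh:
        if header:
            fh.write(header + "\n")
        study.samples.rename_axis("sample_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# qPCR CSV

QPCR_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


def read_qpcr(path: str | Path) -> QpcrPlate:
    frame = pd.read_csv(path, comment=COMMENT, dtype=str)
    missing = [c for c in QPCR_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: qPCR table missing columns {missing}")
    try:
        frame["replicate"] = frame["replicate"].astype(int)
        frame["ct"] = frame["ct"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric replicate or CT") from exc
    return QpcrPlate(frame)


def write_qpcr(plate: QpcrPlate, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        plate.data.to_csv(fh, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# generic results tables


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    header: str | None = None,
    index: bool = False,
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def write_json(obj: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def gmt_descriptions(pathways: Iterable[str]) -> dict[str, str]:
    return {p: "synthetic pathway" for p in pathways}
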
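import numpy as np
import pandas as pd
import pytest

from comopath import (
    DiseaseGeneCatalog,
    PathwayAnnotation,
    DischargeCohort,
    QpcrPlate,
)


@pytest.fixture
def tiny_annotation() -> PathwayAnnotation:
    return PathwayAnnotation(
        {
            "P1": frozenset({"G1", "G2", "G3"}),
            "P2": frozenset({"G1", "G2", "G4"}),
            "P3": frozenset({"G2", "G5"}),
        }
    )


@pytest.fixture
def tiny_catalog() -> DiseaseGeneCatalog:
    # two 3-gene diseases, no filtering
    return DiseaseGeneCatalog.from_associations(
        {
            "DA": [("G1", 1e-8), ("G2", 1e-6), ("G5", 1e-4)],
            "DB": [("G3", 1e-7), ("G4", 1e-5), ("G6", 1e-3)],
        },
        min_genes=3,
        top_k=3,
    )


def random_annotation(
    rng: np.random.Generator, n_genes: int = 50, n_pathways: int = 12
) -> PathwayAnnotation:
    genes = [f"G{i:03d}" for i in range(n_genes)]
    pathways = {}
    for p in range(n_pathways):
        size = int(rng.integers(3, 9))
        pathways[f"P{p:02d}"] = frozenset(rng.choice(genes, size, replace=False))
    return PathwayAnnotation(pathways)


def make_cohort(rows) -> DischargeCohort:
    """rows: iterable of (age, sex, race, year, codes)"""
    frame = pd.DataFrame(
        [
            {
                "patient_id": f"P{i:05d}",
                "age": age,
                "sex": sex,
                "race": race,
                "survey_year": year,
                "dx_codes": tuple(codes),
            }
            for i, (age, sex, race, year, codes) in enumerate(rows)
        ]
    )
    return DischargeCohort(frame)


def make_plate(records) -> QpcrPlate:
    """records: iterable of (sample, group, gene, replicate, ct)"""
    return QpcrPlate(
        pd.DataFrame(records, columns=["sample", "group", "gene", "replicate", "ct"])
    )
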
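"""Core containers: disease-gene catalogs and pathway annotations.

A :class:`DiseaseGeneCatalog` holds, per disease, the ranked susceptibility
genes from an association study (gene symbol plus association p-value).
Following common practice for pathway-space comparisons of association
results, only diseases with at least ``min_genes`` associated genes are
retained, and within each disease only the ``top_k`` most strongly
associated genes (smallest p-values) are kept, so that every disease
contributes a comparably sized gene set.

A :class:`PathwayAnnotation` maps pathway identifiers to gene sets
(GMT-style, KEGG-like) and maintains the inverse gene-to-pathways map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class PathwayAnnotation:
    """Pathway -> gene-set annotation with a consistent inverse map.

    Parameters
    ----------
    pathways
        Mapping from pathway id to the set of member gene symbols.
        Empty pathways are rejected.
    planted
        Optional provenance of synthetic planting (pathway ids carrying a
        simulated effect); empty for annotations read from file.
    """

    pathways: dict[str, frozenset[str]]
    planted: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for pid, genes in self.pathways.items():
            gs = frozenset(genes)
            if not gs:
                raise ValueError(f"pathway {pid!r} has no member genes")
            clean[pid] = gs
        object.__setattr__(self, "pathways", clean)
        inverse: dict[str, set[str]] = {}
        for pid, gs in clean.items():
            for g in gs:
                inverse.setdefault(g, set()).add(pid)
        object.__setattr__(
            self, "_gene_to_pathways", {g: frozenset(ps) for g, ps in inverse.items()}
        )

    @property
    def gene_to_pathways(self) -> dict[str, frozenset[str]]:
        return self._gene_to_pathways  # type: ignore[attr-defined]

    def pathways_of(self, gene: str) -> frozenset[str]:
        """Pathway ids containing ``gene`` (empty set if unannotated)."""
        return self.gene_to_pathways.get(gene, frozenset())

    def genes(self) -> frozenset[str]:
        """Union of all annotated genes."""
        return frozenset(self.gene_to_pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, pathway: str) -> bool:
        return pathway in self.pathways

    def subset(self, pathway_ids: Iterable[str]) -> "PathwayAnnotation":
        keep = set(pathway_ids)
        return PathwayAnnotation({p: g for p, g in self.pathways.items() if p in keep})


@dataclass(frozen=True)
class DiseaseGeneCatalog:
    """Per-disease ranked susceptibility genes.

    ``diseases`` maps each disease id to its retained (gene, p-value) list,
    sorted ascending by p-value. Construction applies the standard filter:
    drop diseases with fewer than ``min_genes`` genes and truncate each
    remaining disease to its ``top_k`` strongest associations. Equal
    p-values are broken by input order, then gene symbol, so the retained
    set is deterministic.
    """

    diseases: dict[str, tuple[tuple[str, float], ...]]
    min_genes: int = 25
    top_k: int = 25

    @classmethod
    def from_associations(
        cls,
        associations: Mapping[str, Sequence[tuple[str, float]]],
        min_genes: int = 25,
        top_k: int = 25,
    ) -> "DiseaseGeneCatalog":
        """Build a catalog from raw per-disease association lists.

        Duplicate gene entries within a disease keep the strongest
        (smallest-p) record. Diseases falling below ``min_genes`` after
        deduplication are dropped with a warning.
        """
        retained: dict[str, tuple[tuple[str, float], ...]] = {}
        dropped: list[str] = []
        for disease, assoc in associations.items():
            best: dict[str, tuple[float, int]] = {}
            for idx, (gene, p) in enumerate(assoc):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"association p-value {p!r} for {disease}/{gene} outside [0, 1]"
                    )
                if gene not in best or p < best[gene][0]:
                    best[gene] = (p, idx)
            if len(best) < min_genes:
                dropped.append(disease)
                continue
            ranked = sorted(best.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]))
            retained[disease] = tuple((g, p) for g, (p, _) in ranked[:top_k])
        if dropped:
            warnings.warn(
                f"dropped {len(dropped)} disease(s) with fewer than "
                f"{min_genes} associated genes: {', '.join(sorted(dropped)[:5])}"
                + ("..." if len(dropped) > 5 else ""),
                stacklevel=2,
            )
        return cls(retained, min_genes=min_genes, top_k=top_k)

    def __post_init__(self) -> None:
        for disease, assoc in self.diseases.items():
            genes = [g for g, _ in assoc]
            if len(genes) != len(set(genes)):
                raise ValueError(f"duplicate genes in disease {disease!r}")
            ps = [p for _, p in assoc]
            if any(b < a for a, b in zip(ps, ps[1:])):
                raise ValueError(f"genes of {disease!r} not sorted by p-value")

    def gene_set(self, disease: str) -> frozenset[str]:
        return frozenset(g for g, _ in self.diseases[disease])

    def gene_universe(self) -> tuple[str, ...]:
        """Sorted union of every disease's retained genes."""
        out: set[str] = set()
        for assoc in self.diseases.values():
            out.update(g for g, _ in assoc)
        return tuple(sorted(out))

    def __len__(self) -> int:
        return len(self.diseases)

    def __contains__(self, disease: str) -> bool:
        return disease in self.diseases
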
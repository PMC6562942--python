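"""Shared-pathway disease overlap analysis.

Two diseases are compared in *pathway space* rather than gene space: for
every pair of genes (α, β) the matrix entry n(α, β) counts the pathways
the two genes share. For diseases A and B the sample S+ collects n(α, β)
over cross pairs with α in A's gene set and β in B's, while S− collects
the counts for pairs where exactly one gene belongs to the corresponding
disease set (the partner ranging over the full retained gene universe).
A one-tailed Wilcoxon rank-sum test of S+ against S− then asks whether
A's and B's susceptibility genes co-occur in pathways more than expected
from the catalog-wide background.

Self pairs (α = β) are excluded from both samples so that a gene
associated with both diseases cannot drive the signal through the
pathways it trivially shares with itself; the test is thereby a test of
shared *pathways*, not shared *genes*.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .catalog import DiseaseGeneCatalog, PathwayAnnotation

MIN_SAMPLE = 3  # below this, the rank-sum test is not attempted
EXACT_MAX = 8  # exact enumeration when both samples are at most this size


@dataclass
class SharedPathwayMatrix:
    """Symmetric gene x gene matrix of shared-pathway counts n(α, β).

    ``genes`` is the ordered gene universe; ``counts[i, j]`` is the number
    of pathways genes i and j are both annotated to. The diagonal holds
    each gene's own pathway-membership count; genes absent from the
    annotation have all-zero rows.
    """

    genes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match gene universe")
        self._index = {g: i for i, g in enumerate(self.genes)}
        # condensed upper triangle, cached for repeated pair tests
        self._iu, self._ju = np.triu_indices(n, k=1)
        self._pair_values = self.counts[self._iu, self._ju]

    def validate(self) -> None:
        """Assert symmetry and the min-of-diagonals bound."""
        c = self.counts
        if not np.array_equal(c, c.T):
            raise AssertionError("shared-pathway matrix not symmetric")
        if (c < 0).any():
            raise AssertionError("negative shared-pathway count")
        d = np.diag(c)
        bound = np.minimum.outer(d, d)
        off = ~np.eye(len(d), dtype=bool)
        if (c[off] > bound[off]).any():
            raise AssertionError("n(α,β) exceeds min(|pathways(α)|, |pathways(β)|)")

    def value(self, gene_a: str, gene_b: str) -> int:
        return int(self.counts[self._index[gene_a], self._index[gene_b]])

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.fromiter(
            (self._index[g] for g in genes if g in self._index), dtype=np.intp
        )


def build_shared_matrix(
    catalog: DiseaseGeneCatalog, annotation: PathwayAnnotation
) -> SharedPathwayMatrix:
    """Count, for every gene pair of the catalog universe, the pathways shared.

    The universe is the sorted union of all diseases' retained genes. With
    the binary membership matrix M (genes x pathways), the count matrix is
    M Mᵀ; its diagonal is each gene's membership count.
    """
    genes = catalog.gene_universe()
    if not genes:
        raise ValueError("empty catalog: no retained genes")
    pathway_ids = sorted(annotation.pathways)
    pid_index = {p: i for i, p in enumerate(pathway_ids)}
    m = np.zeros((len(genes), len(pathway_ids)), dtype=np.int64)
    for gi, g in enumerate(genes):
        for p in annotation.pathways_of(g):
            m[gi, pid_index[p]] = 1
    counts = m @ m.T
    matrix = SharedPathwayMatrix(genes, counts)
    matrix.validate()
    return matrix


# ---------------------------------------------------------------------------
# one-tailed rank-sum machinery


def rank_sum_greater(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum test of H1: x stochastically greater than y.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of x over y.
    Heavy ties are expected (shared-pathway counts are small integers), so
    ranks are midranks and the normal approximation uses the tie-corrected
    variance with a continuity correction. When both samples have at most
    :data:`EXACT_MAX` observations the permutation distribution of U is
    enumerated exactly instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    if n1 <= EXACT_MAX and n2 <= EXACT_MAX:
        return u, _exact_permutation_p(ranks, n1)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations tied: no evidence either way
        return u, 1.0
    z = (u - mu - 0.5) / np.sqrt(var)
    return u, float(stats.norm.sf(z))


def _exact_permutation_p(ranks: np.ndarray, n1: int) -> float:
    """P(rank-sum of a random n1-subset >= observed), enumerated exactly.

    Conditions on the observed (midrank) configuration, so ties are exact.
    """
    observed = ranks[:n1].sum()
    total = 0
    hits = 0
    for idx in combinations(range(len(ranks)), n1):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            hits += 1
    return hits / total


@dataclass
class OverlapTestResult:
    """Result of the pathway-space overlap test for one disease pair."""

    disease_a: str
    disease_b: str
    n_splus: int
    n_sminus: int
    statistic: float
    p_value: float
    p_bonferroni: float = float("nan")
    low_sample: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def overlap_test(
    disease_a: str,
    disease_b: str,
    matrix: SharedPathwayMatrix,
    catalog: DiseaseGeneCatalog,
) -> OverlapTestResult:
    """Test whether diseases A and B overlap in pathway space.

    S+ holds n(α, β) for unordered gene pairs with one gene in A's set and
    the other in B's; S− holds the counts for pairs touching exactly the
    relevant sets on one side only, the partner drawn from the whole
    retained gene universe. Unordered pairs enter each sample once and the
    diagonal (α = β) enters neither. If either sample has fewer than
    :data:`MIN_SAMPLE` values the test is not attempted and p = 1 is
    returned with ``low_sample`` set.
    """
    if disease_a == disease_b:
        raise ValueError("overlap test requires two distinct diseases")
    for d in (disease_a, disease_b):
        if d not in catalog:
            raise KeyError(f"disease {d!r} not in catalog")
    n = len(matrix.genes)
    a = np.zeros(n, dtype=bool)
    a[matrix.indices(catalog.gene_set(disease_a))] = True
    b = np.zeros(n, dtype=bool)
    b[matrix.indices(catalog.gene_set(disease_b))] = True

    i, j = matrix._iu, matrix._ju
    in_splus = (a[i] & b[j]) | (a[j] & b[i])
    touches = a[i] | b[i] | a[j] | b[j]
    in_sminus = touches & ~in_splus
    splus = matrix._pair_values[in_splus]
    sminus = matrix._pair_values[in_sminus]

    if len(splus) < MIN_SAMPLE or len(sminus) < MIN_SAMPLE:
        return OverlapTestResult(
            disease_a, disease_b, len(splus), len(sminus),
            statistic=float("nan"), p_value=1.0, low_sample=True,
        )
    u, p = rank_sum_greater(splus, sminus)
    return OverlapTestResult(disease_a, disease_b, len(splus), len(sminus), u, p)


@dataclass
class OverlapSummary:
    """All-pairs overlap results plus the significance graph.

    ``adjacency`` is the symmetric 0/1 disease x disease matrix of pairs
    significant after correction; ``components`` groups diseases into
    connected components of that graph (the paper-style "cluster" readout
    is the component structure together with per-disease significant-
    neighbour counts — no parametric clustering algorithm is applied).
    """

    results: list[OverlapTestResult]
    adjacency: pd.DataFrame
    alpha: float
    correction: str

    @property
    def n_pairs(self) -> int:
        return len(self.results)

    @property
    def significant_pairs(self) -> list[OverlapTestResult]:
        return [r for r in self.results if r.p_bonferroni < self.alpha]

    def neighbour_counts(self) -> pd.Series:
        """Number of significantly overlapping partners per disease."""
        return self.adjacency.sum(axis=1).astype(int)

    def components(self) -> list[frozenset[str]]:
        labels = self.adjacency.index
        n_comp, assignment = connected_components(
            csr_matrix(self.adjacency.values), directed=False
        )
        return [
            frozenset(labels[assignment == c]) for c in range(n_comp)
        ]

    def subset_pair_count(self, diseases: Sequence[str]) -> tuple[int, int]:
        """(significant, total) unordered pairs within a disease subset."""
        ds = [d for d in diseases if d in self.adjacency.index]
        total = len(ds) * (len(ds) - 1) // 2
        sig = sum(
            int(self.adjacency.loc[x, y]) for x, y in combinations(ds, 2)
        )
        return sig, total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disease_a": [r.disease_a for r in self.results],
                "disease_b": [r.disease_b for r in self.results],
                "n_splus": [r.n_splus for r in self.results],
                "n_sminus": [r.n_sminus for r in self.results],
                "statistic": [r.statistic for r in self.results],
                "p": [r.p_value for r in self.results],
                "p_adj": [r.p_bonferroni for r in self.results],
                "significant": [r.p_bonferroni < self.alpha for r in self.results],
            }
        )


def all_pairs_overlap(
    catalog: DiseaseGeneCatalog,
    matrix: SharedPathwayMatrix,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> OverlapSummary:
    """Run the overlap test on every unordered disease pair.

    The multiple-testing family is the set of tested pairs. The default
    family-wise correction is Bonferroni; Benjamini-Hochberg step-up is
    available with ``correction="bh_fdr"`` (the adjusted values are then
    q-values rather than Bonferroni-adjusted p-values).
    """
    diseases = sorted(catalog.diseases)
    if len(diseases) < 2:
        raise ValueError("need at least two diseases for pairwise overlap")
    results = [
        overlap_test(a, b, matrix, catalog) for a, b in combinations(diseases, 2)
    ]
    m = len(results)
    if correction == "bonferroni":
        for r in results:
            r.p_bonferroni = min(1.0, r.p_value * m)
    elif correction == "bh_fdr":
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        for r, q in zip(results, p_adj):
            r.p_bonferroni = float(q)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    adj = pd.DataFrame(
        np.zeros((len(diseases), len(diseases)), dtype=int),
        index=diseases,
        columns=diseases,
    )
    for r in results:
        if r.p_bonferroni < alpha:
            adj.loc[r.disease_a, r.disease_b] = 1
            adj.loc[r.disease_b, r.disease_a] = 1
    return OverlapSummary(results, adj, alpha, correction)
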
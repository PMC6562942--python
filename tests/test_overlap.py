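"""Shared-pathway matrix construction and the pathway-space overlap test."""

import itertools
import math

import numpy as np
import pytest

from comopath import (
    DiseaseGeneCatalog,
    PathwayAnnotation,
    all_pairs_overlap,
    build_shared_matrix,
    overlap_test,
    rank_sum_greater,
)
from conftest import random_annotation


def mwu_enumeration_oracle(x, y):
    """One-sided permutation p for H1 'x greater', via the U statistic.

    Counts, over all assignments of the combined values to the two group
    sizes, how often U (number of (x, y) pairs with x > y, plus half the
    ties) is at least the observed U. Independent of the rank-based
    implementation under test.
    """

    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys
        )

    combined = list(x) + list(y)
    observed = u_stat(x, y)
    n1 = len(x)
    hits = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in set(idx)]
        hits += u_stat(xs, ys) >= observed - 1e-9
        total += 1
    return hits / total


class TestSharedMatrix:
    def test_pairwise_intersection_counts(self):
        ann = PathwayAnnotation(
            {
                "P1": {"A", "B"},
                "P2": {"A", "B", "C"},
                "P3": {"C", "D"},
                "P4": {"A", "E"},
            }
        )
        cat = DiseaseGeneCatalog.from_associations(
            {"D1": [("A", 0.01), ("C", 0.02)], "D2": [("B", 0.01), ("D", 0.03)]},
            min_genes=2,
            top_k=2,
        )
        m = build_shared_matrix(cat, ann)
        # A in {P1,P2,P4}, B in {P1,P2} -> 2 shared
        assert m.value("A", "B") == 2
        assert m.value("A", "D") == 0
        # diagonal counts the gene's own memberships
        assert m.value("A", "A") == 3
        assert m.value("C", "C") == 2

    def test_unannotated_gene_has_zero_row(self, tiny_annotation):
        cat = DiseaseGeneCatalog.from_associations(
            {"D1": [("G1", 0.01), ("GX", 0.02)], "D2": [("G2", 0.01), ("G3", 0.03)]},
            min_genes=2,
            top_k=2,
        )
        m = build_shared_matrix(cat, tiny_annotation)
        i = m.genes.index("GX")
        assert m.counts[i].sum() == 0 and m.counts[i, i] == 0

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(7)
        ann = random_annotation(rng, n_genes=50, n_pathways=12)
        genes = sorted(ann.genes())
        half = len(genes) // 2
        cat = DiseaseGeneCatalog.from_associations(
            {
                "D1": [(g, 0.001 * (i + 1)) for i, g in enumerate(genes[:half])],
                "D2": [(g, 0.001 * (i + 1)) for i, g in enumerate(genes[half:])],
            },
            min_genes=10,
            top_k=half,
        )
        m = build_shared_matrix(cat, ann)
        for a in m.genes:
            for b in m.genes:
                expected = len(ann.pathways_of(a) & ann.pathways_of(b))
                assert m.value(a, b) == expected

    def test_empty_catalog_rejected(self, tiny_annotation):
        cat = DiseaseGeneCatalog({})
        with pytest.raises(ValueError, match="empty catalog"):
            build_shared_matrix(cat, tiny_annotation)


class TestRankSum:
    @pytest.mark.parametrize("n1", range(1, 9))
    @pytest.mark.parametrize("n2", range(1, 9))
    def test_exact_path_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        x = rng.integers(0, 4, size=n1)  # heavy ties, like shared-pathway counts
        y = rng.integers(0, 4, size=n2)
        _, p = rank_sum_greater(x, y)
        assert p == pytest.approx(mwu_enumeration_oracle(x, y), abs=1e-10)

    def test_all_tied_values_give_p_one(self):
        _, p = rank_sum_greater(np.full(5, 2.0), np.full(6, 2.0))
        assert p == 1.0
        # asymptotic path: variance is zero under complete ties
        _, p = rank_sum_greater(np.full(20, 2.0), np.full(30, 2.0))
        assert p == 1.0

    def test_complete_separation_small_samples_exact(self):
        x = np.array([10, 11, 12, 13, 14, 15])
        y = np.array([1, 2, 3, 4, 5, 6])
        _, p = rank_sum_greater(x, y)
        assert p == pytest.approx(1 / math.comb(12, 6), abs=1e-12)

    def test_complete_separation_large_samples_extreme(self):
        x = np.arange(100, 125, dtype=float)
        y = np.arange(0, 25, dtype=float)
        _, p = rank_sum_greater(x, y)
        assert p < 1e-8  # normal approximation deep in the tail

    def test_asymptotic_agrees_with_oracle_at_boundary(self):
        # just above the exact-enumeration cutoff: approximation stays close
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=9).astype(float)
        y = rng.integers(0, 5, size=9).astype(float)
        _, p = rank_sum_greater(x, y)
        assert p == pytest.approx(mwu_enumeration_oracle(x, y), abs=0.05)


@pytest.fixture
def planted_instance():
    """Five diseases; D1 and D2 share pathways through disjoint gene sets."""
    rng = np.random.default_rng(11)
    genes = [f"G{i:03d}" for i in range(60)]
    shared = {f"S{p}": frozenset(genes[:12]) for p in range(4)}  # D1+D2 genes
    noise = {
        f"N{p}": frozenset(rng.choice(genes, 5, replace=False)) for p in range(10)
    }
    ann = PathwayAnnotation({**shared, **noise})
    assoc = {}
    blocks = [genes[:6], genes[6:12], genes[12:18], genes[18:24], genes[24:30]]
    for d, block in enumerate(blocks, start=1):
        assoc[f"D{d}"] = [(g, 0.001 * (i + 1)) for i, g in enumerate(block)]
    cat = DiseaseGeneCatalog.from_associations(assoc, min_genes=6, top_k=6)
    return cat, build_shared_matrix(cat, ann)


class TestOverlapTest:
    def test_symmetry_in_disease_order(self, planted_instance):
        cat, m = planted_instance
        for a, b in [("D1", "D2"), ("D3", "D4"), ("D1", "D5")]:
            ra = overlap_test(a, b, m, cat)
            rb = overlap_test(b, a, m, cat)
            assert ra.p_value == rb.p_value
            assert ra.n_splus == rb.n_splus and ra.n_sminus == rb.n_sminus

    def test_planted_pair_beats_null_pairs(self, planted_instance):
        cat, m = planted_instance
        planted_p = overlap_test("D1", "D2", m, cat).p_value
        null_ps = [
            overlap_test(a, b, m, cat).p_value
            for a, b in itertools.combinations(["D3", "D4", "D5"], 2)
        ]
        assert planted_p < min(null_ps)
        assert planted_p < 1e-6

    def test_removing_uninvolved_pathway_changes_nothing(self, planted_instance):
        cat, _ = planted_instance
        rng = np.random.default_rng(11)
        genes = [f"G{i:03d}" for i in range(60)]
        shared = {f"S{p}": frozenset(genes[:12]) for p in range(4)}
        noise = {
            f"N{p}": frozenset(rng.choice(genes, 5, replace=False)) for p in range(10)
        }
        ann_full = PathwayAnnotation({**shared, **noise})
        # a pathway touching no gene of D1 or D2 (their genes are genes[:12])
        ab_genes = set(genes[:12])
        spare = next(
            p for p, gs in ann_full.pathways.items() if not gs & ab_genes
        )
        ann_reduced = ann_full.subset(set(ann_full.pathways) - {spare})
        p_full = overlap_test(
            "D1", "D2", build_shared_matrix(cat, ann_full), cat
        ).p_value
        p_reduced = overlap_test(
            "D1", "D2", build_shared_matrix(cat, ann_reduced), cat
        ).p_value
        assert p_full == pytest.approx(p_reduced, abs=1e-12)

    def test_tiny_samples_return_p_one_with_flag(self, tiny_annotation):
        cat = DiseaseGeneCatalog.from_associations(
            {"D1": [("G1", 0.01)], "D2": [("G2", 0.01)]}, min_genes=1, top_k=1
        )
        m = build_shared_matrix(cat, tiny_annotation)
        r = overlap_test("D1", "D2", m, cat)
        assert r.low_sample and r.p_value == 1.0

    def test_same_disease_rejected(self, planted_instance):
        cat, m = planted_instance
        with pytest.raises(ValueError):
            overlap_test("D1", "D1", m, cat)


class TestAllPairs:
    def test_pair_count_and_bonferroni_factor(self, planted_instance):
        cat, m = planted_instance
        summary = all_pairs_overlap(cat, m)
        assert summary.n_pairs == 10  # C(5, 2)
        for r in summary.results:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_value * 10))

    def test_subset_pair_count_complete_subgraph(self, planted_instance):
        cat, m = planted_instance
        summary = all_pairs_overlap(cat, m)
        sig, total = summary.subset_pair_count(["D1", "D2"])
        assert (sig, total) == (1, 1)
        _, total5 = summary.subset_pair_count(["D1", "D2", "D3", "D4", "D5"])
        assert total5 == 10

    def test_adjacency_symmetric_and_components(self, planted_instance):
        cat, m = planted_instance
        summary = all_pairs_overlap(cat, m)
        assert (summary.adjacency.values == summary.adjacency.values.T).all()
        comps = summary.components()
        assert any({"D1", "D2"} <= c for c in comps)

    def test_bh_correction_available(self, planted_instance):
        cat, m = planted_instance
        summary = all_pairs_overlap(cat, m, correction="bh_fdr")
        assert summary.correction == "bh_fdr"
        assert all(r.p_bonferroni >= r.p_value - 1e-15 for r in summary.results)
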
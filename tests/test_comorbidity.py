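"""Pathway load, case selection, exact matching, ratios and correlation."""

import warnings
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from comopath import (
    ComorbidityResult,
    DiseaseGeneCatalog,
    PathwayAnnotation,
    comorbidity_ratios,
    correlate_load_vs_ratio,
    match_controls,
    pathway_load,
    select_ad_cases,
)
from comopath.comorbidity import MatchedCohort
from conftest import make_cohort, random_annotation


def _catalog(assoc, k):
    return DiseaseGeneCatalog.from_associations(assoc, min_genes=k, top_k=k)


class TestPathwayLoad:
    def test_single_pathway_gets_full_load(self):
        ann = PathwayAnnotation({"P": {"A", "B"}})
        cat = _catalog({"D": [("A", 0.01), ("B", 0.02)]}, 2)
        table = pathway_load(cat, ann)
        assert table.loads.loc["D", "P"] == 1.0

    def test_incidence_counting_splits_load(self):
        # one gene in {P1}, one in {P1, P2}: three incidences in total
        ann = PathwayAnnotation({"P1": {"A", "B"}, "P2": {"B", "X"}})
        cat = _catalog({"D": [("A", 0.01), ("B", 0.02)]}, 2)
        table = pathway_load(cat, ann)
        assert table.loads.loc["D", "P1"] == pytest.approx(2 / 3)
        assert table.loads.loc["D", "P2"] == pytest.approx(1 / 3)

    def test_matches_brute_force_incidence_count(self):
        rng = np.random.default_rng(5)
        ann = random_annotation(rng, n_genes=40, n_pathways=10)
        genes = sorted(ann.genes())
        half = len(genes) // 2
        cat = _catalog(
            {
                "D1": [(g, 0.01) for g in genes[:half]],
                "D2": [(g, 0.01) for g in genes[half:]],
            },
            min(10, half),
        )
        table = pathway_load(cat, ann)
        for d in ("D1", "D2"):
            members = cat.gene_set(d)
            m = {
                p: sum(g in gs for g in members)
                for p, gs in ann.pathways.items()
            }
            denom = sum(m.values())
            for p, count in m.items():
                assert table.gene_counts.loc[d, p] == count
                assert table.loads.loc[d, p] == pytest.approx(count / denom)

    def test_loads_sum_to_one_per_disease(self):
        rng = np.random.default_rng(6)
        ann = random_annotation(rng)
        genes = sorted(ann.genes())
        cat = _catalog({"D": [(g, 0.01) for g in genes[:20]]}, 20)
        table = pathway_load(cat, ann)
        assert table.loads.sum(axis=1).to_numpy() == pytest.approx([1.0])

    def test_unannotated_disease_excluded_with_warning(self):
        ann = PathwayAnnotation({"P": {"A"}})
        cat = _catalog(
            {"D1": [("A", 0.01)], "D2": [("Z", 0.01)]},
            1,
        )
        with pytest.warns(UserWarning, match="no pathway-annotated genes"):
            table = pathway_load(cat, ann)
        assert list(table.loads.index) == ["D1"]


class TestCaseSelection:
    def test_age_boundary_is_strict(self):
        cohort = make_cohort(
            [
                (60, "F", "white", 1990, ["331.0"]),
                (61, "F", "white", 1990, ["331.0"]),
                (75, "M", "black", 1995, ["401.9", "331.0"]),
                (75, "M", "black", 1995, ["401.9"]),
            ]
        )
        cases = select_ad_cases(cohort)
        assert set(cases["age"]) == {61, 75}
        assert len(cases) == 2

    def test_agrees_with_brute_force_filter(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(500):
            codes = ["401.9"]
            if rng.random() < 0.3:
                codes.append("331.0")
            rows.append(
                (int(rng.integers(40, 95)), "F", "white", 1990, codes)
            )
        cohort = make_cohort(rows)
        expected = sum(
            1
            for age, _, _, _, codes in rows
            if "331.0" in codes and age > 60
        )
        assert len(select_ad_cases(cohort)) == expected


class TestMatching:
    def test_perfect_twins_mean_no_drops(self):
        rows = []
        for i in range(10):
            rows.append((70 + i, "F", "white", 1990, ["331.0"]))
            rows.append((70 + i, "F", "white", 1990, ["401.9"]))
        cohort = make_cohort(rows)
        cases = select_ad_cases(cohort)
        matched = match_controls(cases, cohort, seed=0)
        assert matched.n_dropped == 0 and len(matched) == 10

    def test_key_multisets_identical_between_arms(self):
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(3000):
            codes = ["331.0"] if rng.random() < 0.1 else ["401.9"]
            rows.append(
                (
                    int(rng.integers(55, 90)),
                    "F" if rng.random() < 0.5 else "M",
                    str(rng.choice(["white", "black"])),
                    int(rng.integers(1990, 1994)),
                    codes,
                )
            )
        cohort = make_cohort(rows)
        cases = select_ad_cases(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matched = match_controls(cases, cohort, seed=2)
        keys = ["sex", "age", "race", "survey_year"]
        case_keys = Counter(map(tuple, matched.cases[keys].to_numpy()))
        ctrl_keys = Counter(map(tuple, matched.controls[keys].to_numpy()))
        assert case_keys == ctrl_keys

    def test_competition_for_scarce_control_drops_one(self):
        cohort = make_cohort(
            [
                (70, "F", "white", 1990, ["331.0"]),
                (70, "F", "white", 1990, ["331.0", "250.0"]),
                (70, "F", "white", 1990, ["401.9"]),
            ]
        )
        cases = select_ad_cases(cohort)
        with pytest.warns(UserWarning, match="dropped"):
            matched = match_controls(cases, cohort, seed=0)
        assert len(matched) == 1 and matched.n_dropped == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        rows = []
        for _ in range(400):
            codes = ["331.0"] if rng.random() < 0.2 else ["401.9"]
            rows.append(
                (int(rng.integers(61, 80)), "F", "white", 1990, codes)
            )
        cohort = make_cohort(rows)
        cases = select_ad_cases(cohort)
        a = match_controls(cases, cohort, seed=5)
        b = match_controls(cases, cohort, seed=5)
        pd.testing.assert_frame_equal(a.controls, b.controls)

    def test_controls_never_carry_index_code(self):
        rows = [(70, "F", "white", 1990, ["331.0"])] * 5 + [
            (70, "F", "white", 1990, ["401.9"])
        ] * 5 + [(70, "F", "white", 1990, ["331.0", "401.9"])] * 3
        cohort = make_cohort(rows)
        cases = select_ad_cases(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matched = match_controls(cases, cohort, seed=0)
        assert not matched.controls["dx_codes"].map(
            lambda cs: "331.0" in cs
        ).any()


class TestComorbidityRatios:
    def _matched(self, case_codes, control_codes):
        def frame(code_lists):
            return pd.DataFrame(
                {
                    "patient_id": [f"P{i}" for i in range(len(code_lists))],
                    "age": 70,
                    "sex": "F",
                    "race": "white",
                    "survey_year": 1990,
                    "dx_codes": [tuple(c) for c in code_lists],
                }
            )

        return MatchedCohort(
            frame(case_codes), frame(control_codes), ("sex", "age")
        )

    def test_ratio_and_inclusion(self):
        cases = [["331.0", "714.0"]] * 20 + [["331.0"]] * 10
        controls = [["714.0"]] * 10 + [["401.9"]] * 20
        matched = self._matched(cases, controls)
        res = comorbidity_ratios(matched, {"RA": "714.0"})
        assert len(res) == 1
        assert res[0].case_count == 20 and res[0].control_count == 10
        assert res[0].ratio == 2.0

    def test_boundary_total_fifteen_excluded(self):
        cases = [["331.0", "714.0"]] * 8 + [["331.0"]] * 10
        controls = [["714.0"]] * 7 + [["401.9"]] * 11
        matched = self._matched(cases, controls)
        assert comorbidity_ratios(matched, {"RA": "714.0"}) == []

    def test_zero_controls_excluded_with_warning(self):
        cases = [["331.0", "714.0"]] * 20
        controls = [["401.9"]] * 20
        matched = self._matched(cases, controls)
        with pytest.warns(UserWarning, match="ratio undefined"):
            res = comorbidity_ratios(matched, {"RA": "714.0"})
        assert res == []

    def test_ratio_invariant_under_cohort_duplication(self):
        cases = [["331.0", "714.0"]] * 15 + [["331.0"]] * 10
        controls = [["714.0"]] * 9 + [["401.9"]] * 16
        matched = self._matched(cases, controls)
        doubled = self._matched(cases * 2, controls * 2)
        r1 = comorbidity_ratios(matched, {"RA": "714.0"})[0].ratio
        r2 = comorbidity_ratios(doubled, {"RA": "714.0"})[0].ratio
        assert r1 == r2

    def test_prefix_matching_follows_code_hierarchy(self):
        cases = [["331.0", "714.12"]] * 20
        controls = [["714.9"]] * 10 + [["401.9"]] * 10
        matched = self._matched(cases, controls)
        res = comorbidity_ratios(matched, {"RA": "714"})
        assert res[0].case_count == 20 and res[0].control_count == 10


class TestLoadRatioCorrelation:
    def _loads(self, values):
        loads = pd.DataFrame(values)
        loads = loads.div(loads.sum(axis=1), axis=0)
        from comopath.comorbidity import PathwayLoadTable

        return PathwayLoadTable(loads=loads, gene_counts=(loads * 100).round())

    def test_proportional_loads_give_r_one(self):
        diseases = [f"D{i}" for i in range(6)]
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        loads = self._loads(
            pd.DataFrame({"P1": x, "P2": 7 - x}, index=diseases)
        )
        ratios = [
            ComorbidityResult(d, int(10 * v), 10) for d, v in zip(diseases, x)
        ]
        res = correlate_load_vs_ratio(loads, ratios)
        top = next(r for r in res if r.pathway == "P1")
        assert top.r == pytest.approx(1.0)
        neg = next(r for r in res if r.pathway == "P2")
        assert neg.r == pytest.approx(-1.0)

    def test_bonferroni_over_tested_pathways(self):
        diseases = [f"D{i}" for i in range(5)]
        rng = np.random.default_rng(2)
        loads = self._loads(
            pd.DataFrame(
                rng.random((5, 4)), index=diseases, columns=list("ABCD")
            )
        )
        ratios = [ComorbidityResult(d, 20, 15) for d in diseases]
        # constant ratio vector: correlation undefined -> every pathway skipped
        with pytest.warns(UserWarning, match="constant"):
            assert correlate_load_vs_ratio(loads, ratios) == []

    def test_requires_three_shared_diseases(self):
        loads = self._loads(
            pd.DataFrame({"P1": [1.0, 2.0]}, index=["D1", "D2"])
        )
        ratios = [ComorbidityResult("D1", 10, 10), ComorbidityResult("D2", 12, 10)]
        with pytest.raises(ValueError, match=">=3 diseases"):
            correlate_load_vs_ratio(loads, ratios)

    def test_permuted_ratios_rarely_significant(self):
        rng = np.random.default_rng(4)
        diseases = [f"D{i}" for i in range(12)]
        loads = self._loads(
            pd.DataFrame(
                rng.random((12, 8)),
                index=diseases,
                columns=[f"P{i}" for i in range(8)],
            )
        )
        hits = trials = 0
        base = rng.normal(1.0, 0.3, size=12).clip(0.2)
        for _ in range(40):
            perm = rng.permutation(base)
            ratios = [
                ComorbidityResult(d, int(100 * v), 100)
                for d, v in zip(diseases, perm)
            ]
            for r in correlate_load_vs_ratio(loads, ratios):
                hits += r.p_value < 0.05
                trials += 1
        assert hits / trials < 0.15  # near-nominal false-positive rate
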
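"""Frequency metrics, threshold cascade and Pareto ranking vs a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from herbscreen import (
    Corpus,
    CorpusError,
    DrugFrequencyPoint,
    ParetoFrontModel,
    RecipeRecord,
    SearchTerm,
    apply_threshold,
    build_subsets,
    compute_frequencies,
    link_recipes,
    pareto_ranks,
    rank_matrix,
)

# ---------------------------------------------------------------------------
# Independent oracle: O(n^2) repeated non-dominated-set peeling.
# ---------------------------------------------------------------------------


def brute_force_ranks(points, max_rank=None):
    """Rank by repeatedly extracting the non-dominated set, pairwise checks."""

    def dominates(a, b):
        return (
            a.f1 >= b.f1
            and a.f2 >= b.f2
            and (a.f1 > b.f1 or a.f2 > b.f2)
        )

    remaining = list(range(len(points)))
    ranks = {}
    rank = 0
    while remaining and (max_rank is None or rank < max_rank):
        rank += 1
        front = [
            i
            for i in remaining
            if not any(dominates(points[j], points[i]) for j in remaining if j != i)
        ]
        for i in front:
            ranks[i] = rank
        remaining = [i for i in remaining if i not in front]
    return [ranks.get(i) for i in range(len(points))]


def random_points(rng, n):
    f1 = rng.integers(1, 700, size=n)
    db = f1 + rng.integers(0, 5000, size=n)
    return [DrugFrequencyPoint(f"d{i}", int(f1[i]), int(db[i])) for i in range(n)]


def corpus_with_counts(pairs):
    """A corpus where drug i appears in (f1 in-term, db_total) recipes.

    ``pairs`` maps drug name -> (in-selection count, corpus total count).
    """
    recipes = []
    k = 0
    for drug, (f1, total) in pairs.items():
        for j in range(total):
            term = "target" if j < f1 else "other"
            recipes.append(RecipeRecord(f"r{k}", {term}, {drug}))
            k += 1
    return Corpus(recipes)


TARGET = frozenset({SearchTerm("target", "arthritis", "main")})


class TestFrequencies:
    def test_worked_relative_frequencies(self):
        corpus = corpus_with_counts({"rare": (11, 13), "ubiquitous": (611, 6000)})
        sel = link_recipes(corpus, TARGET)
        pts = {p.drug: p for p in compute_frequencies(corpus, sel)}
        assert round(pts["rare"].f2, 1) == 84.6
        assert round(pts["ubiquitous"].f2, 1) == 10.2

    def test_selection_exclusive_drug_is_100_percent(self):
        corpus = corpus_with_counts({"exclusive": (7, 7), "filler": (1, 5)})
        sel = link_recipes(corpus, TARGET)
        pts = {p.drug: p for p in compute_frequencies(corpus, sel)}
        assert pts["exclusive"].f2 == 100.0

    def test_f2_normalized_to_corpus_not_selection(self):
        corpus = corpus_with_counts({"a": (5, 50)})
        sel = link_recipes(corpus, TARGET)
        (pt,) = compute_frequencies(corpus, sel)
        assert pt.db_total == 50 and pt.f2 == 10.0

    def test_foreign_selection_rejected(self, small_corpus, search_terms):
        sel = link_recipes(small_corpus, search_terms)
        other = corpus_with_counts({"a": (1, 2)})
        with pytest.raises(CorpusError, match="absent"):
            compute_frequencies(other, sel)

    def test_point_invariants(self):
        with pytest.raises(ValueError):
            DrugFrequencyPoint("d", 5, 4)  # f1 > db_total
        with pytest.raises(ValueError):
            DrugFrequencyPoint("d", 1, 0)


class TestThreshold:
    def test_min_count_one_is_identity(self, small_corpus, search_terms):
        sel = link_recipes(small_corpus, search_terms)
        pts = compute_frequencies(small_corpus, sel)
        rep = apply_threshold(pts, sel, small_corpus, min_count=1)
        assert rep.points == pts
        assert rep.selection.recipe_ids == sel.recipe_ids
        assert not rep.dropped_drugs and not rep.dropped_recipes

    def test_cascade_drops_recipes_and_terms(self):
        # Recipes of "lonely" contain only a sub-threshold drug, so the
        # drug, then those recipes, then the term itself are all dropped.
        recipes = [
            RecipeRecord(f"c{i}", {"common-term"}, {"staple"}) for i in range(5)
        ] + [RecipeRecord("x1", {"lonely"}, {"obscure"})]
        corpus = Corpus(recipes)
        terms = frozenset(
            {
                SearchTerm("common-term", "arthritis", "main"),
                SearchTerm("lonely", "skin"),
            }
        )
        sel = link_recipes(corpus, terms)
        pts = compute_frequencies(corpus, sel)
        rep = apply_threshold(pts, sel, corpus, min_count=3)
        assert rep.dropped_drugs == {"obscure"}
        assert rep.dropped_recipes == {"x1"}
        assert {t.term for t in rep.dropped_terms} == {"lonely"}
        assert rep.n_retained_recipes == len(sel) - len(rep.dropped_recipes)

    def test_all_dropped_is_error(self):
        corpus = corpus_with_counts({"a": (2, 4)})
        sel = link_recipes(corpus, TARGET)
        pts = compute_frequencies(corpus, sel)
        with pytest.raises(CorpusError, match="empty analysis set"):
            apply_threshold(pts, sel, corpus, min_count=10)


class TestParetoRanks:
    def test_single_point_is_rank_one(self):
        res = pareto_ranks([DrugFrequencyPoint("d", 3, 6)])
        assert res.points[0].rank == 1

    def test_extreme_points_share_rank_one(self):
        # High-frequency/low-specificity and low-frequency/high-specificity
        # extremes co-occupy rank 1: neither dominates the other.
        pts = [
            DrugFrequencyPoint("ubiquitous", 611, 6000),  # f2 = 10.2
            DrugFrequencyPoint("rare", 11, 13),  # f2 = 84.6
            DrugFrequencyPoint("middling", 10, 100),  # dominated by both
        ]
        res = pareto_ranks(pts)
        assert res.rank_of("ubiquitous") == 1
        assert res.rank_of("rare") == 1
        assert res.rank_of("middling") == 2

    def test_coincident_points_share_rank(self):
        pts = [
            DrugFrequencyPoint("a", 10, 20),
            DrugFrequencyPoint("b", 10, 20),
            DrugFrequencyPoint("c", 5, 20),
        ]
        res = pareto_ranks(pts)
        assert res.rank_of("a") == res.rank_of("b") == 1
        assert res.rank_of("c") == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = random_points(rng, int(rng.integers(1, 200)))
        got = [p.rank for p in pareto_ranks(pts, max_rank=None).points]
        assert got == brute_force_ranks(pts)

    def test_max_rank_truncates_consistently(self):
        rng = np.random.default_rng(99)
        pts = random_points(rng, 120)
        full = brute_force_ranks(pts)
        got = [p.rank for p in pareto_ranks(pts, max_rank=3).points]
        assert got == [r if r is not None and r <= 3 else None for r in full]

    def test_adding_dominated_point_keeps_front(self):
        rng = np.random.default_rng(5)
        pts = random_points(rng, 60)
        front = {p.drug for p in pareto_ranks(pts, None).points if p.rank == 1}
        best = max(pts, key=lambda p: p.f1)
        extra = DrugFrequencyPoint("extra", best.f1 - 1, best.db_total + 100)
        front2 = {
            p.drug
            for p in pareto_ranks(pts + [extra], None).points
            if p.rank == 1
        }
        assert front2 == front

    @given(st.integers(2, 9))
    def test_scaling_f1_preserves_ranks(self, factor):
        # Dominance is order-based: scaling f1 (with db scaled alike so f2
        # is unchanged) leaves every rank as it was.
        rng = np.random.default_rng(11)
        pts = random_points(rng, 80)
        scaled = [
            DrugFrequencyPoint(p.drug, p.f1 * factor, p.db_total * factor)
            for p in pts
        ]
        assert [p.rank for p in pareto_ranks(pts, None).points] == [
            p.rank for p in pareto_ranks(scaled, None).points
        ]

    def test_rank_counts_cumulative_non_decreasing(self):
        rng = np.random.default_rng(21)
        pts = random_points(rng, 150)
        res = pareto_ranks(pts, None)
        counts = {}
        for p in res.points:
            counts[p.rank] = counts.get(p.rank, 0) + 1
        cum = np.cumsum([counts[r] for r in sorted(counts)])
        assert all(np.diff(cum) > 0) and cum[-1] == len(pts)

    def test_enlarging_selection_is_monotone_in_f1(self, search_terms):
        # A superset of recipes can only increase each drug's frequency.
        recipes = [
            RecipeRecord(f"r{i}", {"crane knee wind" if i < 4 else "leg pain"}, {"ginger"})
            for i in range(8)
        ]
        corpus = Corpus(recipes)
        small = link_recipes(
            corpus, {SearchTerm("crane knee wind", "arthritis", "main")}
        )
        big = link_recipes(corpus, search_terms)
        f1_small = compute_frequencies(corpus, small)[0].f1
        f1_big = compute_frequencies(corpus, big)[0].f1
        assert f1_big >= f1_small


class TestRankMatrix:
    def _results(self):
        joint = pareto_ranks(
            [DrugFrequencyPoint("a", 20, 40), DrugFrequencyPoint("b", 10, 12)],
            dataset_name="all_terms",
        )
        sub = pareto_ranks([DrugFrequencyPoint("a", 5, 40)], dataset_name="skin")
        return joint, {"skin": sub}

    def test_absent_drug_gives_empty_cell(self):
        joint, subs = self._results()
        m = rank_matrix(joint, subs).frame
        assert m.loc["a", "skin"] == 1
        assert pd.isna(m.loc["b", "skin"])

    def test_unknown_annotation_warns_and_is_ignored(self, caplog):
        joint, subs = self._results()
        with caplog.at_level("WARNING"):
            m = rank_matrix(joint, subs, annotation={"ghost": "toxic", "a": "specific"})
        assert "ghost" in caplog.text
        assert m.frame.loc["a", "classification"] == "specific"
        assert "ghost" not in m.frame.index

    def test_identical_points_identical_ranks_across_columns(self):
        joint = pareto_ranks(
            [DrugFrequencyPoint("a", 20, 40)], dataset_name="all_terms"
        )
        sub1 = pareto_ranks([DrugFrequencyPoint("a", 7, 40)], dataset_name="s1")
        sub2 = pareto_ranks([DrugFrequencyPoint("a", 7, 40)], dataset_name="s2")
        m = rank_matrix(joint, {"s1": sub1, "s2": sub2}).frame
        assert m.loc["a", "s1"] == m.loc["a", "s2"]


class TestModelWorkflow:
    def test_fit_on_small_corpus(self, small_corpus, search_terms):
        res = ParetoFrontModel(small_corpus, search_terms, min_count=1).fit()
        assert res.n_initial_recipes == 5
        assert set(res.subset_results) == {
            "arthritis_main_orbit",
            "arthritis_main",
            "skin",
            "arthritis_and_skin",
        }
        pc = res.partition_counts()
        assert pc["main"] + pc["orbit"] == len(res.subsets["arthritis_main_orbit"])
        assert "Pareto-front mining summary" in res.summary()

    def test_subsets_inherit_joint_filtered_drugs(self):
        # A drug above threshold only inside one subset must still be
        # excluded everywhere once it fails the joint-dataset filter.
        recipes = [
            RecipeRecord(f"m{i}", {"crane knee wind"}, {"staple", "niche"})
            for i in range(2)
        ] + [
            RecipeRecord(f"s{i}", {"bayberry sores"}, {"staple"}) for i in range(4)
        ]
        corpus = Corpus(recipes)
        terms = frozenset(
            {
                SearchTerm("crane knee wind", "arthritis", "main"),
                SearchTerm("bayberry sores", "skin"),
            }
        )
        res = ParetoFrontModel(corpus, terms, min_count=3).fit()
        assert "niche" in res.threshold_report.dropped_drugs
        for sub in res.subset_results.values():
            assert all(p.drug != "niche" for p in sub.points)

    def test_save_writes_expected_files(self, small_corpus, search_terms, tmp_path):
        res = ParetoFrontModel(small_corpus, search_terms, min_count=1).fit()
        written = res.save(tmp_path)
        for path in written.values():
            assert path.exists() and path.stat().st_size > 0
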
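"""Frequency metrics and iterative Pareto-front ranking of botanical drugs.

For a selected recipe dataset, each drug is summarized by two jointly
maximized objectives:

* ``f1`` — frequency: the number of selected recipes containing the drug;
* ``f2`` — relative frequency: ``100 * f1 / db_total``, where ``db_total`` is
  the drug's recipe count in the *entire* corpus.  ``f2`` measures how
  specific the drug's use is to the selected indications.

The two are inversely related in realistic corpora (ubiquitous drugs are
rarely indication-specific), so neither alone identifies historically
preferred treatments.  Pareto-front (PF) ranking balances both: rank 1 is the
set of non-dominated points; peeling it off and repeating yields ranks 2, 3,
... .  Point *a* dominates *b* iff ``a.f1 >= b.f1`` and ``a.f2 >= b.f2`` with
at least one strict inequality; coincident points share a rank.

:class:`ParetoFrontModel` bundles the whole mining workflow — subset
construction, frequency computation, the minimum-occurrence filter, per-subset
ranking and the cross-subset rank matrix — behind a statsmodels-style
``fit()`` returning :class:`ParetoFrontResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import (
    Corpus,
    CorpusError,
    DatasetSelection,
    SearchTerm,
    SUBSET_NAMES,
    build_subsets,
    load_annotation,
    load_corpus,
    load_search_terms,
)

__all__ = [
    "DrugFrequencyPoint",
    "ParetoResult",
    "ThresholdReport",
    "RankMatrix",
    "compute_frequencies",
    "apply_threshold",
    "pareto_ranks",
    "rank_matrix",
    "ParetoFrontModel",
    "ParetoFrontResults",
]


@dataclass(frozen=True)
class DrugFrequencyPoint:
    """A drug's (frequency, relative-frequency) point with its PF rank.

    ``f2`` is kept at full precision internally; reporting rounds to one
    decimal.  ``rank`` is ``None`` until assigned (or when beyond the maximum
    reported rank).
    """

    drug: str
    f1: int
    db_total: int
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.f1 < 0 or self.db_total < 0:
            raise ValueError("counts must be non-negative")
        if self.f1 > self.db_total:
            raise ValueError(
                f"{self.drug!r}: selection frequency {self.f1} exceeds corpus total {self.db_total}"
            )
        if self.f1 >= 1 and self.db_total < 1:
            raise ValueError(f"{self.drug!r}: db_total must be >= 1 when f1 >= 1")

    @property
    def f2(self) -> float:
        """Relative frequency as a percentage of whole-corpus occurrences."""
        return 100.0 * self.f1 / self.db_total


@dataclass(frozen=True)
class ParetoResult:
    """Ranked points for one dataset selection."""

    dataset_name: str
    points: tuple[DrugFrequencyPoint, ...]
    max_rank_reported: int = 3

    def rank_of(self, drug: str) -> int | None:
        for p in self.points:
            if p.drug == drug:
                return p.rank
        return None

    def candidates(self, max_rank: int | None = None) -> tuple[DrugFrequencyPoint, ...]:
        """Points on ranks 1..max_rank (default: the reported maximum)."""
        cap = self.max_rank_reported if max_rank is None else max_rank
        return tuple(
            p for p in self.points if p.rank is not None and p.rank <= cap
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "drug": [p.drug for p in self.points],
                "f1": [p.f1 for p in self.points],
                "f2": [round(p.f2, 1) for p in self.points],
                "db_total": [p.db_total for p in self.points],
                "rank": [p.rank for p in self.points],
            }
        )
        return df.sort_values(
            ["rank", "f1"], ascending=[True, False], na_position="last"
        ).reset_index(drop=True)


@dataclass(frozen=True)
class ThresholdReport:
    """Outcome of the minimum-occurrence filter.

    Drugs below ``min_count`` selected-recipe occurrences are dropped; then
    recipes left with no retained ingredient, then search terms left with no
    linked recipe.
    """

    points: tuple[DrugFrequencyPoint, ...]
    selection: DatasetSelection
    min_count: int
    dropped_drugs: frozenset[str]
    dropped_recipes: frozenset[str]
    dropped_terms: frozenset[SearchTerm]

    @property
    def n_retained_recipes(self) -> int:
        return len(self.selection)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_frequencies(
    corpus: Corpus,
    selection: DatasetSelection,
    drugs: Iterable[str] | None = None,
) -> tuple[DrugFrequencyPoint, ...]:
    """Compute (f1, f2) per drug occurring in the selection.

    ``f2`` is always normalized by the drug's whole-corpus recipe count,
    never by its count within the selection.  When ``drugs`` is given, only
    those drugs are scored (still requiring at least one selected
    occurrence).
    """
    unknown = selection.recipe_ids - corpus.recipe_ids
    if unknown:
        raise CorpusError(
            f"selection references recipes absent from corpus: {sorted(unknown)[:5]}"
        )
    sel_counts: dict[str, int] = {}
    db_counts: dict[str, int] = {}
    for rec in corpus:
        in_sel = rec.recipe_id in selection.recipe_ids
        for drug in rec.ingredients:
            db_counts[drug] = db_counts.get(drug, 0) + 1
            if in_sel:
                sel_counts[drug] = sel_counts.get(drug, 0) + 1
    keep = set(sel_counts) if drugs is None else set(drugs) & set(sel_counts)
    return tuple(
        DrugFrequencyPoint(drug=d, f1=sel_counts[d], db_total=db_counts[d])
        for d in sorted(keep)
    )


def apply_threshold(
    points: Sequence[DrugFrequencyPoint],
    selection: DatasetSelection,
    corpus: Corpus,
    min_count: int = 10,
) -> ThresholdReport:
    """Filter drugs occurring fewer than ``min_count`` times in the selection.

    The filter cascades: recipes whose ingredient set no longer intersects
    the retained drug list are dropped from the selection, and search terms
    no longer linked to any remaining recipe are dropped from the term set.
    Retained drugs keep their original frequencies (the dropped recipes by
    construction contain no retained drug).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = tuple(p for p in points if p.f1 >= min_count)
    if not kept:
        raise CorpusError("empty analysis set: every drug fell below the threshold")
    dropped_drugs = frozenset(p.drug for p in points) - frozenset(p.drug for p in kept)
    retained_drugs = frozenset(p.drug for p in kept)
    keep_ids = frozenset(
        rid for rid in selection.recipe_ids if corpus[rid].ingredients & retained_drugs
    )
    dropped_recipes = selection.recipe_ids - keep_ids
    kept_terms = frozenset(
        t
        for t in selection.terms_used
        if any(t.term in corpus[rid].indications for rid in keep_ids)
    )
    dropped_terms = selection.terms_used - kept_terms
    reduced = DatasetSelection(
        name=selection.name, recipe_ids=keep_ids, terms_used=kept_terms
    )
    return ThresholdReport(
        points=kept,
        selection=reduced,
        min_count=min_count,
        dropped_drugs=dropped_drugs,
        dropped_recipes=dropped_recipes,
        dropped_terms=dropped_terms,
    )


def _peel_front(pts: list[tuple[float, float, int]]) -> list[int]:
    """Indices of the non-dominated subset of distinct (f1, f2) points.

    Points are sorted by f1 descending, f2 descending; a sweep keeps a point
    iff its f2 strictly exceeds the best f2 seen so far.  Correct for
    *distinct* points under weak dominance with one strict inequality.
    """
    order = sorted(pts, key=lambda t: (-t[0], -t[1]))
    front: list[int] = []
    best_f2 = -np.inf
    for f1, f2, idx in order:
        if f2 > best_f2:
            front.append(idx)
            best_f2 = f2
    return front


def pareto_ranks(
    points: Sequence[DrugFrequencyPoint],
    max_rank: int | None = 3,
    dataset_name: str = "",
) -> ParetoResult:
    """Assign iterative Pareto-front ranks, maximizing both f1 and f2.

    Rank 1 is the non-dominated set; it is peeled off and the procedure
    repeats until ``max_rank`` fronts are extracted (``None`` ranks every
    point).  Points with identical (f1, f2) coordinates share a rank, since
    neither weakly dominates the other with a strict inequality.
    """
    if not points:
        raise ValueError("pareto_ranks requires at least one point")
    # Group coincident points: ranking operates on distinct coordinates.
    coords: dict[tuple[float, float], list[int]] = {}
    for i, p in enumerate(points):
        coords.setdefault((float(p.f1), p.f2), []).append(i)
    remaining = [(f1, f2, j) for j, (f1, f2) in enumerate(coords)]
    keys = list(coords)
    rank_of_key: dict[int, int] = {}
    rank = 0
    while remaining and (max_rank is None or rank < max_rank):
        rank += 1
        front = set(_peel_front(remaining))
        for j in front:
            rank_of_key[j] = rank
        remaining = [t for t in remaining if t[2] not in front]
    ranked = list(points)
    for j, key in enumerate(keys):
        r = rank_of_key.get(j)
        for i in coords[key]:
            ranked[i] = replace(points[i], rank=r)
    return ParetoResult(
        dataset_name=dataset_name,
        points=tuple(ranked),
        max_rank_reported=max_rank if max_rank is not None else rank,
    )


@dataclass(frozen=True)
class RankMatrix:
    """Cross-dataset rank comparison for the joint dataset's candidates.

    Rows are the drugs on ranks 1..max_rank of the joint dataset; columns are
    dataset names; cells hold that drug's PF rank in that dataset (NaN where
    the drug does not occur there).  An optional annotation column carries
    literature classification labels.
    """

    frame: pd.DataFrame

    def to_csv(self, path: str | Path) -> Path:
        self.frame.to_csv(path)
        return Path(path)


def rank_matrix(
    joint: ParetoResult,
    subsets: Mapping[str, ParetoResult],
    annotation: Mapping[str, str] | None = None,
    max_rank: int | None = None,
) -> RankMatrix:
    """Aggregate per-subset ranks for the joint dataset's top candidates."""
    import logging

    cands = joint.candidates(max_rank)
    rows = [p.drug for p in sorted(cands, key=lambda p: (p.rank, -p.f1))]
    data: dict[str, list] = {joint.dataset_name or "all_terms": [
        joint.rank_of(d) for d in rows
    ]}
    for name, res in subsets.items():
        data[name] = [res.rank_of(d) for d in rows]
    frame = pd.DataFrame(data, index=pd.Index(rows, name="drug"), dtype="Float64")
    if annotation is not None:
        known = set(rows)
        for drug in annotation:
            if drug not in known:
                logging.getLogger(__name__).warning(
                    "annotation for unknown drug %r ignored", drug
                )
        frame["classification"] = [annotation.get(d, "") for d in rows]
    return RankMatrix(frame=frame)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class ParetoFrontModel:
    """Pareto-front mining of a recipe corpus for a set of search terms.

    Parameters
    ----------
    corpus
        The full recipe corpus (relative frequencies are normalized to it).
    terms
        Search terms defining the joint dataset and its subsets.
    min_count
        Minimum joint-dataset occurrences for a drug to enter the analysis
        (default 10).  Applied once, on the joint dataset; subsets inherit
        the filtered drug list.
    max_rank
        Number of Pareto fronts to extract per dataset (default 3).
    annotation
        Optional drug -> classification mapping joined into the rank matrix.
    """

    def __init__(
        self,
        corpus: Corpus,
        terms: Iterable[SearchTerm],
        min_count: int = 10,
        max_rank: int = 3,
        annotation: Mapping[str, str] | None = None,
    ):
        self.corpus = corpus
        self.terms = frozenset(terms)
        if not self.terms:
            raise CorpusError("ParetoFrontModel requires at least one search term")
        self.min_count = int(min_count)
        self.max_rank = int(max_rank)
        self.annotation = dict(annotation) if annotation else None

    @classmethod
    def from_files(
        cls,
        corpus_path: str | Path,
        terms_path: str | Path,
        annotation_path: str | Path | None = None,
        **kwargs,
    ) -> "ParetoFrontModel":
        corpus = load_corpus(corpus_path)
        terms = load_search_terms(terms_path)
        annotation = load_annotation(annotation_path) if annotation_path else None
        return cls(corpus, terms, annotation=annotation, **kwargs)

    def fit(self) -> "ParetoFrontResults":
        """Run the full mining workflow and return the results object."""
        subsets = build_subsets(self.corpus, self.terms)
        joint = subsets["all_terms"]
        points = compute_frequencies(self.corpus, joint)
        report = apply_threshold(points, joint, self.corpus, self.min_count)
        retained = frozenset(p.drug for p in report.points)
        joint_ranked = pareto_ranks(report.points, self.max_rank, "all_terms")
        subset_results: dict[str, ParetoResult] = {}
        reduced_subsets: dict[str, DatasetSelection] = {"all_terms": report.selection}
        for name in SUBSET_NAMES[1:]:
            sel = subsets[name]
            reduced = DatasetSelection(
                name=name,
                recipe_ids=sel.recipe_ids & report.selection.recipe_ids,
                terms_used=sel.terms_used & report.selection.terms_used
                if name != "arthritis_and_skin"
                else sel.terms_used,
                partition={
                    k: v
                    for k, v in sel.partition.items()
                    if k in report.selection.recipe_ids
                },
            )
            reduced_subsets[name] = reduced
            if not reduced.recipe_ids:
                subset_results[name] = ParetoResult(name, (), self.max_rank)
                continue
            sub_points = compute_frequencies(self.corpus, reduced, drugs=retained)
            if sub_points:
                subset_results[name] = pareto_ranks(sub_points, self.max_rank, name)
            else:
                subset_results[name] = ParetoResult(name, (), self.max_rank)
        matrix = rank_matrix(joint_ranked, subset_results, self.annotation)
        return ParetoFrontResults(
            model=self,
            subsets=reduced_subsets,
            initial_selection=joint,
            threshold_report=report,
            joint=joint_ranked,
            subset_results=subset_results,
            matrix=matrix,
        )


@dataclass
class ParetoFrontResults:
    """Results of :meth:`ParetoFrontModel.fit`.

    Attributes
    ----------
    subsets
        Post-threshold dataset selections (joint plus subsets A-D).
    initial_selection
        The joint selection before the occurrence filter.
    threshold_report
        Drop bookkeeping from the minimum-occurrence filter.
    joint, subset_results
        Ranked points for the joint dataset and each subset.
    matrix
        The cross-subset rank matrix over the joint top candidates.
    """

    model: ParetoFrontModel
    subsets: Mapping[str, DatasetSelection]
    initial_selection: DatasetSelection
    threshold_report: ThresholdReport
    joint: ParetoResult
    subset_results: Mapping[str, ParetoResult]
    matrix: RankMatrix

    # -- headline numbers ---------------------------------------------------
    @property
    def n_initial_recipes(self) -> int:
        return len(self.initial_selection)

    @property
    def n_retained_recipes(self) -> int:
        return len(self.threshold_report.selection)

    @property
    def n_retained_drugs(self) -> int:
        return len(self.threshold_report.points)

    def rank_counts(self) -> dict[int, int]:
        """Number of joint-dataset candidates on each reported rank."""
        out: dict[int, int] = {}
        for p in self.joint.points:
            if p.rank is not None:
                out[p.rank] = out.get(p.rank, 0) + 1
        return dict(sorted(out.items()))

    def partition_counts(self) -> dict[str, int]:
        """Main/Orbit partition sizes within the post-threshold subset A."""
        part = self.subsets["arthritis_main_orbit"].partition
        return {
            "main": sum(1 for v in part.values() if v == "main"),
            "orbit": sum(1 for v in part.values() if v == "orbit"),
        }

    def summary(self) -> str:
        """Plain-text summary in the spirit of a statsmodels results table."""
        rc = self.rank_counts()
        pc = self.partition_counts()
        lines = [
            "Pareto-front mining summary",
            "=" * 60,
            f"corpus recipes:            {len(self.model.corpus)}",
            f"search terms:              {len(self.model.terms)}",
            f"joint dataset recipes:     {self.n_initial_recipes}",
            f"occurrence threshold:      f1 >= {self.model.min_count}",
            f"  drugs dropped:           {len(self.threshold_report.dropped_drugs)}",
            f"  recipes dropped:         {len(self.threshold_report.dropped_recipes)}",
            f"  terms dropped:           {len(self.threshold_report.dropped_terms)}",
            f"retained recipes:          {self.n_retained_recipes}",
            f"retained drugs:            {self.n_retained_drugs}",
            "dataset sizes:",
        ]
        for name in SUBSET_NAMES:
            lines.append(f"  {name:<24} {len(self.subsets[name])}")
        lines.append(
            f"  (subset A partition:     {pc['main']} main + {pc['orbit']} orbit)"
        )
        lines.append("joint-dataset candidates per PF rank:")
        for r, n in rc.items():
            lines.append(f"  rank {r}:                  {n}")
        lines.append(f"  total ranks 1-{self.joint.max_rank_reported}:         "
                     f"{sum(rc.values())}")
        return "\n".join(lines)

    def run_summary(self) -> dict:
        """Machine-readable counterpart of :meth:`summary`."""
        return {
            "n_corpus_recipes": len(self.model.corpus),
            "n_search_terms": len(self.model.terms),
            "n_joint_recipes": self.n_initial_recipes,
            "min_count": self.model.min_count,
            "n_dropped_drugs": len(self.threshold_report.dropped_drugs),
            "n_dropped_recipes": len(self.threshold_report.dropped_recipes),
            "n_dropped_terms": len(self.threshold_report.dropped_terms),
            "n_retained_recipes": self.n_retained_recipes,
            "n_retained_drugs": self.n_retained_drugs,
            "subset_sizes": {n: len(self.subsets[n]) for n in SUBSET_NAMES},
            "partition_counts": self.partition_counts(),
            "rank_counts": {str(k): v for k, v in self.rank_counts().items()},
            "n_candidates": len(self.joint.candidates()),
        }

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write ranked-point CSVs per dataset plus the rank matrix."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name, res in {"all_terms": self.joint, **dict(self.subset_results)}.items():
            p = outdir / f"pareto_{name}.csv"
            res.to_frame().to_csv(p, index=False)
            written[name] = p
        written["rank_matrix"] = self.matrix.to_csv(outdir / "rank_matrix.csv")
        return written

    def plot_front(self, dataset: str = "all_terms", ax=None):
        """Scatter of (f1, f2) with front polylines for ranks 1..max_rank."""
        import matplotlib.pyplot as plt

        res = self.joint if dataset == "all_terms" else self.subset_results[dataset]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        pts = res.points
        ax.scatter([p.f1 for p in pts], [p.f2 for p in pts], s=14, c="grey", alpha=0.6)
        for r in range(1, res.max_rank_reported + 1):
            front = sorted(
                (p for p in pts if p.rank == r), key=lambda p: (p.f1, -p.f2)
            )
            if front:
                ax.plot(
                    [p.f1 for p in front],
                    [p.f2 for p in front],
                    marker="o",
                    label=f"PF rank {r}",
                )
        ax.set_xlabel("frequency $f_1$ (recipes in selection)")
        ax.set_ylabel("relative frequency $f_2$ (% of corpus occurrences)")
        ax.set_title(f"Pareto fronts — {dataset}")
        ax.legend()
        return ax
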
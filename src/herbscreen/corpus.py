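"""Recipe-corpus data model, I/O and dataset construction.

A corpus is a collection of historical medical recipes, each linking a set of
indication terms (historical disease names) to a set of ingredient identifiers
(normalized botanical-drug names).  Analysis datasets are selected by a table
of *search terms*: indications judged to resemble arthritis (granularity
"main" for clearly arthritic terms, "orbit" for related musculoskeletal
complaints) or psoriasiform skin lesions.  From one joint selection, four
standard subsets are derived:

========================  ====================================================
``all_terms``             recipes linked to any search term (the joint dataset)
``arthritis_main_orbit``  recipes linked to any arthritis term (subset A)
``arthritis_main``        recipes linked to a main-granularity arthritis term
``skin``                  recipes linked to any skin term (subset C)
``arthritis_and_skin``    recipes linked to both an arthritis and a skin term
========================  ====================================================

Within ``arthritis_main_orbit`` every recipe is attributed to exactly one of
the partitions Main / Orbit: a single main-granularity link wins.

Corpus files are either JSON (an array of recipe objects with native list
fields) or CSV (UTF-8, header row, ``|``-delimited list cells).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RecipeRecord",
    "SearchTerm",
    "Corpus",
    "DatasetSelection",
    "CorpusError",
    "SUBSET_NAMES",
    "normalize_term",
    "load_corpus",
    "write_corpus",
    "load_search_terms",
    "write_search_terms",
    "load_annotation",
    "link_recipes",
    "build_subsets",
]

#: Canonical subset names, in reporting order.
SUBSET_NAMES = (
    "all_terms",
    "arthritis_main_orbit",
    "arthritis_main",
    "skin",
    "arthritis_and_skin",
)

_CATEGORIES = frozenset({"arthritis", "skin"})
_GRANULARITIES = frozenset({"main", "orbit", "none"})


class CorpusError(ValueError):
    """Raised for schema violations, duplicate identifiers or empty corpora."""


def normalize_term(term: str) -> str:
    """Normalize an indication term: collapse whitespace and case-fold.

    Matching between recipe indications and search terms is exact string
    equality on this normalized form; no fuzzy matching is attempted because
    corpus indications are assumed pre-standardized.
    """
    return " ".join(str(term).split()).casefold()


@dataclass(frozen=True)
class SearchTerm:
    """An indication search term with its category and granularity.

    Parameters
    ----------
    term
        The indication string (normalized on construction).
    transliteration
        Optional romanized form, carried through for reporting.
    category
        ``"arthritis"`` or ``"skin"``.
    granularity
        ``"main"`` or ``"orbit"`` for arthritis terms, ``"none"`` for skin.
    """

    term: str
    category: str
    granularity: str = "none"
    transliteration: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "term", normalize_term(self.term))
        if not self.term:
            raise CorpusError("search term must be non-empty")
        if self.category not in _CATEGORIES:
            raise CorpusError(f"unknown category {self.category!r}")
        if self.granularity not in _GRANULARITIES:
            raise CorpusError(f"unknown granularity {self.granularity!r}")
        if self.category == "arthritis" and self.granularity not in ("main", "orbit"):
            raise CorpusError(
                f"arthritis term {self.term!r} needs granularity 'main' or 'orbit'"
            )
        if self.category == "skin" and self.granularity != "none":
            raise CorpusError(f"skin term {self.term!r} must have granularity 'none'")


@dataclass(frozen=True)
class RecipeRecord:
    """One historical recipe: indication links plus an ingredient list.

    ``indications`` and ``ingredients`` are sets — a drug listed twice within
    one recipe counts once, so frequency later means recipe-level presence.
    """

    recipe_id: str
    indications: frozenset[str]
    ingredients: frozenset[str]
    title: str = ""
    source_id: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "indications", frozenset(normalize_term(t) for t in self.indications)
        )
        object.__setattr__(
            self, "ingredients", frozenset(str(i).strip() for i in self.ingredients)
        )
        if not self.recipe_id:
            raise CorpusError("recipe_id must be non-empty")
        if not self.indications:
            raise CorpusError(f"recipe {self.recipe_id!r}: indications empty")
        if not self.ingredients or any(not i for i in self.ingredients):
            raise CorpusError(f"recipe {self.recipe_id!r}: ingredients empty")


class Corpus:
    """A validated recipe corpus with derived vocabularies.

    Vocabularies (all indication terms and ingredient identifiers referenced
    by any recipe) are derived at construction, so the invariant that every
    reference appears in its vocabulary holds by construction.
    """

    def __init__(self, recipes: Iterable[RecipeRecord]):
        self._recipes: dict[str, RecipeRecord] = {}
        for rec in recipes:
            if rec.recipe_id in self._recipes:
                raise CorpusError(f"duplicate recipe_id {rec.recipe_id!r}")
            self._recipes[rec.recipe_id] = rec
        if not self._recipes:
            raise CorpusError("corpus is empty")
        self.ingredient_vocabulary: frozenset[str] = frozenset(
            i for r in self._recipes.values() for i in r.ingredients
        )
        self.term_vocabulary: frozenset[str] = frozenset(
            t for r in self._recipes.values() for t in r.indications
        )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._recipes)

    def __iter__(self):
        return iter(self._recipes.values())

    def __contains__(self, recipe_id: str) -> bool:
        return recipe_id in self._recipes

    def __getitem__(self, recipe_id: str) -> RecipeRecord:
        return self._recipes[recipe_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._recipes == other._recipes

    def __repr__(self) -> str:
        return (
            f"<Corpus: {len(self)} recipes, {len(self.ingredient_vocabulary)} "
            f"ingredients, {len(self.term_vocabulary)} indication terms>"
        )

    @property
    def recipe_ids(self) -> frozenset[str]:
        return frozenset(self._recipes)


@dataclass(frozen=True)
class DatasetSelection:
    """A named set of recipes selected by search terms.

    ``partition`` is only populated for the ``arthritis_main_orbit`` subset
    and maps every selected recipe to ``"main"`` or ``"orbit"``.
    """

    name: str
    recipe_ids: frozenset[str]
    terms_used: frozenset[SearchTerm]
    partition: Mapping[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.recipe_ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LIST_SEP = "|"


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "json"):
        raise CorpusError(f"unsupported corpus format {fmt!r}")
    return fmt


def _record_from_obj(obj: Mapping, where: str) -> RecipeRecord:
    try:
        return RecipeRecord(
            recipe_id=str(obj["recipe_id"]),
            indications=frozenset(obj["indications"]),
            ingredients=frozenset(obj["ingredients"]),
            title=str(obj.get("title", "") or ""),
            source_id=str(obj.get("source_id", "") or ""),
            metadata=dict(obj.get("metadata", {}) or {}),
        )
    except KeyError as exc:
        raise CorpusError(f"{where}: missing field {exc.args[0]!r}") from exc
    except CorpusError as exc:
        raise CorpusError(f"{where}: {exc}") from exc


def load_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Load and validate a corpus from a JSON or CSV file.

    JSON files hold an array of recipe objects; CSV files hold one recipe per
    row with ``|``-delimited ``indications`` and ``ingredients`` cells.
    Duplicate recipe identifiers, empty field sets and unknown formats all
    raise :class:`CorpusError` naming the offending record.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if not isinstance(raw, list):
            raise CorpusError(f"{path}: expected a JSON array of recipe objects")
        records = [
            _record_from_obj(obj, f"{path} record {i}") for i, obj in enumerate(raw)
        ]
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"recipe_id", "indications", "ingredients"}
        missing = required - set(df.columns)
        if missing:
            raise CorpusError(f"{path}: missing columns {sorted(missing)}")
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            obj = {
                "recipe_id": row.recipe_id,
                "indications": [
                    t for t in str(row.indications).split(_LIST_SEP) if t.strip()
                ],
                "ingredients": [
                    t for t in str(row.ingredients).split(_LIST_SEP) if t.strip()
                ],
                "title": getattr(row, "title", ""),
                "source_id": getattr(row, "source_id", ""),
            }
            if hasattr(row, "metadata") and str(row.metadata).strip():
                obj["metadata"] = json.loads(row.metadata)
            records.append(_record_from_obj(obj, f"{path} row {i}"))
    return Corpus(records)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> Path:
    """Write a corpus to JSON or CSV; the output round-trips via load_corpus."""
    path = Path(path)
    fmt = _infer_format(path, format)
    recs = sorted(corpus, key=lambda r: r.recipe_id)
    if fmt == "json":
        payload = [
            {
                "recipe_id": r.recipe_id,
                "title": r.title,
                "indications": sorted(r.indications),
                "ingredients": sorted(r.ingredients),
                "source_id": r.source_id,
                "metadata": dict(r.metadata),
            }
            for r in recs
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=1)
    else:
        df = pd.DataFrame(
            {
                "recipe_id": [r.recipe_id for r in recs],
                "title": [r.title for r in recs],
                "indications": [_LIST_SEP.join(sorted(r.indications)) for r in recs],
                "ingredients": [_LIST_SEP.join(sorted(r.ingredients)) for r in recs],
                "source_id": [r.source_id for r in recs],
                "metadata": [
                    json.dumps(dict(r.metadata), ensure_ascii=False) if r.metadata else ""
                    for r in recs
                ],
            }
        )
        df.to_csv(path, index=False)
    return path


def load_search_terms(path: str | Path) -> frozenset[SearchTerm]:
    """Read a search-term table (CSV: term, transliteration, category, granularity)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"term", "category"} - set(df.columns)
    if missing:
        raise CorpusError(f"{path}: missing columns {sorted(missing)}")
    terms = []
    for i, row in df.iterrows():
        gran = str(row.get("granularity", "") or "").strip().lower() or "none"
        try:
            terms.append(
                SearchTerm(
                    term=row["term"],
                    category=str(row["category"]).strip().lower(),
                    granularity=gran,
                    transliteration=str(row.get("transliteration", "") or ""),
                )
            )
        except CorpusError as exc:
            raise CorpusError(f"{path} row {i}: {exc}") from exc
    if not terms:
        raise CorpusError(f"{path}: no search terms")
    return frozenset(terms)


def write_search_terms(terms: Iterable[SearchTerm], path: str | Path) -> Path:
    rows = sorted(terms, key=lambda t: (t.category, t.granularity, t.term))
    pd.DataFrame(
        {
            "term": [t.term for t in rows],
            "transliteration": [t.transliteration for t in rows],
            "category": [t.category for t in rows],
            "granularity": ["" if t.granularity == "none" else t.granularity for t in rows],
        }
    ).to_csv(path, index=False)
    return Path(path)


def load_annotation(path: str | Path) -> dict[str, str]:
    """Read a drug classification table (CSV: drug, classification).

    Classifications are literature-derived labels (``specific`` /
    ``unspecific`` / ``toxic``) and are passed through to reporting only.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"drug", "classification"} - set(df.columns)
    if missing:
        raise CorpusError(f"{path}: missing columns {sorted(missing)}")
    allowed = {"specific", "unspecific", "toxic"}
    out: dict[str, str] = {}
    for i, row in df.iterrows():
        label = str(row["classification"]).strip().lower()
        if label not in allowed:
            raise CorpusError(f"{path} row {i}: classification {label!r} not in {sorted(allowed)}")
        out[str(row["drug"]).strip()] = label
    return out


# ---------------------------------------------------------------------------
# Selection and subset construction
# ---------------------------------------------------------------------------


def link_recipes(
    corpus: Corpus, terms: Iterable[SearchTerm], name: str = "all_terms"
) -> DatasetSelection:
    """Select every recipe whose indication set intersects the search terms.

    A recipe is selected once no matter how many terms it matches.  An empty
    result is a warning, not an error — it simply means no term occurs in the
    corpus.
    """
    term_set = frozenset(terms)
    if not term_set:
        raise CorpusError("link_recipes requires a non-empty term set")
    term_strings = {t.term for t in term_set}
    ids = frozenset(
        r.recipe_id for r in corpus if r.indications & term_strings
    )
    if not ids:
        logger.warning("no recipe matches any of the %d search terms", len(term_set))
    return DatasetSelection(name=name, recipe_ids=ids, terms_used=term_set)


def build_subsets(
    corpus: Corpus, terms: Iterable[SearchTerm]
) -> dict[str, DatasetSelection]:
    """Build the joint dataset and the four standard subsets.

    Returns the five selections keyed by :data:`SUBSET_NAMES`.  Containment
    invariants hold by construction: every subset is contained in
    ``all_terms``; ``arthritis_main`` and ``arthritis_and_skin`` are contained
    in ``arthritis_main_orbit``; ``arthritis_and_skin`` is contained in
    ``skin``.  The Main/Orbit attribution of ``arthritis_main_orbit`` recipes
    is a partition: any main-granularity link puts a recipe in Main.
    """
    term_set = frozenset(terms)
    arthritis = frozenset(t for t in term_set if t.category == "arthritis")
    main = frozenset(t for t in arthritis if t.granularity == "main")
    skin = frozenset(t for t in term_set if t.category == "skin")

    joint = link_recipes(corpus, term_set, name="all_terms")

    def _sub(name: str, sub_terms: frozenset[SearchTerm]) -> DatasetSelection:
        if not sub_terms:
            return DatasetSelection(name=name, recipe_ids=frozenset(), terms_used=frozenset())
        sel = link_recipes(corpus, sub_terms, name=name)
        return sel

    sel_arth = _sub("arthritis_main_orbit", arthritis)
    sel_main = _sub("arthritis_main", main)
    sel_skin = _sub("skin", skin)
    inter = DatasetSelection(
        name="arthritis_and_skin",
        recipe_ids=sel_arth.recipe_ids & sel_skin.recipe_ids,
        terms_used=arthritis | skin,
    )
    # Main/Orbit partition of subset A: one main link wins.
    partition = {
        rid: ("main" if rid in sel_main.recipe_ids else "orbit")
        for rid in sel_arth.recipe_ids
    }
    sel_arth = DatasetSelection(
        name=sel_arth.name,
        recipe_ids=sel_arth.recipe_ids,
        terms_used=sel_arth.terms_used,
        partition=partition,
    )
    out = {
        "all_terms": joint,
        "arthritis_main_orbit": sel_arth,
        "arthritis_main": sel_main,
        "skin": sel_skin,
        "arthritis_and_skin": inter,
    }
    _assert_lattice(out)
    return out


def _assert_lattice(subsets: Mapping[str, DatasetSelection]) -> None:
    """Post-construction sanity assertions on the subset containment lattice."""
    joint = subsets["all_terms"].recipe_ids
    for name in SUBSET_NAMES[1:]:
        assert subsets[name].recipe_ids <= joint, f"{name} escapes the joint dataset"
    a = subsets["arthritis_main_orbit"]
    assert subsets["arthritis_main"].recipe_ids <= a.recipe_ids
    assert subsets["arthritis_and_skin"].recipe_ids <= a.recipe_ids
    assert subsets["arthritis_and_skin"].recipe_ids <= subsets["skin"].recipe_ids
    n_main = sum(1 for v in a.partition.values() if v == "main")
    n_orbit = sum(1 for v in a.partition.values() if v == "orbit")
    assert n_main + n_orbit == len(a), "Main/Orbit attribution is not a partition"
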
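"""Seeded synthetic-data generators with planted ground truth.

Neither the historical recipe corpus nor the wet-lab binding data analysed
by this package are publicly available, so every pipeline stage is exercised
against synthetic twins whose statistical structure emulates the real data:

* :func:`generate_corpus` produces a recipe corpus with a power-law
  background ingredient distribution (few ubiquitous drugs, a long tail of
  rare ones) plus two kinds of planted signal: *specific* drugs concentrated
  in recipes linked to particular search terms (high relative frequency,
  modest frequency) and *common* drugs used corpus-wide (high frequency, low
  relative frequency).  The background reproduces the inverse relation
  between the two frequency metrics that motivates Pareto-front ranking.
* :func:`generate_plate` produces coregulator binding plates with a
  log-normal per-motif baseline, planted fold changes on GC-responsive
  motifs under the cortisol control, Gaussian bell-shaped LFC gradients over
  the sequential fraction index on plant-responsive motifs, log-normal
  replicate noise, and optional spiked (competition) conditions realizing a
  full / partial / absent inhibition scenario.

Every generator is deterministic given its spec and seed, and returns a
truth record listing each planted effect so recovery can be asserted by the
matching analysis operation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, RecipeRecord, SearchTerm
from .plates import APO, BindingPlate, index_to_well

__all__ = [
    "PlantedSpecific",
    "PlantedCommon",
    "CorpusSpec",
    "CorpusTruth",
    "generate_corpus",
    "ClusterSpec",
    "InhibitionSpec",
    "PlateSpec",
    "PlateTruth",
    "generate_plate",
    "default_motif_names",
    "default_gc_effect",
]


# ---------------------------------------------------------------------------
# Recipe-corpus generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSpecific:
    """A drug planted to be indication-specific.

    Included in recipes linked to any of ``terms`` with probability
    ``in_rate`` and elsewhere with probability ``out_rate``.
    """

    drug: str
    terms: tuple[str, ...]
    in_rate: float = 0.7
    out_rate: float = 0.0005


@dataclass(frozen=True)
class PlantedCommon:
    """A drug planted to be globally common.

    Included anywhere with probability ``rate``; recipes linked to a search
    term use it ``inset_boost`` times more often, keeping its relative
    frequency slightly above the undifferentiated background.
    """

    drug: str
    rate: float
    inset_boost: float = 1.8


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of the synthetic recipe corpus.

    The defaults scale the emulated corpus down by roughly a factor of eight
    (5,000 recipes against an original of order 40,000; 350 background
    indication terms against ~2,900; 450 ingredients against ~3,600) while
    keeping per-term recipe counts in a realistic range.  The search-term
    list (6 main + 9 orbit arthritis terms, 13 skin terms) is scaled from
    the 16/24/34 composition of the emulated study by a factor ~2.6.
    ``search_fraction`` (the probability that a recipe is linked to a search
    term at all) is 0.06, close to the ~5% share of the emulated joint
    dataset in its corpus.
    """

    n_recipes: int = 5000
    n_main_terms: int = 6
    n_orbit_terms: int = 9
    n_skin_terms: int = 13
    n_background_terms: int = 350
    n_background_ingredients: int = 444
    mean_ingredients: float = 6.0
    search_fraction: float = 0.06
    ingredient_exponent: float = 0.7
    n_generalist_drugs: int = 15
    n_specialist_drugs: int = 60
    specialist_mass: float = 0.65
    term_exponent: float = 1.0
    category_mass: tuple[float, float, float] = (0.2, 0.3, 0.5)  # main/orbit/skin
    second_term_rate: float = 0.25
    background_term_rate_inset: float = 0.3
    planted_specific: tuple[PlantedSpecific, ...] = (
        PlantedSpecific("specific-arthritis-drug", ("arthritis-main-01",)),
        PlantedSpecific("specific-orbit-drug", ("arthritis-orbit-01",)),
        PlantedSpecific("specific-skin-drug", ("skin-01",)),
    )
    planted_common: tuple[PlantedCommon, ...] = (
        # Staggered in-set boosts spread the commons along the front
        # (frequency falling, specificity rising) instead of stacking them
        # into a single domination chain.
        PlantedCommon("common-drug-a", 0.35, inset_boost=1.5),
        PlantedCommon("common-drug-b", 0.28, inset_boost=1.8),
        PlantedCommon("common-drug-c", 0.22, inset_boost=2.1),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recipes < 1:
            raise ValueError("n_recipes must be positive")
        for p in self.planted_specific:
            if not (0 <= p.in_rate <= 1 and 0 <= p.out_rate <= 1):
                raise ValueError(f"rates of {p.drug!r} must lie in [0, 1]")
        for p in self.planted_common:
            if not 0 <= p.rate <= 1:
                raise ValueError(f"rate of {p.drug!r} must lie in [0, 1]")
        names = [p.drug for p in self.planted_specific] + [
            p.drug for p in self.planted_common
        ]
        if len(names) != len(set(names)):
            raise ValueError("planted drug names must be disjoint")

    def search_terms(self) -> frozenset[SearchTerm]:
        """The search-term table matching this spec's term vocabulary."""
        terms = [
            SearchTerm(f"arthritis-main-{i + 1:02d}", "arthritis", "main")
            for i in range(self.n_main_terms)
        ]
        terms += [
            SearchTerm(f"arthritis-orbit-{i + 1:02d}", "arthritis", "orbit")
            for i in range(self.n_orbit_terms)
        ]
        terms += [SearchTerm(f"skin-{i + 1:02d}", "skin") for i in range(self.n_skin_terms)]
        return frozenset(terms)


@dataclass
class CorpusTruth:
    """Ground truth of a generated corpus, for oracle tests.

    ``specific`` and ``common`` map planted drug names to the recipe ids
    that contain them; ``term_recipes`` maps each search term to the recipes
    linked to it; ``inset_recipe_ids`` are all recipes linked to any search
    term.
    """

    specific: dict[str, dict]
    common: dict[str, list[str]]
    term_recipes: dict[str, list[str]]
    inset_recipe_ids: list[str]
    specialist_drugs: list[str] = field(default_factory=list)

    @property
    def planted_drugs(self) -> list[str]:
        return list(self.specific) + list(self.common)

    def to_json(self, path: str | Path) -> Path:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "specific": self.specific,
                    "common": self.common,
                    "term_recipes": self.term_recipes,
                    "inset_recipe_ids": self.inset_recipe_ids,
                    "specialist_drugs": self.specialist_drugs,
                },
                fh,
            )
        return Path(path)


def _term_weights(spec: CorpusSpec) -> tuple[list[str], np.ndarray]:
    """Search-term sampling weights: power-law within each category,
    category masses fixed, mirroring the skewed per-term recipe counts of
    real indication tables."""
    names: list[str] = []
    weights: list[float] = []
    groups = (
        ([f"arthritis-main-{i + 1:02d}" for i in range(spec.n_main_terms)], spec.category_mass[0]),
        ([f"arthritis-orbit-{i + 1:02d}" for i in range(spec.n_orbit_terms)], spec.category_mass[1]),
        ([f"skin-{i + 1:02d}" for i in range(spec.n_skin_terms)], spec.category_mass[2]),
    )
    for group, mass in groups:
        w = np.array([1.0 / (r + 1) ** spec.term_exponent for r in range(len(group))])
        w = mass * w / w.sum()
        names += group
        weights += list(w)
    w = np.array(weights)
    return names, w / w.sum()


def generate_corpus(spec: CorpusSpec) -> tuple[Corpus, CorpusTruth]:
    """Generate a corpus with planted frequency/specificity structure.

    Raises ``ValueError`` when a planted drug's expected occurrence count is
    below one (an infeasible rate for the corpus size).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_recipes

    # --- indications -------------------------------------------------------
    term_names, term_w = _term_weights(spec)
    bg_terms = [f"indication-{i + 1:03d}" for i in range(spec.n_background_terms)]
    bw = np.array([1.0 / (r + 1) ** 0.8 for r in range(len(bg_terms))])
    bw /= bw.sum()

    inset = rng.random(n) < spec.search_fraction
    t1 = rng.choice(len(term_names), size=n, p=term_w)
    has_t2 = rng.random(n) < spec.second_term_rate
    t2 = rng.choice(len(term_names), size=n, p=term_w)
    bg_choice = rng.choice(len(bg_terms), size=n, p=bw)
    bg2_choice = rng.choice(len(bg_terms), size=n, p=bw)
    has_bg2 = rng.random(n) < 0.3
    inset_has_bg = rng.random(n) < spec.background_term_rate_inset

    indications: list[set[str]] = []
    for i in range(n):
        terms: set[str] = set()
        if inset[i]:
            terms.add(term_names[t1[i]])
            if has_t2[i]:
                terms.add(term_names[t2[i]])
            if inset_has_bg[i]:
                terms.add(bg_terms[bg_choice[i]])
        else:
            terms.add(bg_terms[bg_choice[i]])
            if has_bg2[i]:
                terms.add(bg_terms[bg2_choice[i]])
        indications.append(terms)

    # --- background ingredients (weighted sample w/o replacement) ----------
    drugs = [f"drug-{i + 1:03d}" for i in range(spec.n_background_ingredients)]
    ranks = np.arange(1, len(drugs) + 1, dtype=float)
    dw_out = ranks**-spec.ingredient_exponent
    dw_out /= dw_out.sum()
    # Recipes linked to a search term draw from a restricted repertoire:
    # generalist drugs (the head of the power law, used for everything) plus
    # a specialist pool of rarer drugs historically associated with these
    # indications.  Unmatched tail drugs never enter the selection, and
    # specialists concentrate most of their corpus occurrences inside it —
    # together this reproduces the inverse relation between overall
    # frequency and indication-specific relative frequency.
    n_gen = min(spec.n_generalist_drugs, len(drugs))
    specialist_idx = rng.choice(
        np.arange(n_gen, len(drugs)),
        size=min(spec.n_specialist_drugs, len(drugs) - n_gen),
        replace=False,
    )
    dw_in = np.zeros(len(drugs))
    head = ranks[:n_gen] ** -spec.ingredient_exponent
    dw_in[:n_gen] = (1.0 - spec.specialist_mass) * head / head.sum()
    dw_in[specialist_idx] = spec.specialist_mass / max(len(specialist_idx), 1)

    linked_to = {t: np.array([t in s for s in indications]) for t in term_names}
    inset_any = np.array([any(t in s for t in term_names) for s in indications])

    k = np.minimum(
        rng.poisson(max(spec.mean_ingredients - 1.0, 0.0), size=n) + 1, len(drugs)
    )
    k = np.where(inset_any, np.minimum(k, int((dw_in > 0).sum())), k)
    # Gumbel-top-k: the k largest of log(w)+Gumbel noise are a weighted
    # sample without replacement.
    gumbel = rng.gumbel(size=(n, len(drugs)))
    with np.errstate(divide="ignore"):
        logw = np.where(
            inset_any[:, None], np.log(dw_in)[None, :], np.log(dw_out)[None, :]
        )
    order = np.argsort(-(logw + gumbel), axis=1)

    spec_masks: dict[str, np.ndarray] = {}
    for p in spec.planted_specific:
        target = np.zeros(n, dtype=bool)
        for t in p.terms:
            if t not in linked_to:
                raise ValueError(f"planted drug {p.drug!r} targets unknown term {t!r}")
            target |= linked_to[t]
        exp_in = p.in_rate * int(target.sum())
        if exp_in < 1:
            raise ValueError(
                f"infeasible rates for {p.drug!r}: expected in-set count {exp_in:.2f} < 1"
            )
        prob = np.where(target, p.in_rate, p.out_rate)
        spec_masks[p.drug] = rng.random(n) < prob

    common_masks: dict[str, np.ndarray] = {}
    for p in spec.planted_common:
        prob = np.where(inset_any, min(p.rate * p.inset_boost, 1.0), p.rate)
        if p.rate * n < 1:
            raise ValueError(f"infeasible rate for {p.drug!r}: expected count < 1")
        common_masks[p.drug] = rng.random(n) < prob

    # --- assemble records ---------------------------------------------------
    records = []
    recipe_ids = [f"R{i + 1:05d}" for i in range(n)]
    for i in range(n):
        ingredients = {drugs[j] for j in order[i, : k[i]]}
        for d, mask in spec_masks.items():
            if mask[i]:
                ingredients.add(d)
        for d, mask in common_masks.items():
            if mask[i]:
                ingredients.add(d)
        records.append(
            RecipeRecord(
                recipe_id=recipe_ids[i],
                indications=frozenset(indications[i]),
                ingredients=frozenset(ingredients),
                title=f"recipe {i + 1}",
                source_id=f"MS{i % 40 + 1:03d}",
            )
        )
    corpus = Corpus(records)

    ids = np.array(recipe_ids)
    truth = CorpusTruth(
        specific={
            p.drug: {
                "terms": list(p.terms),
                "in_rate": p.in_rate,
                "out_rate": p.out_rate,
                "recipe_ids": ids[spec_masks[p.drug]].tolist(),
            }
            for p in spec.planted_specific
        },
        common={p.drug: ids[common_masks[p.drug]].tolist() for p in spec.planted_common},
        term_recipes={t: ids[linked_to[t]].tolist() for t in term_names},
        inset_recipe_ids=ids[inset_any].tolist(),
        specialist_drugs=[drugs[i] for i in sorted(specialist_idx)],
    )
    return corpus, truth


# ---------------------------------------------------------------------------
# Binding-plate generator
# ---------------------------------------------------------------------------


def default_motif_names(n_motifs: int = 101) -> tuple[str, ...]:
    """Motif identifiers: the named coregulator motifs first, then filler."""
    named = ("NCOA1", "PELP1", "DHX30", "NCOR2", "IKBB")
    filler = tuple(f"MOTIF_{i:03d}" for i in range(len(named) + 1, n_motifs + 1))
    return (named + filler)[:n_motifs]


def default_gc_effect() -> dict[str, float]:
    """Fold changes induced by the cortisol control on GC-responsive motifs.

    NCOA1 carries the canonical strong coactivator induction (over
    1,000-fold); a handful of further motifs respond moderately in either
    direction, and the shared motif IKBB responds to both cortisol and
    plant fractions.
    """
    eff = {"NCOA1": 1200.0, "IKBB": 6.0}
    up = {f"MOTIF_{i:03d}": f for i, f in zip(range(10, 20), (8, 6, 5, 4, 4, 3, 3, 2.5, 2.5, 2))}
    down = {f"MOTIF_{i:03d}": f for i, f in zip(range(20, 24), (0.3, 0.35, 0.4, 0.45))}
    eff.update(up)
    eff.update(down)
    return eff


@dataclass(frozen=True)
class ClusterSpec:
    """A planted activity cluster: a Gaussian LFC bump over fraction index."""

    motifs: tuple[str, ...]
    center: float
    width: float
    peak_lfc: float

    def __post_init__(self) -> None:
        if not 1 <= self.center <= 96:
            raise ValueError("cluster center must lie in [1, 96]")
        if self.peak_lfc <= 0:
            raise ValueError("peak LFC must be positive")
        if self.width <= 0:
            raise ValueError("cluster width must be positive")

    def true_lfc(self, index: np.ndarray) -> np.ndarray:
        return self.peak_lfc * np.exp(
            -((np.asarray(index, dtype=float) - self.center) ** 2)
            / (2.0 * self.width**2)
        )

    def bounds(self, threshold: float) -> tuple[int, int]:
        """First and last fraction index with true LFC >= threshold."""
        if threshold >= self.peak_lfc:
            c = int(round(self.center))
            return c, c
        half = self.width * math.sqrt(2.0 * math.log(self.peak_lfc / threshold))
        lo = max(1, math.ceil(self.center - half))
        hi = min(96, math.floor(self.center + half))
        return lo, hi


@dataclass(frozen=True)
class InhibitionSpec:
    """A competition (spiking) scenario appended to a plate.

    ``scenario`` decides which stimulus-responsive motifs the spiked soluble
    motif suppresses back to the Apo level: all of them (``full``), none
    (``none``) or the fraction ``partial_fraction`` of them (``partial``).
    """

    stimulus_well: str
    spiked_motif: str
    scenario: str = "full"
    partial_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.scenario not in ("full", "none", "partial"):
            raise ValueError(f"unknown inhibition scenario {self.scenario!r}")


@dataclass(frozen=True)
class PlateSpec:
    """Parameters of a synthetic binding plate.

    101 motifs and 96 fractions match the emulated assay layout.  The Apo
    baseline is log-normal across motifs; replicate noise is log-normal with
    coefficient of variation ``noise_cv`` (default 10%), the conventional
    model for strictly positive fluorescence intensities.  Screening plates
    carry a single fraction replicate; confirmation and competition plates
    carry three.
    """

    plant_id: str = "plant-01"
    n_motifs: int = 101
    n_fractions: int = 96
    baseline_median: float = 500.0
    baseline_sigma: float = 0.6
    gc_effect: Mapping[str, float] = field(default_factory=default_gc_effect)
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec(("PELP1", "DHX30", "NCOR2", "IKBB"), center=30.0, width=2.0, peak_lfc=2.0),
    )
    control: str = "cortisol"
    replicates_control: int = 3
    replicates_fraction: int = 1
    noise_cv: float = 0.10
    inhibition: InhibitionSpec | None = None
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_fractions <= 96:
            raise ValueError("n_fractions must lie in [1, 96]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not self.allow_overlap:
            seen: dict[str, list[tuple[int, int]]] = {}
            for c in self.clusters:
                lo, hi = c.bounds(threshold=min(0.5, c.peak_lfc))
                for m in c.motifs:
                    for lo2, hi2 in seen.get(m, []):
                        if lo <= hi2 and lo2 <= hi:
                            raise ValueError(
                                f"overlapping clusters on motif {m!r}; "
                                "set allow_overlap=True to merge them"
                            )
                    seen.setdefault(m, []).append((lo, hi))

    def motifs(self) -> tuple[str, ...]:
        return default_motif_names(self.n_motifs)


@dataclass
class PlateTruth:
    """Ground truth of a generated plate."""

    gc_motifs: dict[str, float]
    clusters: list[dict]
    responsive_motifs: list[str]
    intended_call: str | None

    def to_json(self, path: str | Path) -> Path:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh)
        return Path(path)


def generate_plate(
    spec: PlateSpec, truth_threshold: float = 0.5
) -> tuple[BindingPlate, PlateTruth]:
    """Generate a binding plate and its truth record.

    ``truth_threshold`` is the |LFC| level defining the recorded truth
    boundaries of each planted cluster (matching the detector's default).
    """
    rng = np.random.default_rng(spec.seed)
    motifs = spec.motifs()
    m_index = {m: i for i, m in enumerate(motifs)}
    for c in spec.clusters:
        for m in c.motifs:
            if m not in m_index:
                raise ValueError(f"cluster motif {m!r} not on the plate")

    apo_mu = spec.baseline_median * np.exp(
        rng.normal(0.0, spec.baseline_sigma, size=len(motifs))
    )
    sigma_ln = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0

    frac_idx = np.arange(1, spec.n_fractions + 1)
    true_lfc = np.zeros((len(motifs), spec.n_fractions))
    for c in spec.clusters:
        bump = c.true_lfc(frac_idx)
        for m in c.motifs:
            true_lfc[m_index[m]] += bump

    rows: list[tuple[str, str, str, int, float]] = []

    def emit(condition: str, well: str, mean: np.ndarray, n_rep: int) -> None:
        for r in range(1, n_rep + 1):
            noise = (
                np.exp(rng.normal(0.0, sigma_ln, size=len(motifs)))
                if sigma_ln > 0
                else np.ones(len(motifs))
            )
            vals = mean * noise
            rows.extend(
                (motifs[i], condition, well, r, float(vals[i]))
                for i in range(len(motifs))
            )

    emit(APO, "", apo_mu, spec.replicates_control)

    gc_fold = np.ones(len(motifs))
    for m, f in spec.gc_effect.items():
        if m in m_index:
            gc_fold[m_index[m]] = f
    emit(spec.control, "", apo_mu * gc_fold, spec.replicates_control)

    for j, idx in enumerate(frac_idx):
        well = index_to_well(int(idx))
        emit(well, well, apo_mu * 2.0 ** true_lfc[:, j], spec.replicates_fraction)

    responsive: list[str] = []
    intended_call: str | None = None
    if spec.inhibition is not None:
        inh = spec.inhibition
        from .plates import well_to_index as _w2i

        j = _w2i(inh.stimulus_well) - 1
        if j >= spec.n_fractions:
            raise ValueError(f"stimulus well {inh.stimulus_well!r} beyond fraction range")
        stim_mean = apo_mu * 2.0 ** true_lfc[:, j]
        responsive = [
            motifs[i]
            for i in range(len(motifs))
            if abs(true_lfc[i, j]) >= truth_threshold
        ]
        if inh.scenario == "full":
            reduced = set(responsive)
            intended_call = "+"
        elif inh.scenario == "none":
            reduced = set()
            intended_call = "-"
        else:
            n_red = math.ceil(inh.partial_fraction * len(responsive))
            reduced = set(responsive[:n_red])
            intended_call = "±"
        spike_mean = stim_mean.copy()
        for m in reduced:
            spike_mean[m_index[m]] = apo_mu[m_index[m]]  # suppressed to baseline
        emit(
            f"{inh.stimulus_well}+{inh.spiked_motif}",
            "",
            spike_mean,
            spec.replicates_control,
        )

    plate = BindingPlate(
        spec.plant_id,
        pd.DataFrame(rows, columns=["motif", "condition", "well", "replicate", "value"]),
    )
    truth_clusters = []
    for c in spec.clusters:
        lo, hi = c.bounds(truth_threshold)
        apex = int(np.clip(round(c.center), lo, hi))
        truth_clusters.append(
            {
                "motifs": list(c.motifs),
                "center": c.center,
                "width": c.width,
                "peak_lfc": c.peak_lfc,
                "start": lo,
                "end": hi,
                "apex": apex,
            }
        )
    truth = PlateTruth(
        gc_motifs={m: f for m, f in spec.gc_effect.items() if m in m_index},
        clusters=truth_clusters,
        responsive_motifs=responsive,
        intended_call=intended_call,
    )
    return plate, truth
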
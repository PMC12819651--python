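# Methods

`herbscreen` implements a two-stage candidate-discovery pipeline: (1)
Pareto-front mining of a historical medical-recipe corpus to rank botanical
drugs by how frequently *and* how specifically they were used for a chosen
set of disease indications, and (2) analysis of nuclear-receptor coregulator
binding plates to find plant fractions that modulate glucocorticoid-receptor
(GR) activity and to classify their mechanism through competition
experiments. Because neither a public recipe corpus of this kind nor the
assay's raw plates are generally available, the package ships a first-class
synthetic-data module whose generators plant known signal so that every
stage can be validated against ground truth.

## Stage 1 — Pareto-front mining of a recipe corpus

### Data model and dataset construction

A corpus is a set of recipes, each carrying a non-empty set of normalized
indication terms and a non-empty set of ingredient identifiers (botanical
drug names). Ingredients are sets: a drug listed twice in one recipe counts
once, so every frequency below means recipe-level presence. Term matching is
exact string equality after whitespace-collapsing and case-folding — corpus
indications are assumed pre-standardized, and no fuzzy matching is
attempted.

A search-term table (term, category ∈ {arthritis, skin}, granularity ∈
{main, orbit} for arthritis terms) selects the joint dataset: every recipe
whose indications intersect the term set, counted once however many terms it
matches. Four subsets refine it: recipes linked to any arthritis term
(subset A), to a main-granularity arthritis term only (B), to any skin term
(C), and to both an arthritis and a skin term (D = A ∩ C). Within subset A
each recipe is attributed to exactly one of Main/Orbit; a single
main-granularity link wins, making the attribution a partition (so
|Main| + |Orbit| = |A| always).

### Frequency metrics and ranking

For a selection S and drug d:

- f₁(d) = number of recipes in S containing d (frequency);
- f₂(d) = 100 · f₁(d) / n_corpus(d), where n_corpus(d) is d's recipe count
  in the *entire* corpus (relative frequency, a specificity measure). f₂ is
  never normalized to the selection. Reporting rounds f₂ to one decimal;
  all comparisons use full precision.

Drugs with f₁ below a minimum count (default 10) in the joint dataset are
removed before ranking; recipes left without any retained ingredient, and
then search terms left without any linked recipe, are dropped in cascade,
with all drop counts reported. The filter is applied once, on the joint
dataset; subsets inherit the filtered drug list, so a drug cannot re-enter
through a subset where it happens to be locally frequent.

Both metrics are jointly maximized by iterative Pareto-front ranking: point
a dominates b iff a is ≥ b in both objectives and > in at least one; rank 1
is the non-dominated set; peeling it and repeating yields ranks 2, 3, …
(default maximum 3). Points with identical coordinates share a rank, since
weak dominance cannot separate them and any tie-break would be arbitrary.
The implementation peels fronts with an O(n log n) sort-and-sweep per front;
its equivalence to brute-force O(n²) repeated non-dominated-set extraction
is asserted in the test suite on random instances up to 500 points.

A rank matrix aggregates the joint dataset's rank ≤ 3 candidates against
their per-subset ranks (empty cell where a candidate does not occur in a
subset) and joins an optional literature-classification label
(specific / unspecific / toxic), which is consumed as an annotation file
and never computed.

## Stage 2 — Coregulator binding-profile analysis

A binding plate records fluorescence for GR binding to 101 immobilized
coregulator peptide motifs under: the unstimulated receptor (Apo), a
glucocorticoid control (cortisol), up to 96 sequential plant fractions, and
optional spiked (competition) conditions. Fraction wells are mapped to
1-based row-major indices (A1→1 … H12→96); the reverse-phase fractionation
order makes this index a chemical gradient.

**Modulation.** Per motif, LFC = log₂(mean(condition)+ε) − log₂(mean(Apo)+ε)
with a pseudo-count ε = 1 fluorescence unit guarding zeros; log₂ is the
assay convention. Where both sides carry ≥ 2 technical replicates, a Welch
two-sample t-test (two-sided) is computed per motif, with star tiers
p < 0.05 / 0.01 / 0.001. No multiple-testing correction is applied across
the 101 motifs — stars are per-motif descriptions, not family-wise claims.
Screening plates carry a single fraction replicate, so hit finding there is
threshold- and shape-based, never p-value-based.

**Motif classification.** A motif is counted as modulated by a condition
when |LFC| reaches the threshold (default 0.5) and, where replicates permit,
the Welch test is significant at α = 0.05. The effect-size gate matters: at
α = 0.05 without it, ~5% of quiet motifs would be called responsive by
noise alone, which in particular corrupts competition calls (below).
Classes: *GC-responsive* (control only), *plant-exclusive* (fractions
only), *shared* (both), *unresponsive* (neither).

**Cluster detection.** For each plant-responsive motif (plant-exclusive and
shared), maximal contiguous runs of fractions with |LFC| ≥ threshold are
extracted on the fixed 1–96 grid. Runs of length ≥ 3 qualify when their
|LFC| profile is unimodal: among all candidate peak positions, the minimum
number of successive-difference sign violations against a rise-then-fall
shape is ≤ 1 (zero differences are neutral). Unimodality is the
deterministic surrogate for the visual bell-shape criterion: a genuine
metabolite spreads over adjacent fractions as a concentration gradient,
while isolated noisy wells do not form unimodal runs. Overlapping runs from
different motifs merge into one active cluster whose motif set records the
contributors; the apex is the fraction maximizing mean |LFC| over that set.

**Apex confirmation.** The apex fraction is retested with ≥ 3 technical
replicates; a cluster is confirmed iff at least one of its motifs is
significant at α = 0.05 in the direction seen on the screening plate.

**Competition (inhibition) calls.** Spiking the assay with a soluble motif
competes one-to-one for the receptor's coregulator-binding surface. The
responsive motif set is taken from the unspiked stimulus (significantly
induced with LFC ≥ threshold); each responsive motif is then tested
one-sidedly (Welch, α = 0.05) for reduced binding under spiking. The call
is "+" when all responsive motifs are reduced, "−" when fewer than half
are, and "±" when the reduced proportion lies in [0.5, 1). The band is a
documented, configurable stand-in for the three-level calls used in
practice, where no quantitative rule is standard.

## Synthetic data

### Recipe corpus

The default corpus scales a realistic manuscript corpus down by roughly 8×:
5,000 recipes, 350 background indication terms, 444 background ingredients,
about 6 ingredients per recipe, with 28 search terms (6 main + 9 orbit
arthritis, 13 skin) and ~6% of recipes linked to a search term. Search-term
usage is power-law within each category with category masses 0.2/0.3/0.5
(main/orbit/skin), mirroring the heavy skew of real per-term recipe counts.

Ingredient usage is power-law (exponent 0.7): few ubiquitous drugs, a long
tail. Recipes linked to a search term draw from a restricted repertoire —
15 generalist drugs (the power-law head) plus a 60-drug specialist pool of
rarer drugs associated with these indications (sharing 65% of the in-set
ingredient mass). This structure is what produces the inverse relation
between f₁ and f₂ that motivates Pareto ranking: generalists are frequent
everywhere (high f₁, f₂ ≈ the selection's share of their use), specialists
concentrate their occurrences inside the selection (modest f₁, high f₂),
and unmatched tail drugs never enter it. Spearman ρ(f₁, f₂) over selection
drugs is ≈ −0.2 and negative in every tested seed.

Planted signal comes in two kinds, both recorded in a truth file: three
*specific* drugs (in recipes linked to their target term with probability
0.7, elsewhere 0.0005 — high f₂, modest f₁) and three *common* drugs
(corpus-wide rates 0.35/0.28/0.22 with in-set boosts 1.5/1.8/2.1). The
staggered boosts spread the commons along the front — frequency falling as
specificity rises — instead of stacking them into one domination chain; the
same geometry seen in real rank-1 fronts. Rates whose expected planted
count falls below one recipe are rejected as infeasible.

What the generator does **not** emulate: historical/linguistic structure of
indications, dosage and preparation, co-occurrence dependencies between
ingredients beyond the planted ones, and manuscript-level clustering of
recipes. Passing recovery tests therefore shows the estimator recovers
planted frequency/specificity structure at realistic sizes — not that any
particular historical claim is validated.

### Binding plates

Per-motif Apo baselines are log-normal (median 500, σ = 0.6 across motifs).
The cortisol control multiplies GC-responsive motifs by planted folds —
canonically > 1,000-fold on the NCOA1-like coactivator motif, moderate folds
up and down on ~15 further motifs, and a shared motif (IKBB) that also
responds to fractions. Planted activity clusters are Gaussian LFC bumps
over the fraction index (default: motifs PELP1/DHX30/NCOR2/IKBB, center 30,
width 2, peak LFC 2 → a ~7-fraction run above the 0.5 threshold).
Replicate noise is log-normal with CV 10% — the standard model for strictly
positive fluorescence intensities; the paper-style assay publishes no noise
model, so the CV is a parameter. Screening plates carry 1 fraction
replicate, confirmation and competition plates 3. Competition scenarios
suppress all / none / 60% of the stimulus-responsive motifs back to the Apo
level. Truth records carry cluster boundaries at the detection threshold,
responsive motifs and the intended call.

## Numerical and design choices

- Welch test implemented row-vectorized (Welch–Satterthwaite df, `scipy`
  t distribution); degenerate zero-variance cells give p = 1 when means are
  equal, p = 0 otherwise; unreplicated cells give no p-value. The
  implementation is verified against `scipy.stats.ttest_ind` in the tests.
  At n = 3 vs 3 the Welch test is conservative (true size ≈ 3.5% at
  α = 0.05); calibration suites therefore use ≥ 10⁴ motif-tests so the
  estimate's sampling noise is small against that size.
- Pareto ties: coincident points share a rank; the sweep operates on
  distinct coordinates.
- Cluster runs are evaluated on the fixed 96-well grid, so wells missing
  from a plate break contiguity rather than being bridged.
- Apex tie-break: `argmax` takes the first maximum in sequential order.
- Problem sizes in the validation suites: 100 random instances up to 500
  points for oracle equivalence; 50 corpora of 5,000 recipes for planted
  recovery; 200 plates for cluster recovery and 20 null plates for the
  false-positive rate; ≥ 10⁴ motif-tests for type-I calibration.

## Known limitations

- The ranking is descriptive: corpus composition bias (regional disease
  prevalence, plant availability, author preference) is not modeled or
  corrected, and no normalization of per-indication recipe counts is
  attempted.
- The significance machinery treats technical replicates as the unit of
  error; plate-to-plate normalization is out of scope and plates are
  analyzed independently.
- The "±" competition band and the unimodality tolerance are documented
  surrogates for visual judgments; both are configurable.
- Search-term identification, literature classification of drugs and
  compound identification are inputs, not computations.
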
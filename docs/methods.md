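# Methods

`semhub` implements two complementary literature-mining procedures for
profiling drug-class adverse events (AEs), built around the concrete use
case of tyrosine kinase inhibitors (TKIs) for chronic myeloid leukemia but
applicable to any drug class with a labelled abstract corpus and a
predication knowledge graph.

## Corpus arm: TF-IDF / k-means AE profiling

**Model.** Abstracts are cleaned (lowercase, punctuation stripped,
stopwords removed, noun plurals lemmatized) and vectorized as a TF-IDF
matrix restricted to terms whose document frequency lies in the inclusive
band [`min_df`, `max_df`] = [0.01, 0.85] by default: rare hapax noise and
near-universal boilerplate carry no clustering signal. The weight
convention is fixed explicitly so toy corpora can be verified by hand:

    w(d, t) = tf(d, t) · ( ln((1 + N) / (1 + df_count(t))) + 1 )

with L2 row normalisation — the standard smoothed-idf convention. The
matrix is projected to 50 truncated-SVD components (seeded, randomized
solver; the reported explained-variance ratio is the uncentered energy
fraction s_i²/‖M‖_F², which is non-increasing by construction) and
clustered with k-means (default k = 30; k is a free parameter — there is
no principled selection rule at this corpus scale, and profiling runs on
whichever clusters map cleanly to drugs).

**Lemmatizer.** A rule-based noun-plural lemmatizer (exception table +
suffix rules, id `semhub-rule-noun-v1`, recorded in `config_snapshot()`).
Only noun plurals are folded; verb inflections are left alone. Real corpora
processed with a different lemmatizer will yield slightly different
vocabularies; no attempt is made to match any particular published
vocabulary size.

**Cluster→drug mapping and statistics.** A cluster maps to a drug when
that drug's in-cluster document frequency is maximal over clusters and
above a configurable floor; ties report all tied drugs and flag the
cluster ambiguous rather than picking silently. Term statistics are
document-level presence fractions (a term counts once per abstract);
fold change is cluster frequency over corpus frequency. Cluster AE
profiles are compared pairwise with the plain Pearson chi-square of
independence (no continuity correction, so the Σ(O−E)²/E oracle is exact)
over AE-term × cluster document-presence counts; term rows with a zero
pair total are dropped with a warning. The family-wise α = 0.05 is
Bonferroni-corrected by the number of unordered cluster pairs. Whether the
contingency should use token counts or document counts is not a settled
convention; document counts match the presence-fraction framing used
everywhere else in this module.

## Graph arm: HeteSim ranking, TransE link prediction, hub networks

**Knowledge graph.** Directed subject–PREDICATE–object predications with
UMLS-style semantic types; duplicate triples merge by summing occurrence
counts. Node identity is the concept id; names are display-only. A small
default stoplist (`protein`, `complication`, `infection`, `disease`)
removes generic high-frequency concepts that act as ranking artifacts.

**HeteSim (length-2 metapaths).** For schema metapath
s –(p₁,d₁)→ M –(p₂,d₂)→ t with middle type τ, similarity is the cosine of
the forward transition-probability vector from s and the backward vector
from t, both over nodes of type τ. Per-pair relevance is the arithmetic
mean over all schema metapaths supported (nonzero) at both endpoints.
This is the standard HeteSim construction for even-length metapaths;
path length is fixed at 2 — longer reach comes from hub analysis, not
longer metapaths, because metapath extension grows noise exponentially.
Scores are reported as `score = 1 − similarity` (lower = stronger), and a
novelty score `similarity / (1 + ln(1 + w(s)))` discounts relevance by the
source's weighted degree, surfacing under-published connections. The
novelty formula is this package's own construction satisfying that
qualitative behaviour (monotone decreasing in publication mass, equal to
raw similarity for unseen concepts); it is not a published formula.

Multi-target ranking averages similarity across *all* targets, an
unsupported target contributing zero: a candidate supported broadly across
the target set must outrank one with a single incidental one-hot match —
averaging only over supported targets was tried and rewards exactly the
wrong candidates. A candidate that itself appears in the target list is
scored against the remaining targets (self-relevance is trivial); since
disease nodes are among the admitted neighborhood types, dropping such
candidates entirely would exile strongly linked conditions from every
simulation they matter most in.

**TransE.** Entities and relations embedded in R^32 with margin-ranking
loss (margin 1.0, L2 distance, uniform head-or-tail corruption, minibatch
SGD with lr 0.05, batch 64, 200 epochs, entity renormalisation each epoch,
fully seeded). These are desk-scale defaults: loss plateaus well before
200 epochs on graphs of a few hundred nodes, and each configuration value
is exposed in `TransEConfig`. Predicted links carry

    raw_weight = exp(−distance) / (1 + ln(1 + weighted_degree(tail)))

min-maxed to [0,1] per candidate list (a single-candidate or all-tied list
maps to 1.0, the best available). The degree discount keeps hub-like tails
from dominating through connectivity alone; the exact formula is this
package's construction. Filtered evaluation: hits@k excludes observed
training tails and ranks among candidates of the true tail's type.

**Hub pipeline.** Hubs = top-n (default 6) shared neighbors of two anchor
concepts by weighted degree (manual override supported — real hub choices
involve judgment). Each hub's neighborhood is the union of entity
predictions over CAUSES, PRECEDES, AUGMENTS, DISRUPTS, STIMULATES, AFFECTS
restricted to AAPP/BACS/DSYN/GNGM/PHSU, deduplicated at each node's
maximum normalised weight and capped (default 25). Per-hub simulations
rank DSYN sources against {focal node} ∪ neighborhood, min-max normalise
the lower-is-stronger scores to [0,1] (single-candidate simulations
normalise to 0, the strongest value), and aggregate:

    composite(c) = occurrence_rate(c) × (1 − mean_normalized_score(c))

ranked descending with id tie-break. The product form is this package's
choice: it is monotone in both aggregation ingredients, bounded in [0,1],
and equals 1 exactly for a candidate present in every simulation with the
strongest score throughout. Candidate score lists are sorted before
averaging so aggregation is exactly invariant to simulation order. Tiers
cut the ranking at the top 1% / 5% / 10% using ceilings (no tier is empty
for any N ≥ 1); foci labels come from a curated two-column file — foci are
ontology/judgment products and are deliberately not automated — and a
curation template with an `agrees`/`disagrees`/`missing` verdict column
supports human-in-the-loop review.

## Synthetic data

`synthgen` emulates the two study inputs with known ground truth.

*Corpus*: 5 drugs × 50 abstracts of 100 tokens by default; a Zipf-weighted
background vocabulary of 200 terms; 4 AE terms per drug entering at the
mean background weight and boosted ×5 (the enrichment factor) in the
owning drug's abstracts; the drug name always present and boosted equally.
It does not emulate real English, token co-occurrence structure, or
cross-drug mentions — passing recovery tests shows the pipeline machinery
is correct under label-dependent enrichment, not that any particular real
corpus separates.

*Graph*: ~370 nodes by default (200 DSYN; protein/substance/gene layers),
two anchors, six high-degree hub neighbors shared by both anchors plus
six low-degree decoys, per-hub communities of 8 protein members linked by
random 3-subsets of the six causal predicates, 10 planted "relevant" DSYN
nodes sharing bridge middles with community members (the property HeteSim
detects), background DSYN with sparse random middles, geometric edge
weights (literature co-occurrence skew), ~0.4% uniform noise edges, and a
10% holdout of hub–community edges for link-prediction validation.
Middle-layer protein edges use association predicates
(INTERACTS_WITH/COEXISTS_WITH/ASSOCIATED_WITH), as predication databases
do; community members are drawn from the protein layer so that held-out
tails live in a candidate pool much larger than k — hits@10 over a pool of
fewer than ten candidates would be degenerate. A 200-entity variant
(protein-heavy) is used for the link-prediction benchmark; problem sizes
were chosen so the full test suite and the acceptance script each run in
minutes on one CPU.

## Numerical choices and degenerate inputs

- df bounds are inclusive with a 1e-12 count tolerance against float
  rounding of fractional thresholds.
- Ties everywhere break lexicographically by term or node id, so all
  orderings are deterministic.
- Empty abstract → record rejected with a warning; empty vocabulary after
  filtering, k > n_docs, infeasible SVD components → explicit errors, no
  silent clamping.
- HeteSim returns 0 for a metapath with an empty endpoint vector and leaves
  a pair with no supported metapath unranked rather than scoring it 0.
- All randomness (SVD, t-SNE, k-means, TransE init/corruption, generators)
  flows through explicit integer seeds.

## Known limitations

- The HeteSim variant, novelty formula, degree-normalised weight, and
  composite aggregation are reasoned constructions, not published
  formulas; numeric agreement with any published score table is out of
  scope.
- Length-2 metapaths only; the hub mechanism is the sanctioned way to
  extend reach.
- The lemmatizer folds noun plurals only; it is not a full morphological
  analyser.
- rank_sources recomputes step vectors per candidate; fine at desk scale,
  not engineered for a 30-million-abstract graph.
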
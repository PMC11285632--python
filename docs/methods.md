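# Methods

## Problem setting

Given (i) a differential-expression table from a treatment-vs-control
comparison, (ii) a library of replicate ranked expression profiles per
compound, and (iii) compound annotations (targets, predicted off-targets,
side effects), the pipeline ranks compounds by transcriptomic similarity to
the treatment and asks which annotations are over-represented among the
most similar compounds. All rankings are full permutations of a fixed gene
universe; the package never touches raw intensities or counts, and it does
not recompute differential expression — the DEG table is an input.

## Prototype ranked list merging

Replicates of one compound are aggregated by greedy hierarchical
agglomeration: at each step the two current lists with the smallest
*normalized Spearman footrule* distance are replaced by their *Borda merge*
(each gene scored by the mean of its two ranks, re-sorted ascending). The
footrule is `Σ_g |rank_a(g) − rank_b(g)|`, normalized by `⌊N²/2⌋` — the
maximum, attained by the exact reversal — so distances are comparable
across universe sizes.

Design choices where the method family leaves room:

- **Mean-rank information is discarded after each merge**: the merged list
  re-enters the pool as a bare permutation. Every intermediate object then
  satisfies the same bijection invariant, which keeps validation uniform.
- **All tie-breaking is lexicographic on identifiers** — equal mean ranks
  break by gene id, equal pair distances by the sorted pair of list labels
  (replicate ids; a merged list is labelled by its children, e.g.
  `(r1+r3)`). No positional or random state enters, so the PRL is invariant
  under permutation of the input replicates, which the tests assert.
- **Replicates are unweighted.** Covariates such as cell line or dose are
  not modelled; a weighted merge would need metadata the rank formats do
  not carry.

## Query signature and connectivity scoring

A gene enters the query if its BH-adjusted p-value is strictly below the
FDR threshold (default 0.05); the sign of the log2 fold-change assigns the
direction, zero fold-changes are excluded. Query genes absent from the
library universe are dropped and counted; the run aborts if either
direction retains fewer than `min_overlap` (default 5) genes, since a
near-empty direction makes the bidirectional score meaningless.

The running-sum enrichment score of a k-subset against an N-ranking walks
positions 1..N adding `1/k` on hits and `−1/(N−k)` on misses and returns
the extreme deviation; on ties in |value| the earliest position wins, a
convention fixed so the statistic is single-valued and exactly testable
against a brute-force prefix walk. Steps are unweighted — the library
stores pure rankings, so fold-change weighting has nothing to act on.

The connectivity score is `(ES_up − ES_down)/2 ∈ [−1, 1]`: +1 when the
compound's PRL puts all up-genes at the head and all down-genes at the
tail, −1 for the exact opposite. When both ES share a strict sign the score
is set to 0 (both directions piling on the same end is evidence of
something other than mimicry); a flag disables this nulling for users who
prefer the raw signed average. Scores are not normalized library-wide:
normalization cannot change the ranking and raw scores are easier to
verify. Ranking is descending by score with lexicographic tie-break.

## Chemogenomic enrichment

Feature membership is intersected with the ranked library first; the
member count m used for the null is the post-intersection size, so the null
reflects the universe actually ranked. The permutation null randomizes
*feature membership* — B uniformly drawn m-subsets of the library — not the
compound ranking, matching the design of drawing randomized drug-target
sets of equivalent size. The two-tailed p is one-tailed on |ES| with
add-one smoothing, `p = (1 + #{|ES_null| ≥ |ES_obs|}) / (B + 1)`: for a
sign-symmetric null this is the two-tailed probability, it can never be 0,
and its floor `1/(B+1)` is a testable contract. B defaults to 10,000 and
must be at least 100 for any reported p.

Null draws are cached per m and generated from a seed-derived substream
keyed on m (`SeedSequence(seed, spawn_key=(m,))`). Features of equal size
share one null sample — an order-of-magnitude saving with size-matched
decoys — and results are independent of the order in which features are
processed. BH adjustment is applied within each feature category by
default (targets, off-targets and side effects come from different sources
with different set-size distributions); a `global` scope pools everything.

## Synthetic data generator

The generator emulates the statistical shape of a merged perturbation
library: per compound a latent prototype permutation; per replicate the
prototype perturbed by `round(noise · N)` random transpositions; a planted
subset of compounds whose prototypes place the query's up genes uniformly
within the top `⌈placement_fraction · N⌉` positions and down genes within
the bottom window; one planted target feature equal to the planted set,
among decoy features drawn at the same size (size-confound control; a null
library with no planted feature draws decoy sizes uniformly from
[5, min(30, n_compounds/2)] so calibration covers mixed sizes).

Defaults — 1,000 genes, 200 compounds, 5 replicates, 20 planted, 50+50
query genes, 5% placement window, 5% transposition noise, 100 decoys per
category — are chosen so the planted window exactly matches the query
sizes (planted compounds hit score +1 at zero noise) and the library is
large enough for stable nulls while a full pipeline run stays in seconds.
The transposition model is deliberately simple: it spans identity to
near-uniform with one dial and makes within-compound discordance
monotone in `noise`, which the tests exploit. It is *not* a model of real
replicate variation — no dose/cell-line structure, no correlated gene
modules, no heavy-tailed effect sizes — so passing recovery tests shows the
machinery is correct, not that real libraries are this easy. Likewise the
uniform background prototypes make unplanted compounds exactly null,
whereas real compound classes share targets and profiles.

## Numerical and degenerate-input conventions

- ES ties on |value| resolve to the earliest position; equal-magnitude
  floats compare exactly because both the implementation and the test
  oracle accumulate the same sequential sums.
- Empty or full hit sets are errors (the statistic is undefined), as are
  non-bijective rank vectors, duplicate ids, overlapping query directions,
  and features covering the whole library; unusable features are skipped
  with a logged reason rather than aborting a whole enrichment run.
- Output floats are printed with 6 significant digits, and every stage
  writes to a temp file with an atomic rename, making byte-identity of
  repeat runs a meaningful (and tested) property. Provenance sidecars
  record config, seed and input SHA-256 hashes with paths relative to the
  output directory, so identical runs in different directories produce
  identical trees.
- One top-level seed governs a run; the simulator and the enrichment null
  draw from disjoint substreams, so re-running enrichment alone with a new
  seed changes p-values but never ES.

## Validation problem sizes

The statistical checks run at sizes chosen to finish in seconds while
keeping the relevant asymptotics honest: the ES oracle comparison uses
1,000 random instances at N ≤ 50 (exact equality); the sampled-vs-exact
permutation comparison uses libraries of 8–12 compounds where exhaustive
subset enumeration is feasible, with B = 10,000; null calibration uses 100
compounds, 500 genes and 500 decoy features at B = 2,000; planted recovery
runs the full default bundle at B = 10,000; PRL recovery sweeps noise over
{0, 0.05, 0.2, 0.5} on 20 compounds.

## Known limitations

- The greedy closest-pair merge is one member of the prototype-ranked-list
  family; other aggregation orders (or Kemeny-optimal aggregation) can give
  different PRLs for highly discordant replicates.
- The permutation null treats compounds as exchangeable; it does not
  preserve per-compound annotation multiplicity, so heavily annotated
  compounds are not specially controlled for.
- p-values are resolution-limited at 1/(B+1); with within-category BH this
  bounds attainable significance for small categories.
- No batch/query multiplexing: one query signature per run.
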
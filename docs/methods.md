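# Methods

## The model

The unit of analysis is the *block*: a maximal run of alignment columns
whose joint word distribution carries the same grouping information as a
single seed column. The motivating premise is that coevolution is rarely a
property of isolated residues — substitutions tend to involve short
fragments, and the fragment's words (one per sequence, gaps included) are
the natural alphabet for asking whether two regions of a protein changed
together across the family.

Because the method counts word co-occurrences rather than estimating
distributional parameters, it needs neither sequence divergence nor large
families. Its only stochastic assumption is embodied in the *exception*
mechanism: a word seen once in the family is unverifiable signal, so the
sequence carrying it is set aside for that block (at most `D` such
sequences per block; two occurrences is the smallest evidence of
persistence). This is what lets the analysis run on families of six
sequences, or on families at 85–90 % identity where only gap placement
varies.

### Blocks

For a column, the dimension `d` counts symbols occurring exactly once (gap
= 21st symbol). Extension of a hit admits an adjacent column iff

1. the adjacent column's own exception count is ≤ `d`,
2. its exceptions lie within the hit's exception rows, and
3. over the non-exception rows, the word partition of the extended run
   still equals the hit column's residue partition (rows sharing a word
   share the hit residue, and vice versa).

Since each condition is local and the set of valid runs through the hit is
closed under union, the maximal extension is unique; the greedy
left/right order is immaterial (property-tested). Columns that are ≥ 40 %
gapped — the fraction computed over rows carrying repeated words — are
removed afterwards; each maximal surviving run is kept only if it still has
exactly the hit's exceptions in the same rows and the same word partition
(a run that merges word groups is discarded). Thresholds are strict as
stated: a block column needs gap fraction < 0.40; positions-mode scoring
drops columns with ≥ 0.60 gaps. Blocks from different hits that coincide
are merged; overlapping blocks are a feature, not an error.

A deliberate consequence, exercised in the tests: adding one sequence to
the family moves a block's exception count by at most one (+1 exactly when
the newcomer carries a new word, −1 when it duplicates a previously unique
one), but it can relocate block boundaries when it tips a column over the
40 % gap threshold or unlocks a longer extension. The stability law is
therefore asserted on the word table of the fixed interval, plus a
membership check for re-detected intervals.

### Scores

The comparison score of `b2` given `b1` over `N` retained sequences is

    S(b2|b1) = Σ_i (n_i/N) · (1/m_i) · Σ_j (n_ij/n_i)

(notation as in the README). The three factors weight each conditioning
word by its frequency, penalize promiscuous pairing (`1/m_i`), and account
for how the word's sequences distribute over partners. `S ∈ (0, 1]`,
`S = 1` iff pairing is bijective, and `S` is asymmetric — a fully conserved
block scores 1 *given* any block but not conversely.

The correlated-distribution score threads `S` through the sequence tree:

    C(leaf) = 1
    C(T) = ( S(T) + (n1·C(T1) + n2·C(T2)) / (n1+n2) ) / 2

with `S(T)` recomputed on `T`'s leaves and subtrees weighted by leaf
count. The recursion makes the score sensitive to *where* an imperfection
sits: a mismatching sequence under a two-leaf cherry costs less than the
same mismatch breaking a large clade, because the latter pushes `S < 1`
into every ancestor evaluation. Both scores are exercised against an
independent oracle that enumerates all subtrees explicitly.

Per pair, the retained rows are those that are exceptions of neither
block; the tree is pruned to them (unary nodes collapsed) before the
recursion. Pairs retaining fewer than two rows are reported as missing
(`NA`) and never enter clustering. Blocks found at different exception
counts are scored against each other like any others.

### Clustering and topology

A cluster is a set of blocks with near-maximal mutual scores *and* matching
score profiles against every other block. With `R` the range of the finite
symmetrized (max-of-both-directions) entries, blocks `i, j` are cohesive
iff `sym(i,j) ≥ max − Δ·R` and `max_k |sym(i,k) − sym(j,k)| ≤ Δ·R`;
clusters are connected components of the cohesion graph, singletons
dropped. This is a documented approximation in the spirit of
environment-based clustering of score matrices; it is deliberately
range-normalized, hence invariant under affine rescaling of the matrix, and
decreasing Δ can only refine clusters. Default `Δ = 0.1`. A block left
unclustered but carrying several hits contributes those hits as one extra
cluster (all hits of a block behave identically against other blocks, by
construction).

Cluster intervals (smallest to largest member position) form an interval
graph — endpoints inclusive, touching counts as overlap — whose connected
components are the *partitions*, candidate independently-evolving regions.
On a structure, a cluster's blocks are connected by an edge when any atom
pair (all atoms by default; heavy-only optional) sits strictly below the
4 Å cutoff; the contact network and its connectivity are reported, and a
copy of the PDB is written with cluster ids in the B-factor column for
viewer coloring. Only the first model of multi-model files is used.

### Small-family block probability

For a block whose `w` repeated words occur `k_1 ≥ … ≥ k_w ≥ 2` times over
`n` sequences, the chance that a uniform assignment of the `w` words to the
`n' = Σk_i` non-exception sequences reproduces the vector is
`multinomial(n'; k_1..k_w) / w^n'` — e.g. 90/729 ≈ 0.123 for three
double-occurrence words over six sequences. Rows beyond `n'` are exception
rows and are excluded from the event, which is the reading consistent with
an exhaustive-enumeration oracle over word assignments; the function is
validated against that oracle and against Monte-Carlo estimates.

### Evaluation statistics

Sensitivity, specificity, accuracy and positive predictive value are
computed from exact integer confusion counts, with zero denominators
reported as undefined rather than raised. Table-parity rounding is
half-up to two decimals (0.9956 prints as 1). The enrichment probability
is the exact upper hypergeometric tail P(X ≥ TP) for drawing the predicted
set out of `L` positions containing `E` validated ones, evaluated in exact
integer arithmetic because benchmark values reach 1e−17. One benchmark
family's probability is printed inconsistently in its two sources
(0.0009 vs 9.89e−3); the exact tail is 9.891e−4, which matches the former
and exposes a shifted exponent in the latter — the test suite records both
fixtures and the adjudication. System comparison follows the 3-of-4 rule:
better on at least three measures wins; a 2–2 split is decided by the sign
of the summed differences; everything within `tol = 0.05` is comparable.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `max_exceptions` (D) | 2 | deepest hit/block dimension searched; conserved families need 0–1, divergent ones more |
| `delta` | 0.1 | Δ-cohesion tolerance as a fraction of the matrix range |
| block gap threshold | 0.40 (strict <) | maximal gap fraction of a block column |
| hit gap threshold | 0.60 (≥ drops) | positions-mode gap filter |
| contact cutoff | 4.0 Å (strict <) | atomic contact distance |
| motif distance `t` | 2 columns | reach of motif extension / new-motif grouping |
| comparison `tol` | 0.05 | comparability band of the 3-of-4 rule |

## The synthetic generator

`SynthSpec` defaults describe the study conditions used throughout the
tests: 40 sequences, 120 columns, target identity 0.8, three planted
fragment pairs (widths 3–4), one injected exception sequence and one 50 %
gapped region. Each planted pair picks a clade of a random rooted binary
tree (distinct bipartitions across pairs) and assigns one word to the clade
and another to its complement in both intervals, so the pair is perfectly
correlated by construction; optional noise flips move single rows to the
opposite word. Planted intervals are flanked by barrier columns carrying
three singletons, so blocks at `d ≤ 2` can neither seed there nor extend
across. Background columns are skewed two-residue splits on random row
subsets; the two adjacent minority sizes are mixed in the proportion that
makes the expected column identity hit the target after accounting for the
planted, barrier and gapped columns (measured API lands within ±0.01 of
the target at the default size, comfortably inside the ±0.05 design
tolerance). Background subsets that would duplicate a planted clade
exactly are redrawn, keeping background variation uncorrelated with the
planted signal.

What the generator does *not* emulate: substitution-model evolution,
rate heterogeneity, realistic gap patterns, or alignment error. Passing the
planted-recovery study therefore demonstrates the combinatorics and the
ranking behavior of the scores, not performance on real families. Two
background columns can, rarely, draw the same random subset and form a
genuinely coevolving pair; recovery precision is reported with ties broken
against the planted pairs, so it is a lower bound.

## Numerical and design choices

- Gap canonicalization: `.` and `-` both accepted, stored as `-`; a
  gap–gap pair counts as identical in the percentage of identity (the gap
  is a residue throughout).
- Information content per column: `−Σ f ln f / ln 21` with the gap as 21st
  symbol — 0 at full conservation, 1 for a uniform 21-symbol column.
- Guide tree: UPGMA on 1 − fraction-identical-columns, joins tie-broken by
  lexicographically smallest member id, so the tree is independent of row
  order. Unrooted Newick input is midpoint-rooted (unit branch lengths
  assumed where missing); multifurcations are resolved into a caterpillar
  ordered by descending subtree size then smallest leaf id, since the score
  recursion is defined on two immediate subtrees.
- Coordinates are 1-based inclusive in every report and 0-based half-open
  internally.
- The score matrix computes both directions of a pair in one bottom-up pass
  over the pruned tree, carrying the joint word-count table upward; pruned
  trees are cached per retained-row set.
- Symmetrization for clustering takes the maximum of the two directed
  scores; both directed and symmetrized matrices are written.
- The clustering profile comparison includes the mutual and diagonal
  entries; missing entries are skipped and never create cohesion.
- `C(leaf) = 1` is forced by self-consistency: a perfectly paired tree must
  score 1 under the recursion.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on generated data:
oracle cross-checks use 200 random instances each (trees ≤ 8 leaves;
alignments ≤ 8×10), stability laws 100 random alignments, the recovery
study 20 seeds of the default 41×120 spec, and Monte-Carlo checks 10⁶
draws. A full suite run takes well under a minute on one core.

## Known limitations

- The Δ-cohesion clustering is a faithful implementation of the *described*
  cluster properties, not a re-implementation of any external clustering
  program; on borderline matrices the two can group differently.
- Conserved blocks score `C = 1` given any block (their single word pairs
  trivially), so the symmetrized matrix saturates on families with many
  fully conserved blocks; there the profile condition of the clustering,
  driven by gap placement, does the discriminating work.
- `map_to_structure` matches the reference row to a chain positionally
  (with a mismatch budget); it does not align sequence to structure and
  will refuse chains with unmodelled interior residues unless the tolerance
  is raised.
- Positions-mode analysis shares all machinery with blocks mode but cannot
  recover fragment-level signal by construction; it exists for comparison.
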
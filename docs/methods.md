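# Methods

This note documents the model implemented by `essalign`, the choices
made where the design was genuinely open, what the synthetic data do and
do not emulate, and the numerical conventions.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## From KGML to enzymatic step sequences

A KGML pathway is parsed into a directed multigraph: one node per
(entry, EC code) for entries of type `enzyme`/`gene`/`ortholog` carrying
EC annotations (entries without any EC annotation are dropped with a
logged warning), and an edge `u → v` labelled with compound `c` whenever
`c` is a product of `u` and a substrate of `v`.  A reversible enzyme
offers both of its compound sets on either side of this rule, and every
edge incident to a reversible enzyme is additionally walkable backwards
(its reverse is included).  EC codes are truncated to three levels; an
unresolved level (`5.x.x`) is kept as a sentinel token that equals only
itself.  Entries listing several EC numbers yield one node per code
sharing the entry's compounds, since the method compares catalytic
activities, not genes.  `ECrel` relations serve as a fallback edge
source only when a document carries no reaction data at all.  Currency
metabolites are not filtered; nothing in the edge rule treats any
compound specially.

*Initialization nodes* are enzymes that represent a pathway's metabolic
input: (i) no substrate of the node is produced by another enzyme of the
same map, or (ii) at least one substrate is annotated (via `maplink`
relations) as arriving from another map and the node has at most two
neighbors in the undirected sense.  Each initialization node roots a
BFS tree over directed edges — children are enqueued in ascending
node-id order so trees are deterministic — and each root-to-leaf branch
becomes one enzymatic step sequence (ESS) of EC codes.  Exact duplicates
(same map, root and step string) are collapsed; sequences of length 1
are kept by default (`min_length` is configurable).  Per-map statistics
report sample (n−1) standard deviations, with SD = 0 for a single
sequence.

## The alignment objective

For an alignment `M` with `S` rows and columns `m_j` (all-gap columns
are removed before any evaluation):

* per-level entropy `E(m_jk) = −Σ p log2 p`, normalized by `log2 S`, the
  maximum achievable with `S` rows (a `distinct`-symbols normalization is
  available in `ScoringConfig`); a gap contributes one gap symbol at
  every level;
* column entropy `E(m_j) = (15·E1 + 10·E2 + 5·E3)/30` — most weight on
  the EC class;
* `Gaps(m_j) = #gaps/(S−1)`, compensating the false homogeneity of
  gap-heavy columns;
* column homogeneity `H(m_j) = 0.6·E(m_j) + 0.4·Gaps(m_j)`; alignment
  homogeneity is the mean over columns;
* gap concentration `GC = S̄GB/GP` (mean internal gap-block length over
  total internal gaps, per row; leading and trailing runs excluded; 0
  with no internal gaps);
* column increment `CI = C0/C1` (longest unaligned sequence over aligned
  width);
* objective `O.F. = 0.9·Homogeneity + 0.05·GC + 0.05·CI`, minimized.

Two printed formulas conflict with their surrounding prose: minimizing
`S̄GB/GP` numerically favors scattered single gaps although the text
describes rewarding concentrated blocks, and minimizing `C0/C1` rewards
adding columns although the text describes penalizing them.  The
package implements the formulas literally and exposes
`gap_concentration_mode`/`column_increment_mode = literal | inverted`
(`inverted` = `GP/S̄GB` and `C1/C0`) so either reading is available;
`literal` is the default everywhere.  With the 0.9/0.05/0.05 weights the
choice is rarely decisive: the identity optimum is 0.05 and a fully
distinct gap-free pair scores 0.59 under both.

## Genetic algorithm

Chromosomes are per-row binary gap masks (1 = enzyme, 0 = gap) over
rectangular variable-width alignments; decoding a mask against its
sequence reproduces the row, so EC content is conserved by construction.
Defaults follow the published configuration: population 100, crossover
rate 0.9, stop after 20 generations without elite improvement, best of
10 replicates (replicate `r` is seeded with `seed + r`).  Choices the
source description leaves open:

* **Mutation policy.**  The description states both a "1% mutation rate"
  and that an individual is mutated each generation.  Default
  (`per_individual`): every offspring receives exactly one mutation
  event per generation (`individual_mutation_prob = 1.0`); the
  alternative (`per_position`) applies the 1% rate independently per
  cell.  One mutation event picks a uniform (row, position): a gap is
  extended or deleted with equal probability, an enzyme gets a gap
  opened before it; rows are re-padded and all-gap columns stripped.
* **Crossover.**  One-point: the second parent is cut, per row, after
  consuming the same number of enzymes as the first parent holds left of
  the cut column; shorter right sides are padded with gaps on their left
  edge and shorter left sides on their right edge, so offspring stay
  rectangular and decode invariantly.
* **Elitism** (best individual copied unchanged) is added although
  unstated — the stagnation stop is otherwise ill-defined; tournament
  size defaults to 2.
* **Canonical pair order.**  Pairs are sorted by sequence id before
  seeding, so the objective is symmetric in argument order.
* For two-row alignments with default scoring the GA provably cannot go
  below 0.05, so a run that reaches it stops early.  An inlined two-row
  scorer (tested to 1e-12 against the reference implementation)
  accelerates pair fitness.

Two reference aligners validate the GA.  `brute_force_align` enumerates
every gap placement up to `len(A)+len(B)` columns (vectorized; capped at
length 6 per sequence; ties broken by fewest columns, then lexicographic
placement).  `dp_align` is a Needleman–Wunsch minimizer whose
substitution cost is `0.6 ·` two-row column entropy and whose gap-column
cost is 1.0 — the two global terms (GC, CI) cannot enter a column-local
recursion — after which the traced alignment is re-scored with the full
objective.  By construction the DP result can never beat the exhaustive
optimum; empirically (recomputed by the acceptance script) it ranks
pairs almost identically to the GA.

## Similarity, significance, clustering, MSA

The all-against-all matrix stores, symmetrically with a zero diagonal,
the best GA objective per unordered pair; each pair's sub-seed derives
from the base seed and the pair ids (CRC32), so the matrix is
reproducible and order-independent, and an optional on-disk cache makes
long runs resumable.

Significance: shuffled collections pool all EC tokens, permute them, and
refill the original lengths in order — conserving the global composition
and the length vector exactly.  The score threshold is `x̄ − 3σ` (sample
SD) of the real score distribution; fractions below the threshold use
strict inequality.

Clustering is PAM-style k-medoids on the precomputed matrix (random
medoid initialization, alternating assignment/update, best of 20
replicates; cluster quality = total dissimilarity to medoids, the
canonical k-medoids objective — the source names no quality function).
k is selected where the discrete second difference
`Q(k−1) − 2Q(k) + Q(k+1)` is maximal; ties return the smallest k with a
degeneracy flag, and the full curve plus candidate peaks are returned
for inspection.  Depuration removes members whose mean fitness with the
rest of their cluster exceeds the cutoff (0.4), computed in a single
pass against the original membership — which makes the operation
idempotent; a `cascade` option re-evaluates among survivors to a
fixpoint.

Progressive MSA orders members most-similar-pair-first, then repeatedly
adds the unplaced member with minimal mean fitness to the placed set
(ties by id).  Extension freezes the relative gap pattern of aligned
rows: the extension GA may only insert whole-block gap columns or place
gaps in the incoming row.  The trivially padded stack is always injected
into the initial population, so the result is never worse than stacking.

## Synthetic data: what it emulates, and what it does not

`generate_maps` builds random reaction trees (each node consumes the
compound on the edge from its parent, so the graph is exactly the tree
plus reversibility back-edges), plants a shared motif as a contiguous
chain, marks random substrates as external, and serializes minimal valid
KGML — the root always consumes an unproduced compound, guaranteeing an
initialization node.  `generate_ess_blocks` plants a partition: each
cluster's template is drawn from its own slice of the alphabet and
members substitute `round(divergence·length)` positions, half of the
substitutions changing only the third EC level (exercising the 15/10/5
weights).

Alphabet geometry matters more than one might expect, because the
entropy objective grants partial credit for agreement at single EC
levels:

* Block alphabets (`block_alphabet`) use realistic wide level spreads —
  each template family has a unique EC class and random sub-levels —
  because compact alphabets let unrelated sequences collect partial
  credit at the heavily weighted first levels.
* Injected outliers (`random_ess_collection(avoid=...)`) are rejection-
  sampled until their DP-baseline objective against every planted
  sequence exceeds 0.5: a purely random draw can by chance share EC
  classes with a template at several positions, which the objective
  legitimately scores as borderline-similar, and an "outlier" with
  ambiguous ground truth cannot anchor a planted-structure experiment.
* The significance fixture is a separate regime: 20 sequences over a
  diverse random vocabulary (`diverse_alphabet`) in which 10 pairs are
  planted near-copies, emulating a genome-scale inventory where a few
  percent of real pairs — and almost no composition-preserving shuffles
  — score below the 0.4 cutoff.  A fixture dominated by near-identical
  copies shows the *opposite* separation, because shuffling then
  produces sequences sharing most of their composition.

None of the generators attempt biologically realistic network topology,
degree distributions, or EC-class frequencies; passing tests demonstrate
that the machinery recovers planted structure under the stated noise, not
that real pathway inventories will cluster equally cleanly.

## Experiment and test sizes

Validation experiments (`essalign/validation.py`) use scaled-down GA
settings chosen so the full battery runs in minutes on one CPU —
population 20 / 2 replicates / stagnation 8 for the oracle sweep, and
population 16 / 1 replicate / stagnation 6 for matrix-scale experiments
— while `GAParams` defaults remain the published 100/10/20.  Problem
sizes: the oracle sweep is exhaustive over all 7 140 unordered pairs of
sequences up to length 4 on a three-code alphabet plus 200 random pairs;
operator fuzzing runs 10 000 cases; planted-cluster recovery and
significance each run 20 independent seeds (18–21 and 20 sequences per
seed); the DP/GA rank correlation uses 100 pairs.

## Known limitations

* The GA objective is evaluated exactly but searched heuristically; the
  oracle-equivalence guarantee is empirical and limited to short
  sequences.
* `brute_force_align` is exponential and capped at length 6.
* The DP baseline optimizes only the homogeneity term; its re-scored
  objective is an upper bound on the optimum, not an optimum.
* k-medoids quality is non-convex in k on small noisy matrices; the
  elbow rule can be degenerate on flat curves (flagged, smallest k
  returned).
* KGML support targets the entry/reaction/relation subset the method
  needs (v0.71-era documents and the package's own serializer); graphics
  and gene-level detail are ignored.
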
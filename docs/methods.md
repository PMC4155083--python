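# Methods

## Model and pipeline

`synblock` compares two genomes given as ordered lists of oriented genes
plus a family assignment (either a precomputed table or a reconciled gene
forest pruned at the last common ancestor).  The pipeline per chromosome
pair is: filter → rewrite in tandem blocks → build the sparse matrix of
homology packs (MHP) → extract strict consistent diagonals → merge them up
to `gap_max` → validate each diagonal with a p-value.  Chromosome pairs are
independent comparisons; genes on different chromosomes cannot be in
synteny, so nothing is lost by pairwise chromosome search.

### Families from gene trees

A reconciled gene tree (binary, NHX `S=`/`D=` annotations, TreeBest
conventions: a missing `D` tag means speciation) is cut at the maximal
nodes whose species label equals the chosen ancestor (the LCA of the two
species by default).  A duplication node *at* that ancestor represents a
duplication inside the ancestral genome, so each of its children roots a
separate family; chained ancestral duplications keep splitting.  Leaves
whose root path never crosses an ancestral node are lineage-specific
births and receive no family.  Pruning at an earlier ancestor (optional
`ancestor` argument) folds the duplications between that ancestor and the
LCA into single families, which adds paralogy relations.  Ancestral gene
names are deterministic (`fam<tree>.<rootPath>`) because reference
ancestral-gene identifiers are dataset-specific and not reproducible from
the forest alone.

### Filters

`InCommonAncestor` (default) keeps genes that descend from an ancestral
gene, so lineage-specific births are removed but genes whose ortholog was
deleted in the other species are retained — deletions then break synteny,
which is the right semantics for ancestral gene-order work.
`InBothSpecies` keeps only genes whose family is present in both genomes
(anchor genes).  `None` keeps everything; family-less genes then become
singleton pseudo-families that match nothing and act as gaps.

### Tandem blocks and the MHP

Only strictly adjacent same-family genes collapse into one tandem block
(tandem gap 0); a family recurring at non-adjacent positions yields
distinct tbs (dispersed paralogs), i.e. several hps in one row or column.
A tb keeps its genes' shared orientation, or `unknown` when they disagree.
The MHP cell for homologous tbs carries the orientation product
(+1/−1/unknown).  Storage is a coordinate-keyed dict, proportional to the
number of hps.

### Diagonal extraction and merging

Strict diagonals are consumed greedily scanning x ascending, then y
ascending.  The diagonal type comes from the first hp's sign, else from
the position of the strict neighbour ((+1,+1) → slash, (+1,−1) →
backslash), else the 1-hp diagonal stays `undetermined` and can adopt the
type of whatever it later merges with (never merged, it is reported as an
undetermined 1-hp block, which the p-value filter removes in practice).

Merging proceeds distance by distance, d = 2 … `gap_max`+1 (distance =
gap + 1).  The distance between two diagonals is the minimum, over
directionally compatible extremity pairs (strictly monotone in both
coordinates under the common type), of the metric distance between the
extremities.  A fusion at distance d is performed only if every hp sign is
consistent with the resulting type and the merged chain is strictly
monotone in both coordinates; equal-x or equal-y extremity alignments
never pair (micro-rearrangements inside a gap can therefore only arise
through multi-step merges).  When several fusions tie at the same
distance the one maximising the resulting hp count wins, then the
leftmost (smallest x, then smallest y) — the greedy order is confluent
except when fusions are mutually exclusive, and the tie-break makes the
output deterministic.  Greedy merging can return non-maximum blocks; no
global optimisation is attempted.

Metrics on cell offsets (Δx, Δy ≥ 0): CD = max, MD = Δx+Δy,
ED = round(√(Δx²+Δy²)) (nearest integer — the only rounding consistent
with ED = CD = 3 at offset (3,1); floor would also give 3 there, nearest
is used throughout), DPD = 2·max − min.  DPD favours merges along ±45°,
MD favours lateral merges (tolerating indels and annotation errors over
micro-inversions); MD is the default, CD gives the most
method-independent block definition (a block under CD is exactly a
max-gap cluster with order and orientation constraints).

Ancestral gene order within a block is read along chromosome A; the
ancestral orientation of an hp is o(tb_a) when known, otherwise o(tb_b)
for a slash diagonal and −o(tb_b) for a backslash, otherwise unknown.

### Statistical validation

For a diagonal of m hps in an l_a×l_b window with maximum Chebyshev gap
g, in a comparison of n_a × n_b tbs with n_ab hps:

* p_d(k): binomial density — each hp lies in the window independently
  with probability (l_a·l_b)/(n_a·n_b).  This is the standard
  no-dispersed-paralogy approximation (each family once per chromosome;
  at real densities ~2–3% of tbs are dispersed duplicates, which biases
  p-values slightly downward — a known, accepted approximation).
* p_g2d(k, g) = p_chain(k, g, l_a) · p_chain(k, g, l_b): for monotone
  chains the Chebyshev gap condition holds iff both axis projections are
  1D max-gap chains.  p_chain is exact: the number of k-subsets of
  {1..l} with consecutive differences ≤ g+1 (dynamic programming with a
  sliding window, integer arithmetic, edge effects included by
  construction) over C(l, k).
* p_oo(k) = min(1, (1/k!)·[(P₊+P?)ᵏ + (P₋+P?)ᵏ]): a common order on both
  chromosomes has probability 1/k!, and all signs must be consistent
  with the direction; p_oo(1) = 1.  Sign probabilities are the empirical
  hp sign frequencies pooled over the whole genome comparison — stabler
  than per-pair frequencies for sparse chromosome pairs.
* p_w(m, g, l_a, l_b) = Σ_{k=m}^{min(n_ab, l_a, l_b)} p_d·p_g2d·p_oo —
  the probability that the window holds a consistent diagonal at least
  as extreme.  Summing the "exactly k present and all k chain" terms
  under-counts configurations where only a subset chains; this is a
  deliberate conservative reading, accurate in the sparse regime where
  the k = m term dominates (verified against a placement Monte-Carlo
  under the model's null — distinct rows × distinct columns, random
  bijection, iid signs — agreeing within a factor ≲ 3 on small
  configurations).
* pVal = 1 − (1 − p_w)^Nw with Nw = ⌊n_a/l_a⌋·⌊n_b/l_b⌋ non-overlapping
  window placements, computed as −expm1(Nw·log1p(−p_w)) for precision.

Gaps inside the p-value are always Chebyshev, independent of the merge
metric.  A diagonal is a synteny block when pVal ≤ α (inclusive; default
α = 10⁻³, per-chromosome-pair, no genome-wide multiplicity correction —
a documented limitation).  2-hp blocks are eligible.  Numerical choice:
series terms with p_d·p_oo < 10⁻³⁰ are skipped; the 1/k! decay bounds
the neglected tail below 10⁻²⁸.

### Recommended gap_max

The recommendation is the largest g ∈ 0..20 such that a minimal
significant configuration — a 2-hp diagonal with gap g in its tightest
(2+g)×(2+g) window — still has pVal ≤ α in a genome-representative
context: length-weighted mean chromosome sizes (a random hp falls on a
chromosome with probability proportional to its length), genome-wide
mean hp density, pooled sign frequencies.  Beyond g = 20 the block
definition loses meaning at mammalian densities, hence the cap.

## Simulator

The simulator draws an ancestral genome (n_genes composed into
n_chromosomes parts, uniform cut points, each part ≥ 1 gene; uniform
random orientations) and evolves it independently along two branches.
Each branch applies its configured event counts in a uniformly shuffled
order at uniformly random positions: de novo births (no family),
deletions, tandem duplications (copy inserted adjacently, inverted with
probability `p_tandem_inverted`), dispersed duplications (copy at a
uniform position, random orientation), segmental inversions (segment
reversed and orientation-flipped), reciprocal translocations (two
chromosomes exchange terminal segments), fusions and fissions.  Segment
and tail lengths are geometric — the minimal memoryless choice — with
configurable means.

Defaults are human–mouse-like magnitudes chosen once: 20,000 ancestral
genes, 20 chromosomes, and per branch 400 births, 700 deletions, 800
tandem duplications, 100 dispersed duplications, 250 inversions (mean
length 5 genes — micro-inversions dominate between closely related
mammals), 25 translocations (mean tail 20), 3 fusions, 4 fissions.
These orders of magnitude reflect the known extent of human–mouse
rearrangement since their common ancestor; they are package defaults,
not a fit to any particular dataset.

The ground truth is the list of oriented ancestral adjacencies between
*consecutive conserved* ancestral genes (genes with at least one
descendant in each extant genome) on each ancestral chromosome,
canonicalised so that reading an adjacency from either strand compares
equal.  Restricting to conserved genes is deliberate: a gene deleted in
one lineage leaves its neighbours ancestrally "adjacent up to loss", and
an inference spanning that loss is correct for ancestral-order purposes.

Benchmark metrics follow the conventions stated in the README; note the
sensitivity denominator counts conserved ancestral *genes* while the
numerator counts adjacencies, so even perfect recovery scores (N−k)/N
for k chromosomes of N total genes — the definition is kept as stated
rather than silently repaired.  N50 is the smallest block length L such
that blocks of length ≥ L contain at least half of the ancestral genes
contained in blocks.

### What the simulator does and does not emulate

It reproduces the event spectrum that shapes gene order at this
evolutionary distance, with uniform event placement and geometric
lengths.  It does not model rate heterogeneity along chromosomes,
hotspots, WGD, gene conversion between duplicates, or annotation error
beyond what births/deletions mimic.  Passing tests on simulated data
therefore demonstrate correctness of the detection machinery under the
stated null and event model, not performance guarantees on any
particular real genome pair.

## Problem sizes used in the test suite

Unit tests run on toy inputs (≤ 40 genes).  The end-to-end quality band
uses 20 replicates of the full default configuration (20,000 genes); one
replicate simulates and detects in ~2.5 s.  The probability kernels are
checked against exhaustive enumeration up to l = 12 and against 10⁶-draw
Monte-Carlo placements on matrices up to 7×7.

## Known limitations

* The density model ignores dispersed paralogy (p-values slightly
  anti-conservative; small for closely related species).
* α is applied per chromosome pair without genome-wide FDR control.
* Greedy merging may return non-maximum blocks.
* Only pairwise comparisons — no multi-genome profiles, no
  highly-diverged ("twilight zone") block recovery, no WGD handling.
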
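# Methods

## Signal model

A structural variant leaves up to three footprints in a paired-end
short-read alignment: clipped reads whose unaligned tail abuts a
breakpoint, split reads whose supplementary alignment spans a junction,
and read-pairs whose template length or mutual orientation violates the
library expectation.  `svgraph.signals` converts each record into typed
signals:

* **CLIP_LEFT / CLIP_RIGHT** — a soft or hard clip of at least
  `min_clip_fraction` (default 0.10) of the full read length, anchored
  on the boundary of the aligned portion on the clipped side.  Hard
  clips count toward the fraction, so the rule is invariant to how the
  aligner stores the clipped bases.
* **SPLIT** — the same boundary on a record with a split companion
  (supplementary flag or `SA` tag) and mapping quality ≥
  `min_split_mapq` (default 20; the threshold is configurable because
  "high mapping quality" is a judgment call).  A split record whose
  quality falls below the threshold still contributes a plain clip.
* **ARP_*** — one signal per read end of an intrachromosomal discordant
  pair.  Orientation anomalies take precedence: FF and RR pairs mark
  inversions, an RF (everted) pair marks a tandem duplication.  Normally
  oriented pairs are insert-discordant when |TLEN| falls outside
  μ ± k·σ with k = `insert_sd_mult` (default 3, configurable); large
  inserts imply deletion, small inserts imply insertion.  The signal
  position is the breakpoint-proximal read edge (end of the leftmost
  read, start of the rightmost), which keeps clusters tight around the
  junction.

Interchromosomal pairs are dropped: the target events are local
rearrangements, and translocation handling would need a different edge
model.  Duplicate and QC-fail records are skipped; supplementary records
contribute split signals only.

The insert-size profile is estimated from primary proper pairs with the
top and bottom 1% of template lengths trimmed before taking moments, so
a handful of mismapped pairs cannot inflate σ.  The read length is the
modal primary read length.

## Graph construction

Clip/split signals of the same type within `clip_merge_window` (5 bp)
merge into one node by single linkage; a node keeps the supporting read
identifiers, and `weight = |read_ids|`.  Nodes failing `min_weight`
(2) or a `weight / coverage` ratio below `min_weight_ratio` (0.1, with
coverage measured from primary-alignment depth at the node midpoint) are
discarded.

Discordant pairs are clustered per signal type with single linkage at
gap ≤ (mean insert − 2 × read length), floored at
`min_cluster_distance_floor` (50 bp) so degenerate libraries still
cluster: first on left ends, then on right ends within each left
cluster.  Each cluster yields a left node, a right node, and a pairing
record with the shared pair count.  Two controls suppress randomly
occurring discordant alignments: a minimum pair support (2) and the same
support/coverage ratio used for clip nodes, evaluated at the larger of
the two cluster-end coverages so clusters bordering deleted sequence are
not penalized.  With ~0.1% of normal pairs exceeding the 3σ insert
cutoff by chance, unfiltered two-pair clusters otherwise attach to
nearby event subgraphs through reference adjacency and drag call
boundaries outward.

Paired (Epe) edges take their type from the generating signal
(Del/Ins/Dup/Inv, or Split for co-occurring split junctions on one
read); parallel edges of different types between the same node pair are
all retained, since compound events genuinely superimpose connection
types.  Adjacent (Eae) edges connect every pair of consecutive
same-contig nodes with their gap, clamped at zero on overlap.  Node
order — and therefore node numbering — is the canonical
(contig, start, type) sort, making construction deterministic and
permutation-invariant.  Nodes keep one signal type each; clip and split
clusters at the same coordinate stay separate nodes, matching the
*(type, pos, weight)* node definition.

## Pattern growth

Growth extends a subgraph one node at a time in increasing position
order.  Candidates are the immediate reference successor of the frontier
and the paired-edge neighbors of all members beyond the frontier (a
projected index maintained incrementally).  A candidate joins when its
gap to the frontier is below `min_dist`, or when a paired edge connects
it to any member (checked from the newest member backwards).  The
distance constraint applies only to adjacent-edge extensions because
those edges come from the reference, not from the sample; paired-edge
jumps may repeatedly exceed `min_dist`, as the rule conditions only on
edge existence.

`min_dist` defaults to max(2 × mean insert, 1000 bp): adjacent signals
of one event fall within roughly an insert of each other, and the floor
keeps short-insert libraries from fragmenting events.  `min_freq`
(default 1) gates node-type participation; the default keeps rare,
single-instance subgraphs, and a node-level frequency test of
`freq ≥ min_freq` is used so that the default does not paradoxically
exclude every node.  A subgraph's `freq` counts the genomic instances
sharing its node-type sequence.

Every node of every sufficiently frequent type seeds one growth.  Two
exact optimizations keep this near-linear on realistic graphs: only
growth leaves (inextensible subgraphs) are recorded, since every
intermediate is contained in a leaf; and a seed already absorbed by an
earlier growth is skipped, because candidate sets and the acceptance
rule are monotone in subgraph membership, so any subgraph grown from the
skipped seed is contained in a leaf of the earlier growth.  The final
callset keeps leaves that are not node-subsets of another leaf.  A
brute-force oracle that enumerates all growths without these shortcuts
verifies equality on 1000 seeded random graphs in the test suite, and a
10,000-node adjacency-only chain confirms the absence of combinatorial
blowup.  A per-seed step budget (10⁵) guards pathological inputs.

## Calls

A call's boundary spans the leftmost node start to the rightmost node
end of its subgraph.  `CXS = (# distinct node types) × (# Epe edges)`
summarizes complexity — the worked four-type, two-edge example scores 8.
The phrase "identical node types" in the score's definition is read as
*distinct* node types, which the worked example forces.  Edge connection
types label the call (`Del,Inv`, `Dup,Ins`, ...); an adjacent edge
joining two orientation-class nodes of the same type contributes that
type (an inversion's FF/RR flanks), and an edgeless subgraph falls back
to the types its node kinds imply.  Output is VCF 4.2 with a symbolic
`<CSV>` allele (1-based inclusive `END`), a BED sidecar (0-based
half-open) with one event row per call plus one junction row per Epe
edge, and a JSON sidecar with the full subgraph; the original tool's
bespoke text format is replaced by these interoperable ones.  The
rightmost boundary uses the rightmost node's *end* so the interval
covers the whole supporting cluster.

The `filter_csv` operation retains calls with more than one edge
connection type (threshold 2), the selection used for surveying
confident compound events; the discovery pipeline itself defaults to
`min_link_types = 1` because benchmark recall is measured on the full
callset.

## Evaluation

`unique_interval_match` requires both predicted outer breakpoints within
`slop` (500 bp, inclusive) of the benchmark's outermost breakpoints;
`all_breakpoint_match` requires every truth subcomponent matched on both
ends, with predictions reusable across components.  Unique-interval
scoring assigns predictions to truths one-to-one, greedily by smallest
summed breakpoint shift, so one prediction cannot satisfy two events.
For all-breakpoint scoring the caller supplies junction-level intervals
(one per induced Epe edge) alongside event intervals — the paired edges
are precisely the caller's assertions about individual junctions.  A
`recall_only` mode reports correct discoveries without FP counts for
real-data-style comparisons lacking a curated negative set.

## Simulator

The generator emulates the standard benchmark workflow (reference →
implant SVs on two haplotypes → wgsim-style reads → alignment) without
external data or tools.  Defaults are the benchmark operating point: a
2 Mb i.i.d. reference at GC 0.41, 50 events per replicate, 30×
coverage, 2 × 100 bp reads, insert 500 ± 50, 1% substitution errors.
Basic-operation lengths are log-uniform on [100, 1000] bp for the
reported catalog — the scale of experimentally validated compound
events — and [100, 5000] bp in randomized mode; operations within one
composite event are separated by 20–200 bp so the event shares an
anchor locus; dispersed-duplication targets land 800–2500 bp beyond the
source; events are spaced ≥ 10 kb apart.  Heterozygous events modify
one randomly chosen haplotype, homozygous events both.

Truth subcomponents record what a breakpoint-accurate caller should
recover.  For Del, Inv, Tandup and Invdup the novel-adjacency junction
span coincides with the source interval.  A dispersed duplication's
junctions do not: its two new adjacencies are source-start ↔ target and
source-end ↔ target, so those two spans are recorded (plus the
copy–copy junction for the tandem dispersed form); the source interval
alone contains no reference breakpoint pair any read can witness.
DelSpaDel keeps the three-component Del / spacer / Del decomposition,
with the spacer inverted in half of the draws.

**Truth-guided alignment.**  The default aligner places every read
exactly through the known haplotype→reference block map: collinear
pieces ≥ 20 bp become alignment records (longest piece primary, others
supplementary with `SA` tags), shorter pieces and novel-insertion
sequence become soft clips, and mate fields/TLEN/proper-pair flags are
derived from the two primary placements.  This gives breakpoint-exact
signals and makes tests independent of any aligner's heuristics; an
`external_aligner` mode runs `bwa mem` instead and is exercised in the
test suite.  Consequences for interpretation: truth-guided BAMs contain
no mapping ambiguity, no mismapping in repeats, and substitution errors
never produce spurious clips, so recall measured on them is an upper
bound relative to real alignments — the event representation, library
geometry and sampling noise are faithful, the alignment noise is not.
Microhomology at junctions and non-uniform error profiles are not
simulated.

All randomness flows from one seed; equal configurations reproduce
byte-identical outputs.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; 1-based only in VCF.
* Clip/split anchors use the last aligned reference base of the clipped
  side; equal-position nodes are ordered by type name for determinism.
* `discordant_cluster_distance` clamps at a 50 bp floor when
  2 × read length exceeds the mean insert.
* A coverage of zero at a node midpoint disables the ratio filter for
  that node rather than dividing by zero.
* Empty inputs (no signals, empty graph, empty callset) yield empty
  outputs, not errors; a header-only VCF is still valid output.
* Insert-profile estimation refuses to run on fewer than `min_sample`
  proper pairs, naming the shortfall.

## Known limitations

* Interchromosomal and multi-contig events are out of scope.
* No genotyping: zygosity of a call is not estimated.
* Boundaries inherit discordant-cluster granularity; without clip/split
  support at a junction the breakpoint is resolved only to within about
  an insert length.
* The all-breakpoint criterion depends on junction-level intervals from
  paired edges; a junction supported by coverage changes alone (no
  discordant or split evidence) cannot be matched.
* Benchmark numbers from the simulator characterize the method under
  idealized alignment; real-data performance additionally depends on
  the upstream aligner and reference context (repeats, segmental
  duplications) that the generator does not model.
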
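# svgraph

Complex structural variants (CSVs) are genomic rearrangements with more
than two breakpoints — a deletion flanked by an inversion, a dispersed
duplication stacked on a deletion, and similar compound events.  Callers
built around a fixed model of one SV type match only part of a CSV's
signal and fragment it into several misleading simple calls.  `svgraph`
takes the opposite, model-free route for paired-end short reads: it
collects every abnormal-alignment signal, organizes the signals into a
graph that encodes their possible breakpoint connections, and reports
each maximal connected pattern of that graph as a single candidate CSV.

It is aimed at people studying structural variation from WGS BAMs who
want compound events kept intact, and it ships with a self-contained
benchmark simulator and evaluator, so the whole method can be tested
without any external data.

## Method

**Signal graph.**  From a coordinate-sorted BAM, `svgraph` extracts
clipped reads (clip ≥ 10% of the read length), split reads with mapping
quality ≥ 20, and discordant read-pairs (template length outside
μ ± 3σ of the insert-size profile, or an RF / FF / RR orientation).
Signals are clustered into nodes *v = (type, [start, end), weight)*;
clip/split clusters are filtered by weight and by the weight/coverage
ratio, and discordant clusters by pair support and the same ratio.  The
graph *G = (V, E)* has two edge families:

* *Epe* — paired edges between two nodes supported by *rp* read pairs or
  split reads, typed by the implied rearrangement (large insert → Del,
  small insert → Ins, RF → Dup, FF/RR → Inv, split-only → Split);
* *Eae* — adjacent edges between consecutive nodes on the reference,
  attributed with their genomic gap *dist*.

The discordant clustering distance is the estimated mean insert size
minus twice the read length.

**Pattern growth.**  A candidate CSV is a maximal subgraph grown from a
seed node in increasing position order: the immediate successor joins
when its gap is below *minDist* (adjacent-edge extension), and any later
node joins when a paired edge connects it to a member (backtracking).
Every node of every type with frequency ≥ *minFreq* (default 1) seeds a
growth; grown subgraphs that are node-subsets of another are discarded.
Each call reports its boundary (leftmost node start to rightmost node
end), its edge connection types (e.g. `Del,Inv`), and a complexity score

    CXS = (# distinct node types) × (# Epe edges).

**Evaluation.**  Two tiers against a truth set: a *unique-interval*
match places both predicted outer breakpoints within 500 bp of the
benchmark's outermost breakpoints; an *all-breakpoint* match requires
every subcomponent of the benchmark event to be matched on both ends.

**Simulator.**  `svgraph simulate` builds a random reference, implants
reported-catalog CSV types (Disdup, Invdup, DelInv, DelDisdup,
DelInvdup, DisdupInvdup, InsInv, Tantrans, DelSpaDel, TanDisdup) or
randomized compositions of basic operations on two haplotypes, samples
wgsim-style read pairs, and places them back on the reference exactly
through the known variant map (or through `bwa mem` with
`--align-mode external_aligner`), emitting BAM + truth TSV.

## Worked example

```bash
svgraph simulate --out-dir demo --seed 5 --genome-length 300000 --n-events 8
svgraph call --bam demo/alignments.bam --ref demo/reference.fa --out-prefix demo/calls
# -> 9 calls written to demo/calls.vcf
svgraph evaluate --truth demo/truth.tsv --pred demo/calls.events.bed \
    --criterion unique_interval
```

which prints

```json
{
 "criterion": "unique_interval",
 "slop": 500,
 "tp": 8,
 "fn": 0,
 "recall": 1.0,
 "fp": 1,
 "precision": 0.8889,
 "f1": 0.9412
}
```

All 8 implanted heterozygous CSVs are recovered within 500 bp on both
ends; one extra call (a low-support discordant cluster) is a false
positive.  `demo/calls.vcf` holds the calls with `CXS`, `LINKTYPES`,
`NNODES` and `NEPE` INFO fields; `demo/calls.bed` adds one junction
interval per paired edge (used by the all-breakpoint criterion) and
`demo/calls.json` the full subgraph of every call.

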
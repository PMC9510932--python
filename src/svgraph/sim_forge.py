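"""Synthetic CSV benchmark generation.

This module makes the whole caller testable offline: it synthesizes a
reference contig, implants simple and complex rearrangements on two
haplotypes, samples wgsim-style paired-end reads, and either maps each
read back to the reference exactly through the known variant map
(truth-guided alignment, the default) or shells out to an external
short-read aligner.  The truth set records the outer interval and the
typed subcomponents of every event.

Rearrangements are compositions of five basic operations — deletion
(Del), inversion (Inv), inverted duplication (Invdup), tandem duplication
(Tandup) and dispersed duplication (Disdup) — plus retained spacers,
novel-sequence insertions and adjacent segment swaps.  The reported-type
catalog covers the ten composite types observed in short-read CSV
surveys: Disdup, Invdup, DelInv, DelDisdup, DelInvdup, DisdupInvdup,
InsInv, Tantrans, DelSpaDel and TanDisdup; randomized mode composes 2-4
random basic operations per locus.

Truth subcomponents for duplication operations record novel-adjacency
junction spans (e.g. a dispersed duplication contributes source-start <->
target and source-end <-> target), the breakpoint pairs a short-read
caller can actually evidence; for Del/Inv/Tandup/Invdup the junction span
coincides with the source interval.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

from .evaluation import TruthRecord, write_truth

__all__ = [
    "SimConfig",
    "OpSpec",
    "CsvSpec",
    "SimDataset",
    "make_reference",
    "reported_catalog_spec",
    "randomized_spec",
    "implant_csvs",
    "simulate_read_pairs",
    "write_fastq",
    "truth_guided_align",
    "external_align",
    "simulate_dataset",
    "REPORTED_TYPES",
]

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated benchmark replicate."""

    genome_length: int = 2_000_000
    gc_fraction: float = 0.41
    n_events: int = 50
    coverage: float = 30.0
    read_length: int = 100
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    base_error_rate: float = 0.01
    seed: int = 1
    mode: str = "reported"  # reported | randomized
    zygosity: str = "het"  # het | hom
    align_mode: str = "truth_guided"  # truth_guided | external_aligner
    contig: str = "chr1"
    event_spacing: int = 10_000

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert_mean must exceed twice the read length")
        if self.mode not in ("reported", "randomized"):
            raise ValueError(f"unknown mode: {self.mode}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity: {self.zygosity}")


# ---------------------------------------------------------------------
# reference


def make_reference(
    path: str,
    genome_length: int,
    gc_fraction: float = 0.41,
    rng: Optional[np.random.Generator] = None,
    contig: str = "chr1",
) -> str:
    """Write a seeded i.i.d. reference FASTA (+ .fai) and return the sequence."""
    if genome_length < 100_000:
        raise ValueError("genome_length must be at least 100 kb")
    if rng is None:
        rng = np.random.default_rng(0)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                       size=genome_length, p=[at, gc, gc, at])
    seq = codes.tobytes().decode("ascii")
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, genome_length, 60):
            fh.write(seq[i : i + 60])
            fh.write("\n")
    pysam.faidx(path)
    return seq


# ---------------------------------------------------------------------
# rearrangement specs

REPORTED_TYPES = (
    "Disdup", "Invdup", "DelInv", "DelDisdup", "DelInvdup",
    "DisdupInvdup", "InsInv", "Tantrans", "DelSpaDel", "TanDisdup",
)


@dataclass(frozen=True)
class OpSpec:
    """One basic operation inside a composite rearrangement.

    ``gap`` is untouched reference preceding the operation; ``offset`` is
    the dispersal distance of a Disdup target beyond the source segment;
    ``copies`` the number of tandem copies a Disdup inserts; ``length2``
    the second segment of a Tantrans swap.
    """

    op: str  # Del | Inv | Invdup | Tandup | Disdup | spacer | Ins | Tantrans
    length: int
    gap: int = 0
    offset: int = 0
    copies: int = 1
    inverted: bool = False
    length2: int = 0

    def __post_init__(self) -> None:
        if self.length < 50 and self.op != "Ins":
            raise ValueError("operation length must be >= 50 bp")


@dataclass(frozen=True)
class CsvSpec:
    """A named composite rearrangement: ordered basic operations + zygosity."""

    name: str
    operations: tuple[OpSpec, ...]
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if not self.operations:
            raise ValueError("CsvSpec needs at least one operation")


def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def reported_catalog_spec(
    name: str, rng: np.random.Generator, zygosity: str = "het",
    length_range: tuple[int, int] = (100, 1000),
) -> CsvSpec:
    """Draw a concrete spec for one reported-catalog CSV type."""
    L = lambda: _log_uniform(rng, *length_range)
    gap = lambda: int(rng.integers(20, 201))
    off = lambda: int(rng.integers(800, 2501))
    ops: tuple[OpSpec, ...]
    if name == "Disdup":
        ops = (OpSpec("Disdup", L(), offset=off()),)
    elif name == "Invdup":
        ops = (OpSpec("Invdup", L()),)
    elif name == "DelInv":
        ops = (OpSpec("Del", L()), OpSpec("Inv", L()))
    elif name == "DelDisdup":
        ops = (OpSpec("Del", L()), OpSpec("Disdup", L(), gap=gap(), offset=off()))
    elif name == "DelInvdup":
        ops = (OpSpec("Del", L()), OpSpec("Invdup", L(), gap=gap()))
    elif name == "DisdupInvdup":
        ops = (OpSpec("Disdup", L(), offset=off()), OpSpec("Invdup", L(), gap=gap()))
    elif name == "InsInv":
        ops = (OpSpec("Inv", L()), OpSpec("Ins", int(rng.integers(55, 81))))
    elif name == "Tantrans":
        ops = (OpSpec("Tantrans", L(), length2=L()),)
    elif name == "DelSpaDel":
        ops = (
            OpSpec("Del", L()),
            OpSpec("spacer", L(), inverted=bool(rng.integers(0, 2))),
            OpSpec("Del", L()),
        )
    elif name == "TanDisdup":
        ops = (OpSpec("Disdup", L(), offset=off(), copies=2),)
    else:
        raise ValueError(f"unknown reported CSV type: {name}")
    return CsvSpec(name, ops, zygosity)


_BASIC_OPS = ("Del", "Inv", "Invdup", "Tandup", "Disdup")


def randomized_spec(
    rng: np.random.Generator, zygosity: str = "het",
    length_range: tuple[int, int] = (100, 5000),
) -> CsvSpec:
    """Compose 2-4 random basic operations sharing one anchor locus."""
    n_ops = int(rng.integers(2, 5))
    ops = []
    names = []
    for i in range(n_ops):
        op = str(rng.choice(_BASIC_OPS))
        names.append(op)
        kw = {"gap": int(rng.integers(20, 201)) if i else 0}
        if op == "Disdup":
            kw["offset"] = int(rng.integers(800, 2501))
        ops.append(OpSpec(op, _log_uniform(rng, *length_range), **kw))
    return CsvSpec("+".join(names), tuple(ops), zygosity)


# ---------------------------------------------------------------------
# haplotype blocks


@dataclass(frozen=True)
class Block:
    """A haplotype segment: a reference slice (possibly inverted) or novel sequence."""

    ref_start: int
    ref_end: int
    strand: str = "+"  # '+' | '-'
    novel: Optional[str] = None

    def __len__(self) -> int:
        if self.novel is not None:
            return len(self.novel)
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class _Realization:
    name: str
    zygosity: str
    consumed: tuple[int, int]  # reference interval the blocks replace
    blocks: tuple[Block, ...]
    components: tuple[tuple[str, int, int], ...]


def _realize(spec: CsvSpec, anchor: int) -> _Realization:
    """Expand a CsvSpec into haplotype blocks anchored at ``anchor``."""
    cursor = anchor
    blocks: list[Block] = []
    comps: list[tuple[str, int, int]] = []
    for op in spec.operations:
        if op.gap:
            blocks.append(Block(cursor, cursor + op.gap))
            cursor += op.gap
        s = cursor
        e = s + op.length
        if op.op == "Del":
            comps.append(("Del", s, e))
            cursor = e
        elif op.op == "Inv":
            blocks.append(Block(s, e, "-"))
            comps.append(("Inv", s, e))
            cursor = e
        elif op.op == "spacer":
            blocks.append(Block(s, e, "-" if op.inverted else "+"))
            comps.append(("spacer", s, e))
            cursor = e
        elif op.op == "Tandup":
            blocks.append(Block(s, e))
            blocks.append(Block(s, e))
            comps.append(("Tandup", s, e))
            cursor = e
        elif op.op == "Invdup":
            blocks.append(Block(s, e))
            blocks.append(Block(s, e, "-"))
            comps.append(("Invdup", s, e))
            cursor = e
        elif op.op == "Disdup":
            t = e + op.offset
            blocks.append(Block(s, t))
            for _ in range(op.copies):
                blocks.append(Block(s, e))
            label = "TanDisdup" if op.copies > 1 else "Disdup"
            comps.append((label, s, t))
            comps.append((label, e, t))
            if op.copies > 1:
                comps.append((label, s, e))
            cursor = t
        elif op.op == "Ins":
            comps.append(("Ins", cursor, cursor))
            blocks.append(Block(0, 0, novel="__NOVEL__" + str(op.length)))
            # placeholder; the actual sequence is drawn once in implant_csvs
        elif op.op == "Tantrans":
            m = s + op.length
            e = m + op.length2
            blocks.append(Block(m, e))
            blocks.append(Block(s, m))
            comps.append(("Tantrans", s, m))
            comps.append(("Tantrans", m, e))
            cursor = e
        else:
            raise ValueError(f"unknown operation: {op.op}")
    return _Realization(spec.name, spec.zygosity, (anchor, cursor),
                        tuple(blocks), tuple(comps))


class HaplotypeMap:
    """One haplotype as an ordered list of blocks with cumulative offsets."""

    def __init__(self, blocks: Sequence[Block]):
        merged: list[Block] = []
        for b in blocks:
            if len(b) == 0:
                continue
            if merged and merged[-1].novel is None and b.novel is None:
                p = merged[-1]
                if p.strand == "+" == b.strand and p.ref_end == b.ref_start:
                    merged[-1] = Block(p.ref_start, b.ref_end, "+")
                    continue
                if p.strand == "-" == b.strand and b.ref_end == p.ref_start:
                    merged[-1] = Block(b.ref_start, p.ref_end, "-")
                    continue
            merged.append(b)
        self.blocks = merged
        self.offsets = np.cumsum([0] + [len(b) for b in merged])
        self.length = int(self.offsets[-1])

    def sequence(self, ref_seq: str) -> str:
        parts = []
        for b in self.blocks:
            if b.novel is not None:
                parts.append(b.novel)
            elif b.strand == "+":
                parts.append(ref_seq[b.ref_start : b.ref_end])
            else:
                parts.append(revcomp(ref_seq[b.ref_start : b.ref_end]))
        return "".join(parts)

    def map_interval(
        self, start: int, end: int
    ) -> list[tuple[int, int, Optional[int], Optional[int], str]]:
        """Map haplotype [start, end) to reference segments.

        Returns ``(q0, q1, ref_start, ref_end, strand)`` with ``q`` offsets
        relative to ``start`` in haplotype orientation; novel-sequence
        spans carry ``ref_start is None``.
        """
        out = []
        i = int(np.searchsorted(self.offsets, start, side="right")) - 1
        pos = start
        while pos < end and i < len(self.blocks):
            b = self.blocks[i]
            b0 = int(self.offsets[i])
            lo = pos - b0
            hi = min(end - b0, len(b))
            if b.novel is not None:
                out.append((pos - start, pos - start + (hi - lo), None, None, "+"))
            elif b.strand == "+":
                out.append(
                    (pos - start, pos - start + (hi - lo),
                     b.ref_start + lo, b.ref_start + hi, "+")
                )
            else:
                out.append(
                    (pos - start, pos - start + (hi - lo),
                     b.ref_end - hi, b.ref_end - lo, "-")
                )
            pos = b0 + hi
            i += 1
        return out


def implant_csvs(
    ref_len: int,
    config: SimConfig,
    rng: np.random.Generator,
    specs: Optional[Sequence[CsvSpec]] = None,
) -> tuple[HaplotypeMap, HaplotypeMap, list[TruthRecord]]:
    """Place events on the reference and build two haplotype maps.

    Events are placed left to right with at least ``event_spacing`` bp of
    untouched reference between them; heterozygous events modify one
    (randomly chosen) haplotype, homozygous events both.  Raises when the
    events cannot fit with the required spacing.
    """
    if specs is None:
        specs = []
        for _ in range(config.n_events):
            if config.mode == "reported":
                name = str(rng.choice(REPORTED_TYPES))
                specs.append(reported_catalog_spec(name, rng, config.zygosity))
            else:
                specs.append(randomized_spec(rng, config.zygosity))

    margin = 5000
    reals: list[_Realization] = []
    cursor = margin
    for k, spec in enumerate(specs):
        anchor = cursor + int(rng.integers(0, 500))
        real = _realize(spec, anchor)
        blocks = []
        for b in real.blocks:
            if b.novel is not None and b.novel.startswith("__NOVEL__"):
                n = int(b.novel.removeprefix("__NOVEL__"))
                codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n)
                b = Block(0, 0, novel=codes.tobytes().decode("ascii"))
            blocks.append(b)
        real = replace(real, blocks=tuple(blocks))
        reals.append(real)
        cursor = real.consumed[1] + config.event_spacing
    if cursor - config.event_spacing + margin > ref_len:
        raise ValueError(
            f"{len(specs)} events need {cursor + margin} bp, "
            f"reference is only {ref_len} bp"
        )

    hap_blocks: tuple[list[Block], list[Block]] = ([], [])
    prev = [0, 0]
    truths: list[TruthRecord] = []
    for real in reals:
        a, b = real.consumed
        targets = (0, 1) if real.zygosity == "hom" else (int(rng.integers(0, 2)),)
        for h in (0, 1):
            if h in targets:
                hap_blocks[h].append(Block(prev[h], a))
                hap_blocks[h].extend(real.blocks)
                prev[h] = b
        coords = [a, b]
        for _, s, e in real.components:
            coords.extend((s, e))
        outer = (min(coords), max(coords))
        comps = tuple(
            (ty, min(s, e), max(s, e)) for ty, s, e in real.components
        )
        truths.append(
            TruthRecord(config.contig, outer[0], outer[1], comps, real.zygosity)
        )
    for h in (0, 1):
        hap_blocks[h].append(Block(prev[h], ref_len))
    return HaplotypeMap(hap_blocks[0]), HaplotypeMap(hap_blocks[1]), truths


# ---------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadPair:
    name: str
    hap: int
    frag_start: int
    insert: int
    seq1: str  # leftmost read, haplotype forward strand
    seq2: str  # rightmost read, reverse-complemented


def _apply_errors(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err <= 0:
        return seq
    positions = rng.integers(0, len(seq), size=n_err)
    bases = "ACGT"
    out = list(seq)
    for p in positions:
        cur = out[p]
        choices = [b for b in bases if b != cur]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_read_pairs(
    hap_seqs: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> Iterator[ReadPair]:
    """wgsim-style paired-end sampling from the haplotype sequences.

    Fragment starts are uniform per haplotype, inserts are normal
    (``insert_mean``, ``insert_sd``, floored at twice the read length),
    reads are taken from both fragment ends with i.i.d. substitution
    errors.  The expected pair count is
    ``coverage * total_haplotype_length / (2 * 2 * read_length)``.
    """
    rl = config.read_length
    total = sum(len(s) for s in hap_seqs)
    n_pairs = int(round(config.coverage * total / (2 * 2 * rl)))
    hap_p = np.array([len(s) / total for s in hap_seqs])
    haps = rng.choice(len(hap_seqs), size=n_pairs, p=hap_p)
    inserts = np.maximum(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)),
        2 * rl,
    ).astype(np.int64)
    u = rng.random(size=n_pairs)
    if config.base_error_rate > 0:
        n_err = rng.binomial(rl, config.base_error_rate, size=(n_pairs, 2))
    else:
        n_err = np.zeros((n_pairs, 2), dtype=np.int64)
    for i in range(n_pairs):
        hap = int(haps[i])
        seq = hap_seqs[hap]
        ins = min(int(inserts[i]), len(seq))
        start = int(u[i] * (len(seq) - ins + 1))
        s1 = seq[start : start + rl]
        s2 = revcomp(seq[start + ins - rl : start + ins])
        if n_err[i, 0]:
            s1 = _apply_errors(s1, int(n_err[i, 0]), rng)
        if n_err[i, 1]:
            s2 = _apply_errors(s2, int(n_err[i, 1]), rng)
        yield ReadPair(f"sim{i}", hap, start, ins, s1, s2)


def write_fastq(pairs: Iterable[ReadPair], fq1_path: str, fq2_path: str) -> None:
    with open(fq1_path, "w") as f1, open(fq2_path, "w") as f2:
        for p in pairs:
            q1 = "I" * len(p.seq1)
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


# ---------------------------------------------------------------------
# truth-guided alignment

_MIN_PIECE = 20  # smallest mapped piece emitted as its own record


def _segments_for_read(
    hapmap: HaplotypeMap, start: int, end: int, read_revcomp: bool, rl: int
) -> list[tuple[int, int, int, bool]]:
    """Mappable pieces of one read: (q0, q1, ref_start, is_reverse).

    ``q`` coordinates are in read orientation (after reverse complement
    for the rightmost read of the pair).
    """
    segs = []
    for q0, q1, rs, re_, strand in hapmap.map_interval(start, end):
        if rs is None or q1 - q0 < _MIN_PIECE:
            continue
        if read_revcomp:
            a, b = rl - q1, rl - q0
        else:
            a, b = q0, q1
        is_rev = read_revcomp ^ (strand == "-")
        segs.append((a, b, rs, is_rev))
    segs.sort()
    return segs


def _make_records(
    name: str,
    flag_read2: bool,
    seq: str,
    segs: list[tuple[int, int, int, bool]],
    tid: int,
    header: pysam.AlignmentHeader,
    contig: str,
) -> list[pysam.AlignedSegment]:
    """Primary + supplementary records for one read (longest piece primary)."""
    rl = len(seq)
    primary_idx = max(range(len(segs)), key=lambda i: segs[i][1] - segs[i][0])
    records = []
    sa_items = []
    for i, (a, b, rs, is_rev) in enumerate(segs):
        if is_rev:
            sa, sb = rl - b, rl - a
            stored = revcomp(seq)
        else:
            sa, sb = a, b
            stored = seq
        cigar = []
        if sa:
            cigar.append((4, sa))
        cigar.append((0, b - a))
        if rl - sb:
            cigar.append((4, rl - sb))
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.query_sequence = stored
        rec.reference_id = tid
        rec.reference_start = rs
        rec.mapping_quality = 60
        rec.cigartuples = cigar
        rec.is_paired = True
        rec.is_read2 = flag_read2
        rec.is_read1 = not flag_read2
        rec.is_reverse = is_rev
        rec.is_supplementary = i != primary_idx
        records.append(rec)
        cig_str = "".join(f"{ln}{'MS'[op == 4]}" for op, ln in cigar)
        sa_items.append(f"{contig},{rs + 1},{'-' if is_rev else '+'},{cig_str},60,0;")
    if len(records) > 1:
        for i, rec in enumerate(records):
            rec.set_tag(
                "SA", "".join(sa_items[:i] + sa_items[i + 1 :]), value_type="Z"
            )
    # move primary first
    records.sort(key=lambda r: r.is_supplementary)
    return records


def truth_guided_align(
    pairs: Iterable[ReadPair],
    hapmaps: Sequence[HaplotypeMap],
    config: SimConfig,
    ref_len: int,
    out_bam: str,
) -> None:
    """Place simulated reads on the reference through the variant map.

    Reads spanning a breakpoint are emitted as clipped/split records with
    SA tags; pairs straddling rearranged segments receive the discordant
    orientations and template lengths the rearrangement implies.  Output
    is a coordinate-sorted, indexed BAM.
    """
    rl = config.read_length
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": config.contig, "LN": ref_len}],
        }
    )
    proper_max = config.insert_mean + 4 * config.insert_sd
    tmp = out_bam + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for p in pairs:
            hm = hapmaps[p.hap]
            segs1 = _segments_for_read(hm, p.frag_start, p.frag_start + rl, False, rl)
            segs2 = _segments_for_read(
                hm, p.frag_start + p.insert - rl, p.frag_start + p.insert, True, rl
            )
            recs1 = (
                _make_records(p.name, False, p.seq1, segs1, 0, header, config.contig)
                if segs1
                else []
            )
            recs2 = (
                _make_records(p.name, True, p.seq2, segs2, 0, header, config.contig)
                if segs2
                else []
            )
            _set_mate_fields(recs1, recs2, proper_max)
            for rec in recs1 + recs2:
                bam.write(rec)
    pysam.sort("-l", "2", "-o", out_bam, tmp)
    os.unlink(tmp)
    pysam.index(out_bam)


def _set_mate_fields(
    recs1: list[pysam.AlignedSegment],
    recs2: list[pysam.AlignedSegment],
    proper_max: float,
) -> None:
    p1 = recs1[0] if recs1 else None
    p2 = recs2[0] if recs2 else None
    for own, mate, own_all in ((p1, p2, recs1), (p2, p1, recs2)):
        for rec in own_all:
            if mate is None:
                rec.mate_is_unmapped = True
                rec.next_reference_id = rec.reference_id
                rec.next_reference_start = rec.reference_start
            else:
                rec.next_reference_id = mate.reference_id
                rec.next_reference_start = mate.reference_start
                rec.mate_is_reverse = mate.is_reverse
    if p1 is None or p2 is None:
        return
    lo = min(p1.reference_start, p2.reference_start)
    hi = max(p1.reference_end, p2.reference_end)
    tlen = hi - lo
    first, second = (p1, p2) if p1.reference_start <= p2.reference_start else (p2, p1)
    first.template_length = tlen
    second.template_length = -tlen
    proper = (
        len(recs1) == 1
        and len(recs2) == 1
        and not first.is_reverse
        and second.is_reverse
        and first.cigartuples[0][0] == 0 == first.cigartuples[-1][0]
        and second.cigartuples[0][0] == 0 == second.cigartuples[-1][0]
        and 0 < tlen <= proper_max
    )
    if proper:
        p1.is_proper_pair = True
        p2.is_proper_pair = True


def external_align(
    fq1: str, fq2: str, reference: str, out_bam: str, threads: int = 1
) -> None:
    """Map simulated reads with an external short-read aligner (bwa mem)."""
    bwa = shutil.which("bwa")
    samtools = shutil.which("samtools")
    if bwa is None or samtools is None:
        raise RuntimeError("external alignment requires bwa and samtools on PATH")
    if not os.path.exists(reference + ".bwt"):
        subprocess.run([bwa, "index", reference], check=True, capture_output=True)
    with tempfile.NamedTemporaryFile(suffix=".sam", delete=False) as tmp:
        sam_path = tmp.name
    try:
        with open(sam_path, "w") as sam:
            subprocess.run(
                [bwa, "mem", "-t", str(threads), reference, fq1, fq2],
                check=True, stdout=sam, stderr=subprocess.DEVNULL,
            )
        pysam.sort("-l", "2", "-o", out_bam, sam_path)
        pysam.index(out_bam)
    finally:
        os.unlink(sam_path)


# ---------------------------------------------------------------------
# one-call dataset generation


@dataclass(frozen=True)
class SimDataset:
    reference_fasta: str
    bam: str
    truth_tsv: str
    truths: tuple[TruthRecord, ...]
    config: SimConfig


def simulate_dataset(
    config: SimConfig,
    out_dir: str,
    specs: Optional[Sequence[CsvSpec]] = None,
    keep_fastq: bool = False,
) -> SimDataset:
    """Generate reference, implant CSVs, simulate reads, align, write truth.

    All randomness flows from ``config.seed``; two runs with equal configs
    produce identical outputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ref_path = os.path.join(out_dir, "reference.fa")
    ref_seq = make_reference(
        ref_path, config.genome_length, config.gc_fraction, rng, config.contig
    )
    hap1, hap2, truths = implant_csvs(len(ref_seq), config, rng, specs)
    truth_path = os.path.join(out_dir, "truth.tsv")
    write_truth(truths, truth_path)
    seqs = [hap1.sequence(ref_seq), hap2.sequence(ref_seq)]
    bam_path = os.path.join(out_dir, "alignments.bam")
    if config.align_mode == "truth_guided" and not keep_fastq:
        pair_iter = simulate_read_pairs(seqs, config, rng)
        truth_guided_align(pair_iter, [hap1, hap2], config, len(ref_seq), bam_path)
    else:
        pairs = list(simulate_read_pairs(seqs, config, rng))
        fq1 = os.path.join(out_dir, "reads_1.fastq")
        fq2 = os.path.join(out_dir, "reads_2.fastq")
        write_fastq(pairs, fq1, fq2)
        if config.align_mode == "external_aligner":
            external_align(fq1, fq2, ref_path, bam_path)
        else:
            truth_guided_align(pairs, [hap1, hap2], config, len(ref_seq), bam_path)
    return SimDataset(ref_path, bam_path, truth_path, tuple(truths), config)
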
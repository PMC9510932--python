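"""Abnormal-alignment signal extraction.

A complex structural variant leaves several kinds of footprints in a
paired-end short-read alignment: clipped reads whose unaligned tail marks a
breakpoint, split reads whose supplementary piece maps across a junction,
and discordant read-pairs whose insert size or mutual orientation violates
the library expectation.  This module estimates the library insert-size
profile and converts each alignment record into zero or more typed
:class:`Signal` objects, the raw material of the signal graph.

Coordinates are 0-based half-open throughout; clip/split signals are
anchored on the boundary of the aligned portion on the clipped side.
"""

from __future__ import annotations

import enum
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

__all__ = [
    "SignalKind",
    "Signal",
    "InsertSizeProfile",
    "SignalParams",
    "InsufficientPairsError",
    "estimate_insert_profile",
    "classify_alignment",
    "extract_signals",
]


class SignalKind(enum.Enum):
    """Abnormal-alignment signal types (the *type* attribute of a node)."""

    CLIP_LEFT = "CLIP_LEFT"
    CLIP_RIGHT = "CLIP_RIGHT"
    SPLIT = "SPLIT"
    ARP_LARGE_INSERT = "ARP_LARGE_INSERT"
    ARP_SMALL_INSERT = "ARP_SMALL_INSERT"
    ARP_RF = "ARP_RF"
    ARP_FF = "ARP_FF"
    ARP_RR = "ARP_RR"


#: kinds carried by one end of a discordant read-pair
ARP_KINDS = frozenset(
    {
        SignalKind.ARP_LARGE_INSERT,
        SignalKind.ARP_SMALL_INSERT,
        SignalKind.ARP_RF,
        SignalKind.ARP_FF,
        SignalKind.ARP_RR,
    }
)


class InsufficientPairsError(ValueError):
    """Raised when too few proper pairs are available to profile the library."""


@dataclass(frozen=True)
class InsertSizeProfile:
    """Library statistics driving the discordance thresholds.

    Attributes
    ----------
    mean_insert, sd_insert:
        Moments of the absolute template length of proper pairs, after
        trimming the top and bottom 1% for robustness.
    read_length:
        Modal primary read length.
    sample_size:
        Number of template lengths the moments were computed from.
    """

    mean_insert: float
    sd_insert: float
    read_length: int
    sample_size: int

    def __post_init__(self) -> None:
        if self.mean_insert <= 0:
            raise ValueError("mean_insert must be positive")
        if self.sd_insert < 0:
            raise ValueError("sd_insert must be non-negative")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass(frozen=True)
class SignalParams:
    """Thresholds for signal classification.

    min_clip_fraction
        Minimum clipped fraction of the full read length for a clip/split
        signal (soft and hard clips both count).
    min_split_mapq
        Minimum mapping quality for split-read signals.
    insert_sd_mult
        ``k`` in the discordance rule: a pair is insert-discordant when its
        template length falls outside ``mean +/- k * sd``.
    """

    min_clip_fraction: float = 0.10
    min_split_mapq: int = 20
    insert_sd_mult: float = 3.0


@dataclass(frozen=True)
class Signal:
    """A single abnormal-alignment observation.

    ``pos`` is the breakpoint-proximal coordinate: the clip/junction
    boundary for CLIP/SPLIT, the inner edge of the read for ARP kinds.
    ``read_id`` identifies the read end (``<qname>/1`` or ``<qname>/2``);
    :meth:`pair_name` recovers the fragment name shared by both ends.
    """

    kind: SignalKind
    contig: str
    pos: int
    read_id: str
    mapq: int
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("signal pos must be >= 0")

    def pair_name(self) -> str:
        return self.read_id.rsplit("/", 1)[0]


def estimate_insert_profile(
    alignments: Iterable[pysam.AlignedSegment],
    min_sample: int = 1000,
) -> InsertSizeProfile:
    """Estimate the insert-size profile from primary proper pairs.

    Template lengths are collected once per pair (the end with positive
    TLEN), the top and bottom 1% are discarded, and the remaining sample
    moments define the profile.  Raises :class:`InsufficientPairsError`
    when fewer than ``min_sample`` usable pairs are seen.
    """
    tlens: list[int] = []
    read_lengths: Counter[int] = Counter()
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.is_duplicate or rec.is_qcfail:
            continue
        rlen = rec.infer_read_length() or rec.query_length
        if rlen:
            read_lengths[rlen] += 1
        if rec.is_proper_pair and rec.template_length > 0:
            tlens.append(rec.template_length)
    if len(tlens) < min_sample:
        raise InsufficientPairsError(
            f"only {len(tlens)} usable proper pairs found, "
            f"need at least {min_sample}"
        )
    arr = np.sort(np.abs(np.asarray(tlens, dtype=np.float64)))
    trim = int(len(arr) * 0.01)
    if trim:
        arr = arr[trim:-trim]
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    read_length = read_lengths.most_common(1)[0][0]
    return InsertSizeProfile(
        mean_insert=mean,
        sd_insert=sd,
        read_length=int(read_length),
        sample_size=int(arr.size),
    )


def _clip_lengths(rec: pysam.AlignedSegment) -> tuple[int, int]:
    """(left, right) clipped bases, soft and hard clips both counted."""
    cig = rec.cigartuples
    if not cig:
        return 0, 0
    left = right = 0
    i = 0
    while i < len(cig) and cig[i][0] in (4, 5):
        left += cig[i][1]
        i += 1
    j = len(cig) - 1
    while j >= 0 and cig[j][0] in (4, 5):
        right += cig[j][1]
        j -= 1
    return left, right


def _read_end_id(rec: pysam.AlignedSegment) -> str:
    suffix = "/2" if rec.is_read2 else "/1"
    return f"{rec.query_name}{suffix}"


def classify_alignment(
    rec: pysam.AlignedSegment,
    profile: InsertSizeProfile,
    params: SignalParams = SignalParams(),
) -> list[Signal]:
    """Classify one alignment record into zero or more signals.

    Rules, in the order applied:

    * a clipped side whose clip length is at least ``min_clip_fraction`` of
      the full read length yields a SPLIT signal (when the record has a
      split companion and sufficient mapping quality) or a CLIP signal
      otherwise, anchored at the boundary of the aligned portion;
    * a primary record of an intrachromosomal pair with abnormal mutual
      orientation yields ARP_RF / ARP_FF / ARP_RR; a normally oriented
      (FR) pair with template length outside ``mean +/- k*sd`` yields
      ARP_LARGE_INSERT or ARP_SMALL_INSERT.

    Unmapped, secondary, duplicate and QC-fail records yield no signal.
    Supplementary records contribute split signals only.
    """
    if rec.is_unmapped or rec.is_secondary or rec.is_duplicate or rec.is_qcfail:
        return []
    if rec.cigartuples is None:
        return []

    out: list[Signal] = []
    contig = rec.reference_name
    read_id = _read_end_id(rec)
    rlen = rec.infer_read_length() or rec.query_length or profile.read_length
    min_clip = params.min_clip_fraction * rlen
    left_clip, right_clip = _clip_lengths(rec)
    is_split = rec.is_supplementary or rec.has_tag("SA")

    # clip / split signals at the aligned-portion boundaries
    for clip_len, kind_clip, pos in (
        (left_clip, SignalKind.CLIP_LEFT, rec.reference_start),
        (right_clip, SignalKind.CLIP_RIGHT, rec.reference_end),
    ):
        if clip_len < min_clip or clip_len <= 0:
            continue
        if is_split and rec.mapping_quality >= params.min_split_mapq:
            out.append(
                Signal(SignalKind.SPLIT, contig, pos, read_id, rec.mapping_quality)
            )
        elif not rec.is_supplementary:
            # low-quality split companions still mark a plain clip
            out.append(Signal(kind_clip, contig, pos, read_id, rec.mapping_quality))

    # discordant read-pair signals: primary intrachromosomal pairs only
    if (
        not rec.is_supplementary
        and rec.is_paired
        and not rec.mate_is_unmapped
        and rec.reference_id == rec.next_reference_id
    ):
        kind = _discordant_kind(rec, profile, params)
        if kind is not None:
            self_left = rec.reference_start < rec.next_reference_start or (
                rec.reference_start == rec.next_reference_start and not rec.is_read2
            )
            pos = rec.reference_end if self_left else rec.reference_start
            out.append(
                Signal(
                    kind,
                    contig,
                    pos,
                    read_id,
                    rec.mapping_quality,
                    mate_contig=rec.next_reference_name,
                    mate_pos=rec.next_reference_start,
                )
            )
    return out


def _discordant_kind(
    rec: pysam.AlignedSegment,
    profile: InsertSizeProfile,
    params: SignalParams,
) -> Optional[SignalKind]:
    self_rev = rec.is_reverse
    mate_rev = rec.mate_is_reverse
    if self_rev == mate_rev:
        return SignalKind.ARP_RR if self_rev else SignalKind.ARP_FF
    left_rev = self_rev if rec.reference_start <= rec.next_reference_start else mate_rev
    if rec.reference_start == rec.next_reference_start:
        # fully overlapping pair: orientation of the leftmost read is
        # ambiguous, treat as normal FR and fall through to insert checks
        left_rev = False
    if left_rev:
        return SignalKind.ARP_RF
    tlen = abs(rec.template_length)
    if tlen == 0:
        return None
    k = params.insert_sd_mult
    if tlen > profile.mean_insert + k * profile.sd_insert:
        return SignalKind.ARP_LARGE_INSERT
    if tlen < max(profile.mean_insert - k * profile.sd_insert, 0.0):
        return SignalKind.ARP_SMALL_INSERT
    return None


def extract_signals(
    bam_path: str,
    profile: InsertSizeProfile,
    params: SignalParams = SignalParams(),
    region: Optional[tuple[str, int, int]] = None,
) -> list[Signal]:
    """Collect all signals from a coordinate-sorted, indexed BAM.

    Returns signals sorted by (contig, pos, kind, read_id); deterministic
    for a fixed file.  ``region`` restricts extraction to
    ``(contig, start, end)``.
    """
    signals: list[Signal] = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(f"BAM index missing for {bam_path}")
        if region is not None:
            it: Iterator[pysam.AlignedSegment] = bam.fetch(*region)
        else:
            it = bam.fetch()
        for rec in it:
            signals.extend(classify_alignment(rec, profile, params))
    signals.sort(key=lambda s: (s.contig, s.pos, s.kind.value, s.read_id))
    return signals
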
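"""Two-tier matching of predictions against a truth set.

A benchmark complex SV is matched at two stringencies:

* unique-interval match — one predicted interval whose start and end each
  fall within ``slop`` bp (default 500) of the benchmark's outermost
  breakpoints;
* all-breakpoint match — every subcomponent of the benchmark is matched
  by at least one prediction on both ends (predictions may be reused
  across components).

True positives satisfy the chosen criterion; unmatched predictions are
false positives and unmatched benchmark events false negatives.  For
real-data-style scoring without a curated negative set, ``recall_only``
suppresses the precision side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

__all__ = [
    "Interval",
    "TruthRecord",
    "MatchReport",
    "unique_interval_match",
    "all_breakpoint_match",
    "score",
    "read_truth",
    "write_truth",
    "read_bed",
]

Interval = tuple[str, int, int]  # contig, start, end (0-based half-open)

Criterion = Literal["unique_interval", "all_breakpoint"]


@dataclass(frozen=True)
class TruthRecord:
    """A benchmark CSV: outer interval plus typed subcomponents."""

    contig: str
    start: int
    end: int
    components: tuple[tuple[str, int, int], ...]
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("truth record needs at least one component")
        for _, s, e in self.components:
            if not (self.start <= s and e <= self.end):
                raise ValueError("component interval outside outer interval")


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: Optional[float]
    f1: Optional[float]
    tiers: list[str] = field(default_factory=list)  # per-truth: none|<criterion>


def _ends_within(pred: Interval, contig: str, start: int, end: int, slop: int) -> bool:
    return (
        pred[0] == contig
        and abs(pred[1] - start) <= slop
        and abs(pred[2] - end) <= slop
    )


def unique_interval_match(pred: Interval, truth: TruthRecord, slop: int = 500) -> bool:
    """Both predicted breakpoints within ``slop`` of the outer breakpoints."""
    return _ends_within(pred, truth.contig, truth.start, truth.end, slop)


def all_breakpoint_match(
    preds: Iterable[Interval], truth: TruthRecord, slop: int = 500
) -> bool:
    """Every subcomponent matched by some prediction on both ends."""
    preds = list(preds)
    for _, s, e in truth.components:
        if not any(_ends_within(p, truth.contig, s, e, slop) for p in preds):
            return False
    return True


def score(
    preds: Sequence[Interval],
    truths: Sequence[TruthRecord],
    criterion: Criterion = "unique_interval",
    slop: int = 500,
    recall_only: bool = False,
) -> MatchReport:
    """Score predictions against the truth set under one match criterion.

    Unique-interval scoring assigns predictions to truths one-to-one,
    greedily by smallest summed breakpoint shift, so a single prediction
    cannot satisfy two benchmark events.  All-breakpoint scoring lets
    predictions be reused across components; a prediction is a false
    positive when it matches no component (and no outer interval) of any
    benchmark event.
    """
    preds = sorted(preds)
    truths_sorted = sorted(enumerate(truths), key=lambda kv: (kv[1].contig, kv[1].start))
    tiers = ["none"] * len(truths)

    if criterion == "unique_interval":
        cand = []
        for ti, t in truths_sorted:
            for pi, p in enumerate(preds):
                if unique_interval_match(p, t, slop):
                    shift = abs(p[1] - t.start) + abs(p[2] - t.end)
                    cand.append((shift, ti, pi))
        cand.sort()
        used_t: set[int] = set()
        used_p: set[int] = set()
        for shift, ti, pi in cand:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            tiers[ti] = "unique_interval"
        tp = len(used_t)
        fp = len(preds) - len(used_p)
    elif criterion == "all_breakpoint":
        matched_p: set[int] = set()
        tp = 0
        for ti, t in truths_sorted:
            if all_breakpoint_match(preds, t, slop):
                tp += 1
                tiers[ti] = "all_breakpoint"
            for pi, p in enumerate(preds):
                if unique_interval_match(p, t, slop) or any(
                    _ends_within(p, t.contig, s, e, slop) for _, s, e in t.components
                ):
                    matched_p.add(pi)
        fp = len(preds) - len(matched_p)
    else:
        raise ValueError(f"unknown criterion: {criterion}")

    fn = len(truths) - tp
    recall = tp / len(truths) if truths else 0.0
    if recall_only:
        precision = f1 = None
    else:
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        denom = recall + precision
        f1 = 2 * recall * precision / denom if denom else 0.0
    return MatchReport(tp=tp, fp=fp, fn=fn, recall=recall,
                       precision=precision, f1=f1, tiers=tiers)


# ---------------------------------------------------------------------
# plain-text formats


def write_truth(truths: Sequence[TruthRecord], path: str) -> None:
    """Truth as BED-like TSV: contig, start, end, zygosity, components.

    Components are encoded ``type:start-end;type:start-end;...``.
    """
    with open(path, "w") as fh:
        for t in truths:
            comp = ";".join(f"{ty}:{s}-{e}" for ty, s, e in t.components)
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.zygosity}\t{comp}\n")


def read_truth(path: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, start, end, zygosity, comp = line.split("\t")
            components = []
            for item in comp.split(";"):
                ty, span = item.split(":")
                s, e = span.split("-")
                components.append((ty, int(s), int(e)))
            out.append(
                TruthRecord(contig, int(start), int(end), tuple(components), zygosity)
            )
    return out


def read_bed(path: str) -> list[Interval]:
    """First three BED columns as prediction intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
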
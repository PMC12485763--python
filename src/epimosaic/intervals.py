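"""Genomic interval primitives and BED-style interval algebra.

All coordinates are 0-based, half-open (BED convention). Chromosome names are
compared as exact strings; no normalization is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def distance(self, chrom: str, pos: int) -> float:
        """Distance from a point to the interval; 0 if inside, inf if other chrom."""
        if chrom != self.chrom:
            return float("inf")
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_key(cls, key: str) -> "GenomicInterval":
        chrom, span = key.rsplit(":", 1)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end))


class IntervalSet:
    """A labelled, sorted, non-overlapping collection of GenomicIntervals.

    Overlapping or bookended input intervals are unioned on construction so the
    stored intervals are always normalized.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            _union(sorted(intervals))
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({self.label!r}, n={len(self)})"

    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def overlaps(self, query: GenomicInterval) -> bool:
        return any(iv.overlaps(query) for iv in self.intervals)

    def overlap_bp(self, query: GenomicInterval) -> int:
        bp = 0
        for iv in self.intervals:
            if iv.chrom != query.chrom:
                continue
            bp += max(0, min(iv.end, query.end) - max(iv.start, query.start))
        return bp

    @classmethod
    def from_bed(cls, path, label: str = "") -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        return cls(ivs, label=label or str(path))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _union(sorted_intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of sorted intervals: merge overlapping and bookended neighbours."""
    out: list[GenomicInterval] = []
    for iv in sorted_intervals:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def merge_intervals(
    intervals: Iterable[GenomicInterval],
    max_gap: int = 0,
    min_size: int = 0,
    label: str = "",
) -> IntervalSet:
    """Merge nearby intervals and drop small products.

    Two consecutive intervals are merged when they overlap/bookend or when the
    gap between them is strictly smaller than ``max_gap`` (a minimum allowed
    distance: blocks closer than ``max_gap`` become one). Merged intervals
    shorter than ``min_size`` bp are discarded.
    """
    if max_gap < 0 or min_size < 0:
        raise ValueError("max_gap and min_size must be >= 0")
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom:
            gap = iv.start - merged[-1].end
            if gap <= 0 or gap < max_gap:
                if iv.end > merged[-1].end:
                    merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
                continue
        merged.append(iv)
    kept = [iv for iv in merged if iv.length >= min_size]
    return IntervalSet(kept, label=label)


def multi_intersect(
    interval_sets: Sequence[IntervalSet],
) -> list[tuple[GenomicInterval, int]]:
    """Partition the covered genome at all breakpoints and count covering sets.

    Equivalent to ``bedtools multiinter``: each returned segment is bounded by
    two consecutive breakpoints (from any input set) and annotated with the
    number of input sets that cover it. Segments covered by no set are not
    emitted. Each set contributes at most 1 to a segment's count.
    """
    if not interval_sets:
        raise ValueError("need at least one interval set")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in interval_sets:
        for iv in s:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[tuple[GenomicInterval, int]] = []
    for chrom in sorted(by_chrom):
        events: dict[int, int] = {}
        points: set[int] = set()
        for start, end in by_chrom[chrom]:
            events[start] = events.get(start, 0) + 1
            events[end] = events.get(end, 0) - 1
            points.update((start, end))
        breakpoints = sorted(points)
        depth = 0
        for a, b in zip(breakpoints, breakpoints[1:]):
            depth += events.get(a, 0)
            if depth > 0:
                out.append((GenomicInterval(chrom, a, b), depth))
        # sanity: sweep ends balanced
    return out
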
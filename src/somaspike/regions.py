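"""Genomic interval sets with BED semantics (0-based half-open).

``RegionSet`` normalizes on construction: intervals are sorted, merged when
overlapping or bookended, and empty intervals dropped. Membership queries
for variants use 1-based positions and are converted exactly once here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from intervaltree import IntervalTree

Interval = Tuple[str, int, int]  # contig, start, end (0-based half-open)


@dataclass
class RegionSet:
    intervals: List[Interval] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.intervals = self._normalize(self.intervals)
        self._trees: Dict[str, IntervalTree] = {}
        for contig, start, end in self.intervals:
            self._trees.setdefault(contig, IntervalTree()).addi(start, end)

    @staticmethod
    def _normalize(intervals: Iterable[Interval]) -> List[Interval]:
        by_contig: Dict[str, List[Tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if end < start:
                raise ValueError(f"interval end {end} < start {start} on {contig}")
            if end > start:
                by_contig.setdefault(contig, []).append((start, end))
        out: List[Interval] = []
        for contig in sorted(by_contig):
            merged: List[Tuple[int, int]] = []
            for start, end in sorted(by_contig[contig]):
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            out.extend((contig, s, e) for s, e in merged)
        return out

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, contig: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(contig)
        return bool(tree and tree.overlaps_point(pos - 1))

    def contains_interval0(self, contig: str, start: int, end: int) -> bool:
        """True if the 0-based half-open interval is fully inside the set."""
        tree = self._trees.get(contig)
        if tree is None:
            return False
        hits = tree.overlap(start, end)
        covered = sorted((max(iv.begin, start), min(iv.end, end)) for iv in hits)
        cursor = start
        for s, e in covered:
            if s > cursor:
                return False
            cursor = max(cursor, e)
        return cursor >= end

    def subtract(self, other: "RegionSet", name: str = "") -> "RegionSet":
        out: List[Interval] = []
        for contig, start, end in self.intervals:
            other_tree = other._trees.get(contig)
            if other_tree is None:
                out.append((contig, start, end))
                continue
            tree = IntervalTree()
            tree.addi(start, end)
            for iv in other_tree.overlap(start, end):
                tree.chop(iv.begin, iv.end)
            out.extend((contig, iv.begin, iv.end) for iv in sorted(tree))
        return RegionSet(out, name=name or self.name)

    def intersect(self, other: "RegionSet", name: str = "") -> "RegionSet":
        out: List[Interval] = []
        for contig, start, end in self.intervals:
            other_tree = other._trees.get(contig)
            if other_tree is None:
                continue
            for iv in other_tree.overlap(start, end):
                out.append((contig, max(start, iv.begin), min(end, iv.end)))
        return RegionSet(out, name=name)

    def union(self, other: "RegionSet", name: str = "") -> "RegionSet":
        return RegionSet(self.intervals + other.intervals, name=name)

    def overlaps(self, other: "RegionSet") -> bool:
        return bool(self.intersect(other))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals
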
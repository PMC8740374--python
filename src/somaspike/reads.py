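"""Aligned-read container and CIGAR arithmetic.

Reads are born aligned: the simulator emits true-origin coordinates and simple
CIGARs, and the spiking engine rewrites sequence/CIGAR locally. Only the
M/I/D/S operations are used. SAM semantics: ``pos`` is the 1-based leftmost
mapped position; ``seq`` is stored in reference-forward orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Tuple

import numpy as np

_CIGAR_RE = re.compile(r"(\d+)([MIDS])")

QUERY_CONSUMING = {"M", "I", "S"}
REF_CONSUMING = {"M", "D"}


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"unsupported CIGAR: {cigar!r}")
    return ops


def cigar_str(ops: Iterable[Tuple[int, str]]) -> str:
    merged: List[Tuple[int, str]] = []
    for n, op in ops:
        if n <= 0:
            continue
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return "".join(f"{n}{op}" for n, op in merged)


def cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in QUERY_CONSUMING)


def cigar_reference_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in REF_CONSUMING)


@dataclass
class AlignedRead:
    """A mapped read. ``fragment_id`` ties the two mates of one template."""

    read_id: str
    contig: str
    pos: int  # 1-based leftmost mapped position
    cigar: str
    seq: str
    quals: np.ndarray  # per-base Phred scores, uint8, len == len(seq)
    mapq: int
    strand: str  # "+" or "-"
    fragment_id: str
    origin: str = "normal"  # provenance tag: "normal" or "tumor"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: {len(self.quals)} quals for "
                f"{len(self.seq)} bases"
            )
        qlen = cigar_query_length(self.cigar)
        if qlen != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: CIGAR {self.cigar} consumes {qlen} query "
                f"bases but sequence has {len(self.seq)}"
            )

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost mapped position."""
        return self.pos + cigar_reference_length(self.cigar) - 1

    def overlaps(self, contig: str, pos: int) -> bool:
        return self.contig == contig and self.pos <= pos <= self.reference_end

    def aligned_pairs(self) -> List[Tuple[int, int]]:
        """(query_offset, ref_pos) pairs for M ops; 0-based query, 1-based ref.

        Deleted reference bases appear as ``(-1, ref_pos)``; inserted and
        soft-clipped query bases appear as ``(query_offset, -1)``.
        """
        out: List[Tuple[int, int]] = []
        q, r = 0, self.pos
        for n, op in parse_cigar(self.cigar):
            if op == "M":
                out.extend((q + i, r + i) for i in range(n))
                q += n
                r += n
            elif op == "I" or op == "S":
                out.extend((q + i, -1) for i in range(n))
                q += n
            elif op == "D":
                out.extend((-1, r + i) for i in range(n))
                r += n
        return out

    def query_offset_at(self, ref_pos: int):
        """Query offset aligned (M) to ``ref_pos``, or None if not M-aligned."""
        q, r = 0, self.pos
        for n, op in parse_cigar(self.cigar):
            if op == "M":
                if r <= ref_pos < r + n:
                    return q + (ref_pos - r)
                q += n
                r += n
            elif op in ("I", "S"):
                q += n
            elif op == "D":
                if r <= ref_pos < r + n:
                    return None
                r += n
        return None

    def base_at(self, ref_pos: int):
        off = self.query_offset_at(ref_pos)
        return None if off is None else self.seq[off]

    def copy(self, **kw) -> "AlignedRead":
        kw.setdefault("quals", self.quals.copy())
        return replace(self, **kw)


def group_fragments(reads: Iterable[AlignedRead]) -> Dict[str, List[AlignedRead]]:
    frags: Dict[str, List[AlignedRead]] = {}
    for r in reads:
        frags.setdefault(r.fragment_id, []).append(r)
    return frags


def total_aligned_bases(reads: Iterable[AlignedRead]) -> int:
    return sum(cigar_reference_length(r.cigar) for r in reads)


def mean_coverage(reads: Iterable[AlignedRead], genome_length: int) -> float:
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return total_aligned_bases(reads) / genome_length
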
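"""Quality-aware pileup over in-memory aligned reads.

Computes, per contig, base-count matrices and summary tracks used both for
candidate scanning and for feature encoding. Reads with a plain ``<n>M``
CIGAR (the vast majority) are counted with vectorized numpy scatter-adds;
reads with indels or clips are walked column by column.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from somaspike.reads import AlignedRead, parse_cigar
from somaspike.synthgenome import Reference

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODEMAP = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _CODEMAP[ord(_b)] = _i


@dataclass
class ContigPileup:
    """Per-position tracks over one contig of length L (index 0 = position 1)."""

    length: int
    base_counts: np.ndarray  # (4, L) bq- and mapq-filtered base counts
    raw_counts: np.ndarray  # (4, L) mapq-filtered only
    del_depth: np.ndarray  # (L,) deleted-base depth (mapq-filtered)
    col_depth: np.ndarray  # (L,) reads (mapq-filtered) spanning with M or D
    bq_sum: np.ndarray  # (L,) sum of base qualities over M bases
    mapq_sum: np.ndarray  # (L,) sum of read mapq over M/D columns
    ins_support: Dict[int, Counter] = field(default_factory=dict)  # anchor pos -> {seq: n}
    del_support: Dict[int, Counter] = field(default_factory=dict)  # anchor pos -> {len: n}

    def mean_bq(self) -> np.ndarray:
        if not hasattr(self, "_mean_bq"):
            raw = self.raw_counts.sum(axis=0)
            self._mean_bq = np.divide(
                self.bq_sum, raw, out=np.zeros(self.length), where=raw > 0
            )
        return self._mean_bq

    def mean_mapq(self) -> np.ndarray:
        if not hasattr(self, "_mean_mapq"):
            self._mean_mapq = np.divide(
                self.mapq_sum,
                self.col_depth,
                out=np.zeros(self.length),
                where=self.col_depth > 0,
            )
        return self._mean_mapq


@dataclass
class Pileup:
    contigs: Dict[str, ContigPileup]
    min_mapq: int
    min_bq: int

    def __getitem__(self, name: str) -> ContigPileup:
        return self.contigs[name]


def compute_pileup(
    reads: Sequence[AlignedRead],
    ref: Reference,
    min_mapq: int = 10,
    min_bq: int = 15,
) -> Pileup:
    lengths = ref.lengths
    out: Dict[str, ContigPileup] = {
        name: ContigPileup(
            length=L,
            base_counts=np.zeros((4, L), dtype=np.int32),
            raw_counts=np.zeros((4, L), dtype=np.int32),
            del_depth=np.zeros(L, dtype=np.int32),
            col_depth=np.zeros(L, dtype=np.int32),
            bq_sum=np.zeros(L, dtype=np.int64),
            mapq_sum=np.zeros(L, dtype=np.int64),
        )
        for name, L in lengths.items()
    }

    simple: Dict[Tuple[str, int], List[AlignedRead]] = defaultdict(list)
    complex_reads: List[AlignedRead] = []
    for r in reads:
        if r.mapq < min_mapq:
            continue
        if r.cigar == f"{len(r.seq)}M":
            simple[(r.contig, len(r.seq))].append(r)
        else:
            complex_reads.append(r)

    CHUNK = 50000
    for (contig, rlen), group in simple.items():
        cp = out[contig]
        for lo in range(0, len(group), CHUNK):
            chunk = group[lo : lo + CHUNK]
            starts = np.fromiter((r.pos - 1 for r in chunk), dtype=np.int64, count=len(chunk))
            seqs = np.frombuffer("".join(r.seq for r in chunk).encode(), dtype=np.uint8)
            flat_codes = _CODEMAP[seqs]
            flat_quals = np.concatenate([r.quals for r in chunk])
            mapqs = np.fromiter((r.mapq for r in chunk), dtype=np.int64, count=len(chunk))
            flat_pos = (starts[:, None] + np.arange(rlen)).ravel()
            np.add.at(cp.raw_counts, (flat_codes, flat_pos), 1)
            passing = flat_quals >= min_bq
            np.add.at(cp.base_counts, (flat_codes[passing], flat_pos[passing]), 1)
            np.add.at(cp.bq_sum, flat_pos, flat_quals)
            np.add.at(cp.col_depth, flat_pos, 1)
            np.add.at(cp.mapq_sum, flat_pos, np.repeat(mapqs, rlen))

    for r in complex_reads:
        cp = out[r.contig]
        q, p = 0, r.pos - 1  # p is 0-based
        last_m_ref = None
        for n, op in parse_cigar(r.cigar):
            if op == "M":
                codes = _CODEMAP[np.frombuffer(r.seq[q : q + n].encode(), dtype=np.uint8)]
                bq = r.quals[q : q + n].astype(np.int64)
                idx = np.arange(p, p + n)
                np.add.at(cp.raw_counts, (codes, idx), 1)
                passing = bq >= min_bq
                np.add.at(cp.base_counts, (codes[passing], idx[passing]), 1)
                cp.bq_sum[p : p + n] += bq
                cp.col_depth[p : p + n] += 1
                cp.mapq_sum[p : p + n] += r.mapq
                last_m_ref = p + n - 1
                q += n
                p += n
            elif op == "I":
                if last_m_ref is not None:
                    anchor = last_m_ref + 1  # 1-based anchor position
                    cp.ins_support.setdefault(anchor, Counter())[r.seq[q : q + n]] += 1
                q += n
            elif op == "D":
                cp.del_depth[p : p + n] += 1
                cp.col_depth[p : p + n] += 1
                cp.mapq_sum[p : p + n] += r.mapq
                if last_m_ref is not None:
                    anchor = last_m_ref + 1
                    cp.del_support.setdefault(anchor, Counter())[n] += 1
                p += n
            elif op == "S":
                q += n
    return Pileup(contigs=out, min_mapq=min_mapq, min_bq=min_bq)
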
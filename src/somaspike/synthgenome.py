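"""Synthetic reference genome, germline background, and pre-aligned normal reads.

The simulator stands in for a real matched-normal alignment: reads are emitted
already placed at their true origin with simple CIGARs, so the pipeline is
deterministic and needs no aligner. Germline variants are applied per fragment
(het sites carried with probability 1/2, hom with probability 1), which gives
the expected allele fractions without modelling linkage between sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from somaspike.edits import apply_variant
from somaspike.errors import ParameterError
from somaspike.reads import AlignedRead
from somaspike.variants import VariantRecord, sort_records

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}

#: Phred score assigned to bases read correctly.
BASELINE_QUAL = 37
#: Range of Phred scores assigned to bases hit by a sequencing error.
ERROR_QUAL_RANGE = (10, 30)


@dataclass
class Reference:
    """A small in-memory genome: list of (name, uppercase ACGT sequence)."""

    contigs: List[tuple]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs:
            if not seq:
                raise ValueError(f"contig {name} has empty sequence")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.contigs]

    @property
    def lengths(self) -> Dict[str, int]:
        return {n: len(s) for n, s in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequence(self, name: str) -> str:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(f"unknown contig {name!r}")

    def base(self, name: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.sequence(name)[pos - 1]

    def slice(self, name: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self.sequence(name)[start - 1 : end]


@dataclass
class GermlineSet:
    """Germline variants with het/hom genotypes; positions sorted per contig."""

    records: List[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sort_records(self.records)
        seen = set()
        for r in self.records:
            if r.genotype not in ("het", "hom"):
                raise ValueError(f"germline record at {r.contig}:{r.pos} lacks genotype")
            if (r.contig, r.pos) in seen:
                raise ValueError(f"duplicate germline position {r.contig}:{r.pos}")
            seen.add((r.contig, r.pos))

    def __len__(self) -> int:
        return len(self.records)

    def on_contig(self, name: str) -> List[VariantRecord]:
        return [r for r in self.records if r.contig == name]


def make_reference(n_contigs: int, contig_length: int, gc_fraction: float, seed: int) -> Reference:
    """I.i.d. random genome with P(G) + P(C) = ``gc_fraction``."""
    if n_contigs < 1:
        raise ParameterError("n_contigs must be >= 1")
    if contig_length < 1000:
        raise ParameterError("contig_length must be >= 1000")
    if not 0 < gc_fraction < 1:
        raise ParameterError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    contigs = []
    for i in range(n_contigs):
        codes = rng.choice(4, size=contig_length, p=p)
        contigs.append((f"chr{i + 1}", _BASES[codes].tobytes().decode()))
    return Reference(contigs)


def _random_alt(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[rng.integers(len(choices))]


def place_germline_variants(
    ref: Reference,
    snv_rate: float,
    indel_rate: float,
    seed: int,
    het_fraction: float = 2 / 3,
    indel_len_range: tuple = (1, 10),
) -> GermlineSet:
    """Drop germline SNVs/INDELs i.i.d. per base at the given rates.

    Affected spans (padded by 1 bp) never overlap; later draws conflicting
    with earlier ones are discarded, a negligible loss at the permitted rates.
    Genotypes are het:hom 2:1 by default.
    """
    for name, rate in (("snv_rate", snv_rate), ("indel_rate", indel_rate)):
        if not 0 <= rate <= 0.01:
            raise ParameterError(f"{name} must be in [0, 0.01], got {rate}")
    rng = np.random.default_rng(seed)
    lo, hi = indel_len_range
    records: List[VariantRecord] = []
    for contig, seq in ref.contigs:
        L = len(seq)
        accepted: List[VariantRecord] = []
        blocked: set = set()

        def try_add(rec: VariantRecord) -> None:
            lo_, hi_ = rec.span()
            span = range(lo_ - 1, hi_ + 2)
            if any(p in blocked for p in span):
                return
            accepted.append(rec)
            blocked.update(span)

        # INDELs first (longer spans), then SNVs
        n_indel = rng.binomial(L, indel_rate)
        for pos in np.sort(rng.choice(L, size=n_indel, replace=False)) + 1:
            pos = int(pos)
            genotype = "het" if rng.random() < het_fraction else "hom"
            length = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5 and pos + length <= L:  # deletion
                refa = seq[pos - 1 : pos + length]
                alta = seq[pos - 1]
            else:  # insertion
                refa = seq[pos - 1]
                alta = refa + "".join(
                    "ACGT"[rng.integers(4)] for _ in range(length)
                )
            try_add(VariantRecord(contig, pos, refa, alta, genotype=genotype))
        n_snv = rng.binomial(L, snv_rate)
        for pos in np.sort(rng.choice(L, size=n_snv, replace=False)) + 1:
            pos = int(pos)
            genotype = "het" if rng.random() < het_fraction else "hom"
            base = seq[pos - 1]
            try_add(VariantRecord(contig, pos, base, _random_alt(rng, base), genotype=genotype))
        records.extend(accepted)
    return GermlineSet(records)


def simulate_normal_reads(
    ref: Reference,
    germline: Optional[GermlineSet],
    coverage: float,
    read_len: int = 100,
    frag_len_mean: int = 300,
    frag_len_sd: Optional[float] = None,
    error_rate: float = 0.001,
    mapq: int = 60,
    seed: int = 0,
    origin: str = "normal",
    id_prefix: str = "frag",
) -> List[AlignedRead]:
    """Paired-end reads at their true origin, with i.i.d. base errors.

    Fragment lengths are Normal(mean, sd) truncated to [read_len, contig];
    both mates carry each germline variant their fragment was drawn to carry.
    Returns reads sorted by (contig, position).
    """
    if coverage <= 0:
        raise ParameterError("coverage must be positive")
    if read_len >= frag_len_mean:
        raise ParameterError("read_len must be below frag_len_mean")
    if not 0 <= error_rate < 1:
        raise ParameterError("error_rate must be in [0, 1)")
    if frag_len_sd is None:
        frag_len_sd = 0.1 * frag_len_mean
    rng = np.random.default_rng(seed)
    germ = germline.records if germline is not None else []
    reads: List[AlignedRead] = []
    for contig, seq in ref.contigs:
        L = len(seq)
        n_frag = int(round(coverage * L / (2 * read_len)))
        if n_frag == 0:
            warnings.warn(f"coverage {coverage} draws zero fragments on {contig}")
            continue
        flen = np.clip(
            np.round(rng.normal(frag_len_mean, frag_len_sd, size=n_frag)),
            read_len,
            L,
        ).astype(np.int64)
        starts = (rng.random(n_frag) * (L - flen + 1)).astype(np.int64) + 1  # 1-based

        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        contig_reads: List[AlignedRead] = []
        for mate, (r_start, strand) in enumerate(
            [(starts, "+"), (starts + flen - read_len, "-")], start=1
        ):
            idx = r_start[:, None] - 1 + np.arange(read_len)
            mat = arr[idx]
            quals = np.full(mat.shape, BASELINE_QUAL, dtype=np.uint8)
            if error_rate > 0:
                err = rng.random(mat.shape) < error_rate
                n_err = int(err.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    codes = np.array([_CODE[b] for b in mat[err]], dtype=np.uint8)
                    mat[err] = _BASES[(codes + shift) % 4]
                    quals[err] = rng.integers(
                        ERROR_QUAL_RANGE[0], ERROR_QUAL_RANGE[1] + 1, size=n_err
                    )
            cigar = f"{read_len}M"
            for i in range(n_frag):
                fid = f"{id_prefix}_{contig}_{i}"
                contig_reads.append(
                    AlignedRead(
                        read_id=f"{fid}/{mate}",
                        contig=contig,
                        pos=int(r_start[i]),
                        cigar=cigar,
                        seq=mat[i].tobytes().decode(),
                        quals=quals[i],
                        mapq=mapq,
                        strand=strand,
                        fragment_id=fid,
                        origin=origin,
                    )
                )
        # apply germline variants fragment-wise
        contig_germ = [g for g in germ if g.contig == contig]
        if contig_germ:
            frag_end = starts + flen - 1
            by_frag: Dict[int, List[VariantRecord]] = {}
            for g in contig_germ:
                p_carry = 0.5 if g.genotype == "het" else 1.0
                lo_, hi_ = g.span()
                overlapping = np.nonzero((starts <= hi_) & (frag_end >= lo_))[0]
                carried = overlapping[rng.random(len(overlapping)) < p_carry]
                for i in carried:
                    by_frag.setdefault(int(i), []).append(g)
            if by_frag:
                index: Dict[str, List[int]] = {}
                for j, r in enumerate(contig_reads):
                    index.setdefault(r.fragment_id, []).append(j)
                for i, variants in by_frag.items():
                    fid = f"{id_prefix}_{contig}_{i}"
                    for j in index[fid]:
                        r = contig_reads[j]
                        for g in variants:
                            r = apply_variant(r, g)
                        contig_reads[j] = r
        reads.extend(contig_reads)
    reads.sort(key=lambda r: (r.contig, r.pos, r.read_id))
    return reads
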
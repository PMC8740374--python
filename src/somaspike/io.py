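"""File-format boundaries (FASTA/SAM/VCF/BED), run configuration, seeds.

Coordinate conventions are converted exactly once, here: SAM and VCF are
1-based inclusive (matching the in-memory types), BED is 0-based half-open
(matching :class:`RegionSet`).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from somaspike.errors import FormatError
from somaspike.reads import AlignedRead, group_fragments
from somaspike.regions import RegionSet
from somaspike.synthgenome import Reference
from somaspike.variants import VariantRecord


def derive_seed(seed: int, *stages: str) -> int:
    """Stable per-stage seed: hash the base seed with the stage names.

    Adding a stage never perturbs another stage's stream; results fit in 31
    bits so they can be passed anywhere a small seed is expected.
    """
    h = hashlib.sha256(f"{seed}:{'/'.join(stages)}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------- FASTA

def write_fasta(ref: Reference, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.contigs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Reference:
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return Reference(contigs)


# ---------------------------------------------------------------- SAM

def _sam_header(ref: Reference) -> Dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref.lengths.items()],
    }


def write_sam(reads: Sequence[AlignedRead], ref: Reference, path) -> None:
    """Coordinate-sorted SAM with proper pair flags and mate coordinates."""
    header = pysam.AlignmentHeader.from_dict(_sam_header(ref))
    tid = {name: i for i, name in enumerate(ref.names)}
    mates: Dict[str, List[AlignedRead]] = group_fragments(reads)
    ordered = sorted(reads, key=lambda r: (tid[r.contig], r.pos, r.read_id))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(header)
            a.query_name = r.fragment_id
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            a.reference_id = tid[r.contig]
            a.reference_start = r.pos - 1
            a.cigarstring = r.cigar
            a.mapping_quality = r.mapq
            flag = 0x1
            mate = [m for m in mates[r.fragment_id] if m.read_id != r.read_id]
            if r.strand == "-":
                flag |= 0x10
            if r.read_id.endswith("/2"):
                flag |= 0x80
            else:
                flag |= 0x40
            if mate:
                m = mate[0]
                flag |= 0x2
                if m.strand == "-":
                    flag |= 0x20
                a.next_reference_id = tid[m.contig]
                a.next_reference_start = m.pos - 1
                lo = min(r.pos, m.pos)
                hi = max(r.reference_end, m.reference_end)
                tlen = hi - lo + 1
                a.template_length = tlen if r.pos <= m.pos else -tlen
            else:
                flag |= 0x8
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.flag = flag
            a.set_tag("XO", r.origin)
            out.write(a)


def read_sam(path) -> List[AlignedRead]:
    reads: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as f:
        it = iter(f)
        while True:
            try:
                a = next(it)
            except StopIteration:
                break
            except OSError as e:
                last = reads[-1].read_id if reads else "<none>"
                raise FormatError(
                    f"malformed SAM record in {path} (after read {last}): {e}"
                ) from e
            if a.is_unmapped:
                continue
            mate = "2" if a.is_read2 else "1"
            try:
                reads.append(
                    AlignedRead(
                        read_id=f"{a.query_name}/{mate}",
                        contig=a.reference_name,
                        pos=a.reference_start + 1,
                        cigar=a.cigarstring,
                        seq=a.query_sequence,
                        quals=np.array(a.query_qualities, dtype=np.uint8),
                        mapq=a.mapping_quality,
                        strand="-" if a.is_reverse else "+",
                        fragment_id=a.query_name,
                        origin=a.get_tag("XO") if a.has_tag("XO") else "normal",
                    )
                )
            except ValueError as e:
                raise FormatError(f"malformed read {a.query_name!r}: {e}") from e
    return reads


# ---------------------------------------------------------------- VCF

_INFO_LINES = [
    '##INFO=<ID=TIER,Number=1,Type=String,Description="Confidence tier">',
    '##INFO=<ID=TVAF,Number=1,Type=Float,Description="Target/observed variant allele frequency">',
    '##INFO=<ID=GENO,Number=1,Type=String,Description="Germline genotype (het/hom)">',
    '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">',
]


def write_vcf(records: Sequence[VariantRecord], ref: Reference, path) -> None:
    header = pysam.VariantHeader()
    for line in _INFO_LINES:
        header.add_line(line)
    for name, length in ref.lengths.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = {name: i for i, name in enumerate(ref.names)}
        for r in sorted(records, key=lambda x: (order.get(x.contig, 99), x.pos)):
            rec = out.new_record(
                contig=r.contig, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            if r.tier is not None:
                rec.info["TIER"] = r.tier
            if r.target_vaf is not None:
                rec.info["TVAF"] = float(r.target_vaf)
            if r.genotype is not None:
                rec.info["GENO"] = r.genotype
            rec.info["VT"] = r.vtype
            out.write(rec)


def read_vcf(path, ref: Optional[Reference] = None) -> List[VariantRecord]:
    out: List[VariantRecord] = []
    known = set(ref.names) if ref is not None else None
    unknown = set()
    with pysam.VariantFile(str(path)) as f:
        for rec in f:
            if known is not None and rec.contig not in known:
                unknown.add(rec.contig)
                continue
            for alt in rec.alts or ():
                out.append(
                    VariantRecord(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        tier=rec.info.get("TIER"),
                        target_vaf=(
                            float(rec.info["TVAF"]) if "TVAF" in rec.info else None
                        ),
                        genotype=rec.info.get("GENO"),
                    )
                )
    if unknown:
        raise FormatError(
            f"VCF {path} references contigs absent from the reference: "
            + ", ".join(sorted(unknown))
        )
    return out


# ---------------------------------------------------------------- BED

def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as f:
        for contig, start, end in regions.intervals:
            f.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path, ref: Optional[Reference] = None, name: str = "") -> RegionSet:
    intervals = []
    unknown = set()
    known = set(ref.names) if ref is not None else None
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line needs >= 3 fields")
            contig, start, end = parts[0], parts[1], parts[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from e
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            if known is not None and contig not in known:
                unknown.add(contig)
                continue
            intervals.append((contig, start_i, end_i))
    if unknown:
        raise FormatError(
            f"BED {path} references contigs absent from the reference: "
            + ", ".join(sorted(unknown))
        )
    return RegionSet(intervals, name=name or Path(path).stem)


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Everything an end-to-end experiment needs, serializable to YAML."""

    seed: int = 1
    genome_length: int = 200_000
    n_contigs: int = 1
    gc_fraction: float = 0.45
    germline_snv_rate: float = 1e-3
    germline_indel_rate: float = 1e-4
    coverage: float = 80.0
    read_len: int = 100
    frag_len_mean: int = 300
    error_rate: float = 0.002
    n_snv: Optional[int] = None  # default: density-scaled from genome length
    n_indel: Optional[int] = None
    vaf_alpha: float = 2.0
    vaf_beta: float = 5.0
    real_vaf_alpha: float = 2.0
    real_vaf_beta: float = 18.0
    ffpe_damage_rate: float = 0.0
    block_size: int = 10_000
    train_fraction: float = 0.5
    spike_fraction: float = 0.10
    call_threshold: float = 0.5
    strategies: List[str] = field(
        default_factory=lambda: ["spike_only", "gt_real", "combined"]
    )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
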
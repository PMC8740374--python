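"""Variant records shared by the simulator, truth sets and the evaluator.

Coordinates are 1-based inclusive (VCF convention). INDELs are anchored at
the base preceding the event, so ``ref`` and ``alt`` always share their first
base for insertions and deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

SNV = "SNV"
INS = "INS"
DEL = "DEL"

TIER_HIGHCONF = "HighConf"
TIER_MEDCONF = "MedConf"
TIER_LOWCONF = "LowConf"
TIER_UNCLASSIFIED = "Unclassified"

#: Tiers that constitute the reference (truth) call set.
TRUTH_TIERS = frozenset({TIER_HIGHCONF, TIER_MEDCONF})


@dataclass(frozen=True)
class VariantRecord:
    """A single SNV or INDEL.

    Parameters
    ----------
    contig, pos : locus, 1-based.
    ref, alt : alleles in VCF style (anchored for INDELs).
    target_vaf : designed variant allele frequency for spike-ins; ``None``
        for germline records and plain calls.
    tier : confidence tier (HighConf/MedConf/LowConf/Unclassified) or ``None``.
    genotype : ``"het"``/``"hom"`` for germline records, else ``None``.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    target_vaf: Optional[float] = None
    tier: Optional[str] = None
    genotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        if len(self.alt) > len(self.ref):
            return INS
        return DEL

    @property
    def size(self) -> int:
        """Signed INDEL size: insertions positive, deletions negative, SNVs 0."""
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> tuple:
        """Exact-match identity: (contig, pos, ref, alt)."""
        return (self.contig, self.pos, self.ref, self.alt)

    def span(self) -> tuple:
        """1-based inclusive reference interval affected by this variant."""
        return (self.pos, self.pos + max(len(self.ref) - 1, 0))

    def with_(self, **kw) -> "VariantRecord":
        return replace(self, **kw)


def sort_records(records: Iterable[VariantRecord]) -> list:
    return sorted(records, key=lambda r: (r.contig, r.pos, r.ref, r.alt))


def spans_conflict(a: VariantRecord, b: VariantRecord, pad: int = 1) -> bool:
    """True when the affected spans of two records, padded by ``pad`` bp, touch."""
    if a.contig != b.contig:
        return False
    a0, a1 = a.span()
    b0, b1 = b.span()
    return a0 - pad <= b1 and b0 - pad <= a1
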
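"""In-silico tumor construction: spike somatic variants into normal reads.

Somatic SNVs/INDELs are written directly into the reads of a normal alignment
at target variant allele frequencies drawn from a Beta distribution
(Beta(2, 5) by default; Beta(2, 18) emulates a low-purity tumor). Selection is
fragment-level: each fragment overlapping a site carries the variant with
probability equal to the site's target VAF, and both mates of a carrier are
edited, as a real mutated molecule would read out on both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from somaspike.edits import apply_variant
from somaspike.errors import CapacityError, ParameterError
from somaspike.reads import AlignedRead, group_fragments
from somaspike.synthgenome import GermlineSet, Reference
from somaspike.variants import TIER_HIGHCONF, VariantRecord, sort_records

#: Default spike density per megabase, preserving the ~4.2:1 SNV:INDEL ratio
#: of the full-scale construction (~92K SNVs and ~22K INDELs genome-wide).
DEFAULT_SNV_PER_MB = 400
DEFAULT_INDEL_PER_MB = 95

#: Minimum gap (bp) between the padded affected spans of two spiked sites.
SITE_SPACING = 2


@dataclass(frozen=True)
class VafModel:
    """Beta distribution over target variant allele frequencies."""

    alpha: float = 2.0
    beta: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("Beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class SpikePlan:
    """Somatic sites to spike, each with a target VAF; spans pairwise disjoint."""

    sites: List[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = sort_records(self.sites)
        for s in self.sites:
            if s.target_vaf is None or not 0 < s.target_vaf <= 1:
                raise ValueError(f"site {s.contig}:{s.pos} needs target_vaf in (0, 1]")

    def __len__(self) -> int:
        return len(self.sites)


def draw_vafs(n: int, model: VafModel, seed: int) -> np.ndarray:
    """Draw ``n`` target VAFs from the model's Beta distribution."""
    if n < 0:
        raise ParameterError("n must be non-negative")
    rng = np.random.default_rng(seed)
    v = rng.beta(model.alpha, model.beta, size=n)
    # keep strictly inside (0, 1) so every VAF is a usable Bernoulli rate
    return np.clip(v, 1e-9, 1 - 1e-9)


def fit_beta_moments(values) -> Tuple[float, float]:
    """Method-of-moments Beta shape estimates from observed VAFs.

    With sample mean m and variance v: k = m(1-m)/v - 1, alpha = m*k,
    beta = (1-m)*k.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ParameterError("need >= 2 values to fit a Beta distribution")
    m = x.mean()
    v = x.var(ddof=1)
    if v <= 0 or not 0 < m < 1:
        raise ParameterError("degenerate sample: cannot fit Beta moments")
    k = m * (1 - m) / v - 1
    if k <= 0:
        raise ParameterError("sample variance too large for a Beta fit")
    return m * k, (1 - m) * k


def select_spike_sites(
    ref: Reference,
    germline: Optional[GermlineSet],
    n_snv: int,
    n_indel: int,
    indel_len_range: Tuple[int, int] = (1, 10),
    model: VafModel = VafModel(),
    seed: int = 0,
    snv_signature: Optional[Tuple[str, str]] = None,
) -> SpikePlan:
    """Choose somatic sites avoiding germline spans and each other.

    ``snv_signature``, e.g. ``("C", "T")``, restricts SNVs to a mutational
    context: substitutions are placed only at the given reference base (or
    its complement, with the complementary alt), emulating the skewed
    substitution spectra of real tumors; ``None`` draws alts uniformly.

    Raises :class:`CapacityError` naming the shortfall when the genome cannot
    host the requested counts at the required spacing.
    """
    if n_snv < 0 or n_indel < 0:
        raise ParameterError("site counts must be non-negative")
    rng = np.random.default_rng(seed)
    blocked: Dict[str, set] = {name: set() for name in ref.names}
    if germline is not None:
        for g in germline.records:
            lo, hi = g.span()
            blocked[g.contig].update(range(lo - SITE_SPACING, hi + SITE_SPACING + 1))

    names = ref.names
    lengths = ref.lengths
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    lo_len, hi_len = indel_len_range

    def place(kind: str) -> Optional[VariantRecord]:
        contig = names[rng.choice(len(names), p=weights)]
        seq = ref.sequence(contig)
        L = lengths[contig]
        pos = int(rng.integers(1, L + 1))
        if kind == "SNV":
            refa = seq[pos - 1]
            if snv_signature is not None:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                want_ref, want_alt = snv_signature
                if refa == want_ref:
                    alta = want_alt
                elif refa == comp[want_ref]:
                    alta = comp[want_alt]
                else:
                    return None
            else:
                alts = [b for b in "ACGT" if b != refa]
                alta = alts[rng.integers(3)]
        else:
            length = int(rng.integers(lo_len, hi_len + 1))
            if rng.random() < 0.5 and pos + length <= L:
                refa = seq[pos - 1 : pos + length]
                alta = seq[pos - 1]
            else:
                refa = seq[pos - 1]
                alta = refa + "".join("ACGT"[rng.integers(4)] for _ in range(length))
        rec = VariantRecord(contig, pos, refa, alta, tier=TIER_HIGHCONF)
        lo, hi = rec.span()
        span = range(lo - SITE_SPACING, hi + SITE_SPACING + 1)
        if any(p in blocked[contig] for p in span):
            return None
        blocked[contig].update(span)
        return rec

    sites: List[VariantRecord] = []
    for kind, want in (("INDEL", n_indel), ("SNV", n_snv)):
        placed = 0
        attempts = 0
        max_attempts = 200 * max(want, 1)
        while placed < want:
            if attempts >= max_attempts:
                raise CapacityError(
                    f"could only place {placed}/{want} {kind} sites on a "
                    f"{ref.total_length} bp genome at spacing {SITE_SPACING}"
                )
            attempts += 1
            rec = place(kind)
            if rec is not None:
                sites.append(rec)
                placed += 1
    vafs = draw_vafs(len(sites), model, seed=int(rng.integers(2**31)))
    sites = [s.with_(target_vaf=float(v)) for s, v in zip(sites, vafs)]
    return SpikePlan(sites)


def spike_mutations(
    normal_reads: List[AlignedRead],
    plan: SpikePlan,
    seed: int = 0,
) -> Tuple[List[AlignedRead], List[VariantRecord]]:
    """Edit reads so each plan site is carried at its target VAF.

    Fragment-level Bernoulli selection: every fragment overlapping a site is
    independently a carrier with probability ``target_vaf``; both mates of a
    carrier are edited where they cover the locus. Returns the edited reads
    (re-sorted, with ``origin`` retagged ``tumor``) and the truth records.
    Sites covered by no fragment are kept in the truth but warned about.
    """
    rng = np.random.default_rng(seed)
    reads = [r.copy(origin="tumor") for r in normal_reads]
    if not plan.sites:
        return reads, []

    frags = group_fragments(reads)
    frag_ids = list(frags)
    by_contig: Dict[str, List[int]] = {}
    starts = np.empty(len(frag_ids), dtype=np.int64)
    ends = np.empty(len(frag_ids), dtype=np.int64)
    for i, fid in enumerate(frag_ids):
        rs = frags[fid]
        starts[i] = min(r.pos for r in rs)
        ends[i] = max(r.reference_end for r in rs)
        by_contig.setdefault(rs[0].contig, []).append(i)
    contig_idx = {c: np.array(ix) for c, ix in by_contig.items()}

    edited: Dict[str, List[AlignedRead]] = {fid: frags[fid] for fid in frag_ids}
    truth: List[VariantRecord] = []
    uncovered: List[str] = []
    for site in plan.sites:
        truth.append(site)
        ix = contig_idx.get(site.contig)
        if ix is None:
            raise CapacityError(f"spike site on unknown contig {site.contig!r}")
        lo, hi = site.span()
        overlapping = ix[(starts[ix] <= hi) & (ends[ix] >= lo)]
        if len(overlapping) == 0:
            uncovered.append(f"{site.contig}:{site.pos}")
            continue
        carriers = overlapping[rng.random(len(overlapping)) < site.target_vaf]
        for i in carriers:
            fid = frag_ids[int(i)]
            edited[fid] = [apply_variant(r, site) for r in edited[fid]]
    if uncovered:
        warnings.warn(f"{len(uncovered)} spike sites had zero coverage: " + ", ".join(uncovered[:5]))
    out = [r for fid in frag_ids for r in edited[fid]]
    out.sort(key=lambda r: (r.contig, r.pos, r.read_id))
    return out, sort_records(truth)


def inject_ffpe_artifacts(
    reads: List[AlignedRead],
    damage_rate: float,
    seed: int = 0,
) -> Tuple[List[AlignedRead], List[Tuple[str, int, int]]]:
    """Formalin-like C>T deamination damage, applied per read.

    Each cytosine in each read's stored sequence independently flips to T with
    probability ``damage_rate``. Damage is single-stranded — mates and
    overlapping reads are hit independently — so artifact allele fractions
    stay low. Returns the damaged reads and a log of
    ``(read_id, query_offset, ref_pos)`` per artifact (``ref_pos`` -1 for
    inserted/clipped bases).
    """
    if not 0 <= damage_rate <= 0.05:
        raise ParameterError("damage_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    if damage_rate == 0:
        return list(reads), []
    out: List[AlignedRead] = []
    log: List[Tuple[str, int, int]] = []
    for r in reads:
        arr = np.frombuffer(r.seq.encode(), dtype=np.uint8)
        c_offsets = np.nonzero(arr == ord("C"))[0]
        if len(c_offsets) == 0:
            out.append(r)
            continue
        hit = c_offsets[rng.random(len(c_offsets)) < damage_rate]
        if len(hit) == 0:
            out.append(r)
            continue
        arr = arr.copy()
        arr[hit] = ord("T")
        damaged = r.copy(seq=arr.tobytes().decode())
        out.append(damaged)
        pairs = dict((q, rp) for q, rp in r.aligned_pairs() if q >= 0)
        for q in hit:
            log.append((r.read_id, int(q), pairs.get(int(q), -1)))
    return out, log
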
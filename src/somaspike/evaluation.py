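"""Scoring call sets against a tiered truth set.

A call is correct only if its normalized (contig, pos, ref, alt) exactly
matches a truth record (HighConf + MedConf tiers) inside the evaluation
regions. Private calls — calls absent from the truth set — are adjudicated
with the coverage/purity projection rule: for a replicate with mean coverage
C and tumor purity P, a private call with d tumor alt-supporting reads is a
false positive iff d >= 3CP/50 (its projected support at 50x and full purity
reaches the truth set's 3-read detection floor); otherwise its somatic
status cannot be ascertained and the call is excluded from every metric.
Blacklisted loci (known low-validation-rate low-confidence calls) are
likewise set aside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from somaspike.errors import ParameterError
from somaspike.regions import RegionSet
from somaspike.synthgenome import Reference
from somaspike.titration import ReplicateSpec
from somaspike.variants import SNV, TRUTH_TIERS, VariantRecord

STATUS_TP = "TP"
STATUS_FP = "FP"
STATUS_FN = "FN"
STATUS_EXCLUDED = "excluded"
STATUS_BLACKLISTED = "blacklisted"

#: Default VAF bin edges; the 5-20% range is where callers diverge most.
DEFAULT_VAF_EDGES = (0.05, 0.10, 0.20, 0.50, 1.0)


@dataclass
class Call:
    """A somatic call with the depth bookkeeping adjudication needs."""

    record: VariantRecord
    qual: float = 0.0
    alt_depth: int = 0  # d: tumor alt-supporting reads passing scan filters
    depth: int = 0
    somatic_prob: Optional[float] = None

    @property
    def key(self) -> tuple:
        return self.record.key

    @property
    def observed_vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0


@dataclass
class AdjudicatedCall:
    """Final status of one call or missed truth record."""

    record: VariantRecord  # the call for TP/FP/excluded, the truth record for FN
    status: str
    d: Optional[int] = None
    depth: Optional[int] = None
    spec: Optional[ReplicateSpec] = None
    truth: Optional[VariantRecord] = None  # matched truth record for TPs

    @property
    def vaf(self) -> Optional[float]:
        """Truth VAF for TP/FN; observed alt fraction for FP."""
        if self.status in (STATUS_TP, STATUS_FN):
            t = self.truth if self.truth is not None else self.record
            if t.target_vaf is not None:
                return t.target_vaf
        if self.d is not None and self.depth:
            return self.d / self.depth
        return None


@dataclass
class MetricBundle:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    excluded: int = 0
    blacklisted: int = 0

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    def as_dict(self) -> Dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "excluded": self.excluded,
            "blacklisted": self.blacklisted,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class EvalReport:
    overall: MetricBundle
    strata: Dict[str, MetricBundle] = field(default_factory=dict)

    def as_dict(self) -> Dict:
        return {
            "overall": self.overall.as_dict(),
            "strata": {k: v.as_dict() for k, v in self.strata.items()},
        }


def normalize_variants(
    records: Sequence[VariantRecord],
    ref: Reference,
    on_mismatch: str = "raise",
) -> List[VariantRecord]:
    """Left-align and parsimony-trim INDELs; SNVs pass through. Idempotent.

    Records whose ref allele disagrees with the reference sequence are
    flagged (``on_mismatch``: "raise" or "keep" — kept unchanged, never
    silently rewritten).
    """
    out: List[VariantRecord] = []
    for r in records:
        seq = ref.sequence(r.contig)
        if seq[r.pos - 1 : r.pos - 1 + len(r.ref)] != r.ref:
            msg = (
                f"record {r.contig}:{r.pos} {r.ref}>{r.alt} disagrees with the "
                "reference sequence"
            )
            if on_mismatch == "raise":
                raise ParameterError(msg)
            out.append(r)
            continue
        pos, ra, aa = r.pos, r.ref, r.alt
        if len(ra) == 1 and len(aa) == 1:
            out.append(r)
            continue
        while (len(ra) > 1 or len(aa) > 1) and ra[-1] == aa[-1]:
            tail = ra[-1]
            ra, aa = ra[:-1], aa[:-1]
            if not ra or not aa:
                if pos == 1:  # cannot extend left of the contig; undo
                    ra, aa = ra + tail, aa + tail
                    break
                pos -= 1
                prev = seq[pos - 1]
                ra, aa = prev + ra, prev + aa
        while len(ra) >= 2 and len(aa) >= 2 and ra[0] == aa[0]:
            ra, aa = ra[1:], aa[1:]
            pos += 1
        out.append(r.with_(pos=pos, ref=ra, alt=aa))
    return out


def match_calls(
    calls: Sequence[Union[Call, VariantRecord]],
    truth: Sequence[VariantRecord],
    eval_regions: Optional[RegionSet] = None,
) -> Tuple[List[AdjudicatedCall], List[Call]]:
    """Exact matching inside the evaluation regions.

    Returns ``(settled, provisional_fps)``: settled holds TPs and FNs;
    provisional FPs await adjudication. Truth is restricted to the
    HighConf/MedConf tiers; calls and truth outside the regions are ignored.
    """
    calls = [c if isinstance(c, Call) else Call(record=c) for c in calls]
    truth_in = [
        t
        for t in truth
        if (t.tier is None or t.tier in TRUTH_TIERS)
        and (eval_regions is None or eval_regions.contains(t.contig, t.pos))
    ]
    truth_by_key = {t.key: t for t in truth_in}
    settled: List[AdjudicatedCall] = []
    provisional: List[Call] = []
    matched = set()
    for c in calls:
        if eval_regions is not None and not eval_regions.contains(
            c.record.contig, c.record.pos
        ):
            continue
        t = truth_by_key.get(c.key)
        if t is not None:
            matched.add(t.key)
            settled.append(
                AdjudicatedCall(c.record, STATUS_TP, d=c.alt_depth, depth=c.depth, truth=t)
            )
        else:
            provisional.append(c)
    for t in truth_in:
        if t.key not in matched:
            settled.append(AdjudicatedCall(t, STATUS_FN, truth=t))
    return settled, provisional


def adjudication_threshold(spec: ReplicateSpec) -> float:
    """Minimum d for a private call to count as a false positive: 3CP/50."""
    return 3.0 * spec.mean_coverage * spec.tumor_purity / 50.0


def adjudicate_private_calls(
    provisional: Sequence[Call],
    blacklist: Sequence[VariantRecord],
    spec: ReplicateSpec,
) -> List[AdjudicatedCall]:
    """Blacklist, false-positive, or exclude each private call.

    FP iff d >= 3CP/50 (boundary inclusive); blacklisted calls are matched
    exactly; everything else is excluded as unascertainable at this
    coverage/purity.
    """
    if spec is None:
        raise ParameterError("adjudication requires a ReplicateSpec with C and P")
    bl_keys = {b.key for b in blacklist}
    thr = adjudication_threshold(spec)
    out: List[AdjudicatedCall] = []
    for c in provisional:
        if c.key in bl_keys:
            status = STATUS_BLACKLISTED
        elif c.alt_depth >= thr:
            status = STATUS_FP
        else:
            status = STATUS_EXCLUDED
        out.append(
            AdjudicatedCall(c.record, status, d=c.alt_depth, depth=c.depth, spec=spec)
        )
    return out


def evaluate_calls(
    calls: Sequence[Union[Call, VariantRecord]],
    truth: Sequence[VariantRecord],
    eval_regions: Optional[RegionSet],
    spec: ReplicateSpec,
    blacklist: Sequence[VariantRecord] = (),
) -> List[AdjudicatedCall]:
    """match -> adjudicate, in one step."""
    settled, provisional = match_calls(calls, truth, eval_regions)
    return settled + adjudicate_private_calls(provisional, blacklist, spec)


def _vtype_of(adj: AdjudicatedCall) -> str:
    return adj.record.vtype


def _bundle(adjudicated: Sequence[AdjudicatedCall]) -> MetricBundle:
    b = MetricBundle()
    for a in adjudicated:
        if a.status == STATUS_TP:
            b.tp += 1
        elif a.status == STATUS_FP:
            b.fp += 1
        elif a.status == STATUS_FN:
            b.fn += 1
        elif a.status == STATUS_EXCLUDED:
            b.excluded += 1
        elif a.status == STATUS_BLACKLISTED:
            b.blacklisted += 1
    return b


def compute_metrics(adjudicated: Sequence[AdjudicatedCall]) -> EvalReport:
    """Precision/recall/F1 overall and separately for SNVs and INDELs.

    Excluded and blacklisted calls contribute to no numerator or denominator;
    empty denominators yield ``None`` (undefined), never silent NaN.
    """
    overall = _bundle(adjudicated)
    strata = {
        SNV: _bundle([a for a in adjudicated if _vtype_of(a) == SNV]),
        "INDEL": _bundle([a for a in adjudicated if _vtype_of(a) != SNV]),
    }
    return EvalReport(overall=overall, strata=strata)


def stratify(
    adjudicated: Sequence[AdjudicatedCall],
    scheme: str,
    vaf_edges: Sequence[float] = DEFAULT_VAF_EDGES,
    region_beds: Optional[Dict[str, RegionSet]] = None,
) -> EvalReport:
    """Per-stratum metrics under one of three schemes.

    ``vaf_bins`` and ``indel_size`` partition the scorable calls (TP/FP/FN);
    ``region_bed`` does not — a call lands in every region set it overlaps,
    plus "outside" when it overlaps none.
    """
    scorable = [
        a for a in adjudicated if a.status in (STATUS_TP, STATUS_FP, STATUS_FN)
    ]
    strata: Dict[str, List[AdjudicatedCall]] = {}
    if scheme == "vaf_bins":
        edges = list(vaf_edges)
        names = [f"<{edges[0]:g}"] + [
            f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])
        ]
        names[-1] = f"[{edges[-2]:g},{edges[-1]:g}]"
        for a in scorable:
            v = a.vaf
            if v is None:
                v = 0.0
            if v < edges[0]:
                name = names[0]
            else:
                name = names[-1]
                for i in range(len(edges) - 1):
                    if edges[i] <= v < edges[i + 1]:
                        name = names[i + 1]
                        break
                if v >= edges[-1]:
                    name = names[-1]
            strata.setdefault(name, []).append(a)
    elif scheme == "indel_size":
        for a in scorable:
            size = a.record.size
            name = "SNV" if size == 0 else str(size)
            strata.setdefault(name, []).append(a)
    elif scheme == "region_bed":
        if not region_beds:
            raise ParameterError("region_bed stratification requires BED region sets")
        for a in scorable:
            hit = False
            for name, rs in region_beds.items():
                if rs.contains(a.record.contig, a.record.pos):
                    strata.setdefault(name, []).append(a)
                    hit = True
            if not hit:
                strata.setdefault("outside", []).append(a)
    else:
        raise ParameterError(f"unknown stratification scheme {scheme!r}")
    return EvalReport(
        overall=_bundle(adjudicated),
        strata={k: _bundle(v) for k, v in sorted(strata.items())},
    )


def private_fn_analysis(
    fn_sets_by_caller: Dict[str, Sequence[set]],
    caller_x: str,
    caller_y: str,
    recurrence_fraction: float = 11 / 21,
    truth: Sequence[VariantRecord] = (),
) -> Dict:
    """Recurrent private false negatives of X vs Y across replicates.

    A truth variant belongs to ``X_FN`` when it is a false negative for X in
    at least ``ceil(recurrence_fraction * R)`` of the R replicates. The
    private sets are ``X_FN - Y_FN`` and ``Y_FN - X_FN``; when ``truth``
    records are supplied, each private set also reports its VAF distribution.
    """
    for caller in (caller_x, caller_y):
        if caller not in fn_sets_by_caller:
            raise ParameterError(f"no results for caller {caller!r}")
    vaf_by_key = {t.key: t.target_vaf for t in truth}

    def recurrent(caller: str) -> set:
        sets = fn_sets_by_caller[caller]
        R = len(sets)
        if R < 2:
            raise ParameterError("private-FN analysis needs >= 2 replicates")
        need = math.ceil(recurrence_fraction * R)
        counts: Dict[tuple, int] = {}
        for s in sets:
            for k in s:
                counts[k] = counts.get(k, 0) + 1
        return {k for k, n in counts.items() if n >= need}

    x_fn = recurrent(caller_x)
    y_fn = recurrent(caller_y)
    x_private = x_fn - y_fn
    y_private = y_fn - x_fn

    def vafs(keys: set) -> List[float]:
        return sorted(
            vaf_by_key[k] for k in keys if vaf_by_key.get(k) is not None
        )

    return {
        "x_fn": x_fn,
        "y_fn": y_fn,
        "x_private": x_private,
        "y_private": y_private,
        "x_private_vafs": vafs(x_private),
        "y_private_vafs": vafs(y_private),
    }
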
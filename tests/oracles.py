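"""Independent brute-force reimplementations used as test oracles.

Everything here is deliberately naive — plain loops, dicts and sets — and
shares no code with the package's implementations.
"""

from collections import Counter


def brute_pileup_base_counts(reads, contig, pos, min_mapq, min_bq):
    """Base -> count at a 1-based position, walking each read's CIGAR."""
    counts = Counter()
    for r in reads:
        if r.contig != contig or r.mapq < min_mapq:
            continue
        q = 0
        ref = r.pos
        for n, op in _cigar_ops(r.cigar):
            if op == "M":
                for i in range(n):
                    if ref + i == pos and r.quals[q + i] >= min_bq:
                        counts[r.seq[q + i]] += 1
                q += n
                ref += n
            elif op in ("I", "S"):
                q += n
            elif op == "D":
                for i in range(n):
                    if ref + i == pos:
                        counts["-"] += 1
                ref += n
    return counts


def _cigar_ops(cigar):
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def brute_leftmost(seq, pos, ref, alt):
    """Leftmost anchored representation of a simple indel, by enumeration.

    Applies (pos, ref, alt) to the sequence, then scans positions left to
    right for the first anchored (pos', ref', alt') producing the same edited
    sequence.
    """
    edited = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    delta = len(alt) - len(ref)
    assert delta != 0, "SNVs have a single representation"
    for p in range(1, len(seq) + 1):
        if delta < 0:  # deletion
            rlen = 1 - delta
            if p - 1 + rlen > len(seq):
                continue
            r2 = seq[p - 1 : p - 1 + rlen]
            a2 = r2[0]
        else:  # insertion
            r2 = seq[p - 1 : p]
            a2 = edited[p - 1 : p + delta]
            if not a2 or a2[0] != r2:
                continue
        if seq[: p - 1] + a2 + seq[p - 1 + len(r2) :] == edited:
            return (p, r2, a2)
    return None


def brute_evaluate(calls, truth, spec, blacklist=(), region_test=None):
    """Set-arithmetic adjudication + metrics.

    calls: iterable of (key, d) where key = (contig, pos, ref, alt).
    truth: iterable of keys (already tier-filtered).
    Returns dict with integer counts and metrics (None when undefined).
    """
    in_region = region_test or (lambda key: True)
    truth_keys = {k for k in truth if in_region(k)}
    call_list = [(k, d) for k, d in calls if in_region(k)]
    call_keys = {k for k, _ in call_list}
    bl = set(blacklist)
    thr = 3.0 * spec.mean_coverage * spec.tumor_purity / 50.0
    tp = len(truth_keys & call_keys)
    fn = len(truth_keys - call_keys)
    fp = excluded = blacklisted = 0
    for k, d in call_list:
        if k in truth_keys:
            continue
        if k in bl:
            blacklisted += 1
        elif d >= thr:
            fp += 1
        else:
            excluded += 1
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and precision + recall > 0
        else None
    )
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "excluded": excluded,
        "blacklisted": blacklisted,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
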
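"""Local read editing for spike-in mutations and germline application.

Edits rewrite a read's sequence, qualities, CIGAR and (rarely) position so the
read carries a given variant, without re-alignment. Reference coordinates of
bases outside the edit are preserved, so edits at distinct loci commute and a
read carrying several variants can be built by applying them in any order.

Conventions for partial overlap:

* SNV — applied only where the read has an M-aligned base at the site.
* Insertion — applied only to reads whose alignment M-covers the anchor base;
  inserted bases get the anchor base's quality.
* Deletion — deleted bases fully inside the read are removed and replaced by
  a D operation. Where the deleted span runs off the read's 3' end, the
  covered tail is soft-clipped instead; where a read starts inside the
  deleted span, its covered head is soft-clipped and the mapped position
  advances past the deletion. A read that would lose every aligned base is
  left unedited.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from somaspike.reads import AlignedRead, cigar_str, parse_cigar
from somaspike.variants import INS, SNV, VariantRecord

# A column is (op, query_offset or -1, ref_pos or -1)
Column = Tuple[str, int, int]


def _columns(read: AlignedRead) -> List[Column]:
    cols: List[Column] = []
    q, r = 0, read.pos
    for n, op in parse_cigar(read.cigar):
        if op == "M":
            cols.extend(("M", q + i, r + i) for i in range(n))
            q += n
            r += n
        elif op in ("I", "S"):
            cols.extend((op, q + i, -1) for i in range(n))
            q += n
        elif op == "D":
            cols.extend(("D", -1, r + i) for i in range(n))
            r += n
    return cols


def _rebuild(read: AlignedRead, cols: List[Column], seq: str, quals: np.ndarray) -> Optional[AlignedRead]:
    """Re-emit a read from an edited column list over (seq, quals)."""
    # convert leading/trailing I to S; find first M for the mapped position
    first_m = next((i for i, c in enumerate(cols) if c[0] == "M"), None)
    last_m = next((i for i in range(len(cols) - 1, -1, -1) if cols[i][0] == "M"), None)
    if first_m is None:
        return None
    ops: List[Tuple[int, str]] = []
    new_seq: List[str] = []
    new_quals: List[int] = []
    pos = cols[first_m][2]
    for i, (op, q, r) in enumerate(cols):
        if op == "I" and not (first_m < i < last_m):
            op = "S"
        if op == "D" and not (first_m < i < last_m):
            continue  # D at a read end is meaningless
        ops.append((1, op))
        if op != "D":
            new_seq.append(seq[q])
            new_quals.append(int(quals[q]))
    return read.copy(
        pos=pos,
        cigar=cigar_str(ops),
        seq="".join(new_seq),
        quals=np.asarray(new_quals, dtype=np.uint8),
    )


def apply_snv(read: AlignedRead, pos: int, alt: str) -> AlignedRead:
    off = read.query_offset_at(pos)
    if off is None:
        return read
    return read.copy(seq=read.seq[:off] + alt + read.seq[off + 1 :])


def apply_insertion(read: AlignedRead, anchor: int, inserted: str) -> AlignedRead:
    cols = _columns(read)
    idx = next((i for i, c in enumerate(cols) if c[0] == "M" and c[2] == anchor), None)
    if idx is None:
        return read
    off = cols[idx][1]
    seq = read.seq[: off + 1] + inserted + read.seq[off + 1 :]
    quals = np.concatenate(
        [read.quals[: off + 1], np.full(len(inserted), read.quals[off], dtype=np.uint8), read.quals[off + 1 :]]
    )
    k = len(inserted)
    shifted = [(op, q + k if q > off else q, r) for op, q, r in cols]
    new_cols = (
        shifted[: idx + 1]
        + [("I", off + 1 + i, -1) for i in range(k)]
        + shifted[idx + 1 :]
    )
    out = _rebuild(read, new_cols, seq, quals)
    return out if out is not None else read


def apply_deletion(read: AlignedRead, anchor: int, del_len: int) -> AlignedRead:
    span = range(anchor + 1, anchor + del_len + 1)
    cols = _columns(read)
    covers_anchor = any(c[0] == "M" and c[2] == anchor for c in cols)
    read_end = read.reference_end
    new_cols: List[Column] = []
    for op, q, r in cols:
        if op == "M" and span.start <= r < span.stop:
            if not covers_anchor:
                new_cols.append(("S", q, -1))  # head inside the deleted span
            elif span.stop - 1 > read_end:
                new_cols.append(("S", q, -1))  # deletion runs off the 3' end
            else:
                new_cols.append(("D", -1, r))
        else:
            new_cols.append((op, q, r))
    if covers_anchor and span.stop - 1 <= read_end:
        # D columns replace removed query bases: drop those bases from seq
        keep = [c[1] for c in new_cols if c[0] != "D"]
        seq = "".join(read.seq[q] for q in keep)
        quals = read.quals[keep]
        remap = {q: i for i, q in enumerate(keep)}
        new_cols = [(op, remap.get(q, -1), r) for op, q, r in new_cols]
        out = _rebuild(read, new_cols, seq, quals)
    else:
        out = _rebuild(read, new_cols, read.seq, read.quals)
    return out if out is not None else read


def apply_variant(read: AlignedRead, variant: VariantRecord) -> AlignedRead:
    """Apply one variant to one read; a no-op where the read misses the locus."""
    if read.contig != variant.contig:
        return read
    vt = variant.vtype
    if vt == SNV:
        return apply_snv(read, variant.pos, variant.alt)
    if vt == INS:
        return apply_insertion(read, variant.pos, variant.alt[1:])
    return apply_deletion(read, variant.pos, len(variant.ref) - 1)
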
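"""Candidate-site scanning, pileup feature encoding, and truth labeling.

Scanning follows the alignment-scan thresholds used by learned somatic
callers: an SNV candidate needs an alternate base at fraction >= 0.03 with
>= 3 supporting reads among bases passing mapq >= 10 and base quality >= 15;
insertion/deletion candidates need supporting fraction >= 0.02. A cheap
minor-allele-fraction prefilter (scan_maf, 0.01) on unfiltered counts runs
before the quality-aware test.

Each candidate is encoded as a channels x window matrix centered on the site
(reference one-hot, tumor/normal base and gap counts, mean base/mapping
quality tracks, an edge mask, and derived non-reference count tracks), with
optional external-caller flags appended as constant channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from somaspike.errors import EncodingMismatchError, ParameterError
from somaspike.pileup import BASE_INDEX, Pileup, compute_pileup
from somaspike.reads import AlignedRead
from somaspike.regions import RegionSet
from somaspike.synthgenome import Reference
from somaspike.variants import DEL, INS, SNV, VariantRecord

LABEL_NONSOMATIC = "non-somatic"
LABEL_SNV = "somatic-SNV"
LABEL_INDEL = "somatic-INDEL"

#: Base feature-matrix layout identifier; ensemble channels extend it.
ENCODING_BASE = "pileup-v1"

CHANNELS = [
    "ref_A", "ref_C", "ref_G", "ref_T",
    "tumor_A", "tumor_C", "tumor_G", "tumor_T", "tumor_gap",
    "normal_A", "normal_C", "normal_G", "normal_T", "normal_gap",
    "tumor_mean_bq", "tumor_mean_mapq", "normal_mean_bq", "normal_mean_mapq",
    "mask",
    "tumor_nonref", "normal_nonref",
]


@dataclass(frozen=True)
class ScanParams:
    """Alignment-scan thresholds; defaults are the standard preprocessing values."""

    scan_maf: float = 0.01
    min_mapq: int = 10
    snp_min_af: float = 0.03
    snp_min_bq: int = 15
    snp_min_ao: int = 3
    ins_min_af: float = 0.02
    del_min_af: float = 0.02
    max_dp: int = 100000
    window: int = 15

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ParameterError("window must be odd and positive")
        for name in ("scan_maf", "snp_min_af", "ins_min_af", "del_min_af"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be a proportion, got {v}")


@dataclass
class CandidateSite:
    contig: str
    pos: int
    ref: str
    alt: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    features: Optional[np.ndarray] = None
    ensemble_flags: Optional[Dict[str, bool]] = None
    label: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        return INS if len(self.alt) > len(self.ref) else DEL

    @property
    def tumor_af(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    def as_record(self, **kw) -> VariantRecord:
        return VariantRecord(self.contig, self.pos, self.ref, self.alt, **kw)


@dataclass
class CandidateStore:
    """Columnar candidate container: metadata frame + stacked feature tensor."""

    meta: pd.DataFrame
    features: np.ndarray  # (n, channels, window) float32
    encoding: str = ENCODING_BASE

    META_COLUMNS = [
        "contig", "pos", "ref", "alt",
        "tumor_depth", "tumor_alt", "normal_depth", "normal_alt", "label",
    ]

    def __post_init__(self) -> None:
        if len(self.meta) != len(self.features):
            raise ValueError("meta and features disagree on candidate count")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.meta)

    @classmethod
    def from_sites(cls, sites: Sequence[CandidateSite], encoding: str = ENCODING_BASE):
        if not sites:
            n_ch = len(CHANNELS)
            return cls(
                pd.DataFrame(columns=cls.META_COLUMNS),
                np.zeros((0, n_ch, 1), dtype=np.float32),
                encoding,
            )
        meta = pd.DataFrame(
            [
                (s.contig, s.pos, s.ref, s.alt, s.tumor_depth, s.tumor_alt,
                 s.normal_depth, s.normal_alt, s.label)
                for s in sites
            ],
            columns=cls.META_COLUMNS,
        )
        feats = np.stack([s.features for s in sites]).astype(np.float32)
        return cls(meta, feats, encoding)

    def subset(self, idx) -> "CandidateStore":
        idx = np.asarray(idx, dtype=np.int64)
        return CandidateStore(self.meta.iloc[idx], self.features[idx], self.encoding)

    def concat(self, other: "CandidateStore") -> "CandidateStore":
        if self.encoding != other.encoding:
            raise EncodingMismatchError(
                f"cannot combine stores with encodings {self.encoding!r} and {other.encoding!r}"
            )
        return CandidateStore(
            pd.concat([self.meta, other.meta], ignore_index=True),
            np.concatenate([self.features, other.features]),
            self.encoding,
        )

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.meta.to_csv(d / "candidates.tsv", sep="\t", index=False)
        np.save(d / "features.npy", self.features)
        (d / "schema.json").write_text(
            json.dumps(
                {
                    "encoding": self.encoding,
                    "n_candidates": len(self),
                    "feature_shape": list(self.features.shape[1:]),
                    "channels": CHANNELS if self.encoding == ENCODING_BASE else None,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, directory) -> "CandidateStore":
        d = Path(directory)
        schema = json.loads((d / "schema.json").read_text())
        meta = pd.read_csv(d / "candidates.tsv", sep="\t")
        if meta.empty:
            meta = pd.DataFrame(columns=cls.META_COLUMNS)
        feats = np.load(d / "features.npy")
        return cls(meta, feats, schema["encoding"])


def _check_sorted(reads: Sequence[AlignedRead], name: str) -> None:
    prev = None
    for r in reads:
        key = (r.contig, r.pos)
        if prev is not None and key < prev:
            raise ValueError(
                f"{name} reads are not coordinate-sorted at {r.contig}:{r.pos}; "
                "sort by (contig, position) first"
            )
        prev = key


def _thin_factor(depth: float, max_dp: int) -> float:
    return 1.0 if depth <= max_dp else max_dp / depth


def scan_candidates(
    tumor_reads: Sequence[AlignedRead],
    normal_reads: Sequence[AlignedRead],
    ref: Reference,
    params: ScanParams = ScanParams(),
    encode: bool = True,
    ensemble_flags: Optional[Dict[tuple, Dict[str, bool]]] = None,
    caller_names: Optional[List[str]] = None,
) -> List[CandidateSite]:
    """Scan a tumor-normal pair for candidate somatic sites.

    ``ensemble_flags`` optionally maps (contig, pos, ref, alt) to per-caller
    booleans; ``caller_names`` fixes the channel order when flags are used.
    """
    _check_sorted(tumor_reads, "tumor")
    _check_sorted(normal_reads, "normal")
    tumor_pu = compute_pileup(tumor_reads, ref, params.min_mapq, params.snp_min_bq)
    normal_pu = compute_pileup(normal_reads, ref, params.min_mapq, params.snp_min_bq)
    sites: List[CandidateSite] = []
    for contig, seq in ref.contigs:
        tp = tumor_pu[contig]
        np_ = normal_pu[contig]
        L = len(seq)
        ref_codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        ref_idx = np.zeros(L, dtype=np.int64)
        for b, i in BASE_INDEX.items():
            ref_idx[ref_codes == ord(b)] = i

        raw_tot = tp.raw_counts.sum(axis=0)
        raw_ref = tp.raw_counts[ref_idx, np.arange(L)]
        with np.errstate(invalid="ignore", divide="ignore"):
            raw_alt_frac = np.where(raw_tot > 0, (raw_tot - raw_ref) / np.maximum(raw_tot, 1), 0.0)
        prefilter = np.nonzero(raw_alt_frac >= params.scan_maf)[0]

        filt_tot = tp.base_counts.sum(axis=0)
        for p0 in prefilter:
            depth = int(filt_tot[p0])
            if depth == 0:
                continue
            f = _thin_factor(int(tp.col_depth[p0]), params.max_dp)
            ref_i = ref_idx[p0]
            for b_i in range(4):
                if b_i == ref_i:
                    continue
                count = int(round(tp.base_counts[b_i, p0] * f))
                eff_depth = max(int(round(depth * f)), 1)
                if count >= params.snp_min_ao and count / eff_depth >= params.snp_min_af:
                    alt = "ACGT"[b_i]
                    pos = int(p0) + 1
                    n_depth = int(np_.base_counts[:, p0].sum())
                    n_alt = int(np_.base_counts[b_i, p0])
                    sites.append(
                        CandidateSite(contig, pos, seq[p0], alt, eff_depth,
                                      count, n_depth, n_alt)
                    )
        # INDEL candidates from insertion/deletion support tables
        for anchor, counter in tp.ins_support.items():
            col = int(tp.col_depth[anchor - 1]) if anchor - 1 < L else 0
            if col == 0:
                continue
            f = _thin_factor(col, params.max_dp)
            for ins_seq, n in counter.items():
                count = int(round(n * f))
                eff = max(int(round(col * f)), 1)
                if count > 0 and count / eff >= params.ins_min_af:
                    refa = seq[anchor - 1]
                    n_sup = np_.ins_support.get(anchor, {}).get(ins_seq, 0)
                    n_col = int(np_.col_depth[anchor - 1])
                    sites.append(
                        CandidateSite(contig, anchor, refa, refa + ins_seq,
                                      eff, count, n_col, int(n_sup))
                    )
        for anchor, counter in tp.del_support.items():
            col = int(tp.col_depth[anchor - 1]) if anchor - 1 < L else 0
            if col == 0:
                continue
            f = _thin_factor(col, params.max_dp)
            for dlen, n in counter.items():
                count = int(round(n * f))
                eff = max(int(round(col * f)), 1)
                if count > 0 and count / eff >= params.del_min_af and anchor + dlen <= L:
                    refa = seq[anchor - 1 : anchor + dlen]
                    n_sup = np_.del_support.get(anchor, {}).get(dlen, 0)
                    n_col = int(np_.col_depth[anchor - 1])
                    sites.append(
                        CandidateSite(contig, anchor, refa, refa[0],
                                      eff, count, n_col, int(n_sup))
                    )
    sites.sort(key=lambda s: (s.contig, s.pos, s.ref, s.alt))
    if ensemble_flags is not None:
        names = caller_names or sorted({c for fl in ensemble_flags.values() for c in fl})
        for s in sites:
            fl = ensemble_flags.get(s.key, {})
            s.ensemble_flags = {c: bool(fl.get(c, False)) for c in names}
    if encode:
        for s in sites:
            s.features = _encode_from_pileups(s, tumor_pu, normal_pu, ref, params)
    return sites


def encoding_version(caller_names: Optional[Sequence[str]] = None) -> str:
    if caller_names:
        return f"{ENCODING_BASE}+ens{len(caller_names)}"
    return ENCODING_BASE


def _encode_from_pileups(
    site: CandidateSite,
    tumor_pu: Pileup,
    normal_pu: Pileup,
    ref: Reference,
    params: ScanParams,
) -> np.ndarray:
    w = params.window
    half = w // 2
    seq = ref.sequence(site.contig)
    L = len(seq)
    tp = tumor_pu[site.contig]
    np_ = normal_pu[site.contig]
    mat = np.zeros((len(CHANNELS), w), dtype=np.float32)
    lo = site.pos - 1 - half  # 0-based window start, may underflow
    cols = np.arange(lo, lo + w)
    valid = (cols >= 0) & (cols < L)
    vc = cols[valid]
    vi = np.nonzero(valid)[0]
    for j, p0 in zip(vi, vc):
        mat[BASE_INDEX[seq[p0]], j] = 1.0
    mat[4:8, vi] = tp.base_counts[:, vc]
    mat[8, vi] = tp.del_depth[vc]
    mat[9:13, vi] = np_.base_counts[:, vc]
    mat[13, vi] = np_.del_depth[vc]
    mat[14, vi] = tp.mean_bq()[vc]
    mat[15, vi] = tp.mean_mapq()[vc]
    mat[16, vi] = np_.mean_bq()[vc]
    mat[17, vi] = np_.mean_mapq()[vc]
    mat[18, vi] = 1.0
    ref_rows = np.array([BASE_INDEX[seq[p0]] for p0 in vc])
    mat[19, vi] = tp.base_counts[:, vc].sum(axis=0) - tp.base_counts[ref_rows, vc]
    mat[20, vi] = np_.base_counts[:, vc].sum(axis=0) - np_.base_counts[ref_rows, vc]
    if site.ensemble_flags:
        flags = np.array(
            [[1.0 if site.ensemble_flags[c] else 0.0] * w for c in sorted(site.ensemble_flags)],
            dtype=np.float32,
        )
        mat = np.concatenate([mat, flags])
    return mat


def encode_features(
    site: CandidateSite,
    tumor_reads: Sequence[AlignedRead],
    normal_reads: Sequence[AlignedRead],
    ref: Reference,
    params: ScanParams = ScanParams(),
) -> np.ndarray:
    """Encode one site directly from reads (convenience for small fixtures)."""
    tumor_pu = compute_pileup(tumor_reads, ref, params.min_mapq, params.snp_min_bq)
    normal_pu = compute_pileup(normal_reads, ref, params.min_mapq, params.snp_min_bq)
    return _encode_from_pileups(site, tumor_pu, normal_pu, ref, params)


def label_candidates(
    candidates: Sequence[CandidateSite],
    truth: Sequence[VariantRecord],
    regions: Optional[RegionSet] = None,
) -> List[CandidateSite]:
    """Attach class labels by exact match against (normalized) truth records.

    Candidates outside ``regions`` are dropped; a candidate matching a truth
    record's (contig, pos, ref, alt) is labeled somatic-SNV or somatic-INDEL,
    anything else non-somatic.
    """
    truth_by_key = {t.key: t for t in truth}
    out: List[CandidateSite] = []
    for c in candidates:
        if regions is not None and not regions.contains(c.contig, c.pos):
            continue
        t = truth_by_key.get(c.key)
        if t is None:
            c.label = LABEL_NONSOMATIC
        else:
            c.label = LABEL_SNV if t.vtype == SNV else LABEL_INDEL
        out.append(c)
    return out
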
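import numpy as np
import pytest

from somaspike.candidates import (
    LABEL_INDEL,
    LABEL_NONSOMATIC,
    LABEL_SNV,
    CandidateSite,
    CandidateStore,
    ScanParams,
    encode_features,
    label_candidates,
    scan_candidates,
)
from somaspike.errors import ParameterError
from somaspike.regions import RegionSet
from somaspike.synthgenome import Reference
from somaspike.variants import VariantRecord

from .conftest import make_read
from .oracles import brute_pileup_base_counts


@pytest.fixture(scope="module")
def flat_ref():
    # deterministic non-repetitive substrate for directed pileups
    rng = np.random.default_rng(99)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2_000))
    return Reference([("chr1", seq)])


def pileup_reads(ref, pos, n_ref, n_alt, alt="X", qual=37, mapq=60, alt_qual=None,
                 alt_mapq=None, read_len=50):
    """n_ref reference reads + n_alt alt-carrying reads over one locus."""
    seq = ref.sequence("chr1")
    start = pos - read_len // 2
    base = seq[start - 1 : start - 1 + read_len]
    if alt == "X":
        alt = "A" if seq[pos - 1] != "A" else "C"
    off = pos - start
    alt_seq = base[:off] + alt + base[off + 1 :]
    reads = []
    for i in range(n_ref):
        reads.append(make_read("chr1", start, base, qual=qual, mapq=mapq, fragment_id=f"r{i}"))
    for i in range(n_alt):
        reads.append(
            make_read(
                "chr1", start, alt_seq,
                qual=alt_qual if alt_qual is not None else qual,
                mapq=alt_mapq if alt_mapq is not None else mapq,
                fragment_id=f"a{i}",
            )
        )
    reads.sort(key=lambda r: (r.contig, r.pos))
    return reads, alt


NO_NORMAL_POS = 1_000


class TestScanThresholds:
    """Directed fixtures at each printed threshold boundary."""

    def scan(self, ref, reads):
        normal = [make_read("chr1", 950, ref.sequence("chr1")[949:1049], fragment_id="n0")]
        return scan_candidates(reads, normal, ref, ScanParams(), encode=False)

    def test_af_below_min_af_not_called(self, flat_ref):
        reads, _ = pileup_reads(flat_ref, NO_NORMAL_POS, 98, 2)  # 0.02 < 0.03
        assert self.scan(flat_ref, reads) == []

    def test_count_below_min_ao_not_called(self, flat_ref):
        reads, _ = pileup_reads(flat_ref, NO_NORMAL_POS, 58, 2)  # 0.033 but 2 < 3
        assert self.scan(flat_ref, reads) == []

    def test_af_and_count_at_boundary_called(self, flat_ref):
        reads, alt = pileup_reads(flat_ref, NO_NORMAL_POS, 97, 3)  # 0.03, 3
        sites = self.scan(flat_ref, reads)
        assert [s.alt for s in sites] == [alt]
        assert sites[0].pos == NO_NORMAL_POS

    def test_low_mapq_alt_reads_excluded(self, flat_ref):
        reads, _ = pileup_reads(flat_ref, NO_NORMAL_POS, 50, 5, alt_mapq=5)
        assert self.scan(flat_ref, reads) == []

    def test_low_bq_alt_bases_excluded(self, flat_ref):
        reads, _ = pileup_reads(flat_ref, NO_NORMAL_POS, 50, 5, alt_qual=14)
        assert self.scan(flat_ref, reads) == []

    def test_bq_at_boundary_included(self, flat_ref):
        reads, alt = pileup_reads(flat_ref, NO_NORMAL_POS, 50, 5, alt_qual=15)
        sites = self.scan(flat_ref, reads)
        assert [s.alt for s in sites] == [alt]

    def test_deletion_at_del_min_af_called(self, flat_ref):
        seq = flat_ref.sequence("chr1")
        start = 975
        base = seq[start - 1 : start - 1 + 50]
        del_reads = []
        for i in range(97):
            del_reads.append(make_read("chr1", start, base, fragment_id=f"r{i}"))
        # 3 reads with a 2-bp deletion after offset 25 (anchor pos 1000)
        del_seq = base[:26] + base[28:]
        for i in range(3):
            del_reads.append(
                make_read("chr1", start, del_seq, cigar="26M2D22M", fragment_id=f"d{i}")
            )
        del_reads.sort(key=lambda r: r.pos)
        sites = self.scan(flat_ref, del_reads)  # 3/100 = 0.03 >= 0.02
        assert len(sites) == 1
        s = sites[0]
        assert s.pos == 1000 and len(s.ref) == 3 and len(s.alt) == 1

    def test_insertion_below_ins_min_af_not_called(self, flat_ref):
        seq = flat_ref.sequence("chr1")
        start = 975
        base = seq[start - 1 : start - 1 + 50]
        reads = [make_read("chr1", start, base, fragment_id=f"r{i}") for i in range(99)]
        ins_seq = base[:26] + "GT" + base[26:]
        reads.append(make_read("chr1", start, ins_seq, cigar="26M2I24M", fragment_id="i0"))
        reads.sort(key=lambda r: r.pos)
        assert self.scan(flat_ref, reads) == []  # 1/100 = 0.01 < 0.02

    def test_unsorted_input_rejected(self, flat_ref):
        seq = flat_ref.sequence("chr1")
        reads = [
            make_read("chr1", 200, seq[199:249], fragment_id="u0"),
            make_read("chr1", 100, seq[99:149], fragment_id="u1"),
        ]
        with pytest.raises(ValueError, match="sort"):
            scan_candidates(reads, [], flat_ref, encode=False)

    def test_threshold_monotonicity(self, flat_ref):
        reads, _ = pileup_reads(flat_ref, NO_NORMAL_POS, 90, 10)
        normal = []
        base_count = len(
            scan_candidates(reads, normal, flat_ref, ScanParams(), encode=False)
        )
        for kw in (
            {"snp_min_af": 0.2},
            {"snp_min_ao": 20},
            {"min_mapq": 70},
            {"snp_min_bq": 45},
        ):
            stricter = len(
                scan_candidates(reads, normal, flat_ref, ScanParams(**kw), encode=False)
            )
            assert stricter <= base_count


class TestFeatureEncoding:
    def test_reference_one_hot_columns_sum_to_one(self, flat_ref):
        reads, alt = pileup_reads(flat_ref, NO_NORMAL_POS, 20, 10)
        site = CandidateSite("chr1", NO_NORMAL_POS, flat_ref.base("chr1", NO_NORMAL_POS), alt, 30, 10, 0, 0)
        mat = encode_features(site, reads, [], flat_ref)
        assert np.allclose(mat[0:4].sum(axis=0), 1.0)

    def test_variant_free_locus_concentrates_on_reference(self, flat_ref):
        reads, _ = pileup_reads(flat_ref, NO_NORMAL_POS, 30, 0)
        site = CandidateSite("chr1", NO_NORMAL_POS, flat_ref.base("chr1", NO_NORMAL_POS), "A", 30, 0, 0, 0)
        mat = encode_features(site, reads, [], flat_ref)
        ref_onehot = mat[0:4]
        tumor_counts = mat[4:8]
        # every column's counts sit on the reference base channel
        assert np.all(tumor_counts[ref_onehot == 0] == 0)

    def test_column_sums_match_brute_force_pileup(self, flat_ref):
        reads, alt = pileup_reads(flat_ref, NO_NORMAL_POS, 25, 7)
        site = CandidateSite("chr1", NO_NORMAL_POS, flat_ref.base("chr1", NO_NORMAL_POS), alt, 32, 7, 0, 0)
        params = ScanParams()
        mat = encode_features(site, reads, [], flat_ref, params)
        w = params.window
        half = w // 2
        for j in range(w):
            pos = NO_NORMAL_POS - half + j
            counts = brute_pileup_base_counts(
                reads, "chr1", pos, params.min_mapq, params.snp_min_bq
            )
            expect = sum(v for k, v in counts.items() if k != "-") + counts["-"]
            assert mat[4:9, j].sum() == expect

    def test_window_truncation_masked_at_contig_edge(self, flat_ref):
        reads = [make_read("chr1", 1, flat_ref.sequence("chr1")[:50], fragment_id="e0")]
        site = CandidateSite("chr1", 2, flat_ref.base("chr1", 2), "A", 1, 0, 0, 0)
        mat = encode_features(site, reads, [], flat_ref)
        w = ScanParams().window
        half = w // 2
        n_pad = half - 1  # positions before the contig start
        assert np.all(mat[18, :n_pad] == 0)
        assert np.all(mat[18, n_pad:] == 1)
        assert np.all(mat[:, :n_pad] == 0)

    def test_encoding_deterministic(self, flat_ref):
        reads, alt = pileup_reads(flat_ref, NO_NORMAL_POS, 12, 4)
        site = CandidateSite("chr1", NO_NORMAL_POS, flat_ref.base("chr1", NO_NORMAL_POS), alt, 16, 4, 0, 0)
        a = encode_features(site, reads, [], flat_ref)
        b = encode_features(site, reads, [], flat_ref)
        assert np.array_equal(a, b)


class TestLabeling:
    def truth(self):
        return [
            VariantRecord("chr1", 100, "A", "T", tier="HighConf"),
            VariantRecord("chr1", 200, "C", "CAT", tier="HighConf"),
        ]

    def site(self, pos, ref, alt):
        return CandidateSite("chr1", pos, ref, alt, 50, 10, 50, 0,
                             features=np.zeros((21, 15), dtype=np.float32))

    def test_exact_match_labels_by_type(self):
        labeled = label_candidates(
            [self.site(100, "A", "T"), self.site(200, "C", "CAT")], self.truth()
        )
        assert [c.label for c in labeled] == [LABEL_SNV, LABEL_INDEL]

    def test_same_locus_different_alt_is_nonsomatic(self):
        labeled = label_candidates([self.site(100, "A", "G")], self.truth())
        assert labeled[0].label == LABEL_NONSOMATIC

    def test_candidates_outside_regions_dropped(self):
        regions = RegionSet([("chr1", 0, 150)])
        labeled = label_candidates(
            [self.site(100, "A", "T"), self.site(200, "C", "G")], self.truth(), regions
        )
        assert len(labeled) == 1 and labeled[0].pos == 100

    def test_gray_zone_buffer_exclusion_drops_candidate(self):
        # regions with a 5-bp buffer removed around position 100
        regions = RegionSet([("chr1", 0, 97), ("chr1", 102, 300)])
        labeled = label_candidates(
            [self.site(100, "A", "T"), self.site(99, "G", "A"), self.site(103, "T", "C")],
            self.truth(),
            regions,
        )
        assert [c.pos for c in labeled] == [103]


class TestCandidateStore:
    def make_store(self, n=5):
        sites = [
            CandidateSite("chr1", 10 * (i + 1), "A", "T", 50, 5, 50, 0,
                          features=np.full((21, 15), i, dtype=np.float32),
                          label=LABEL_NONSOMATIC)
            for i in range(n)
        ]
        return CandidateStore.from_sites(sites)

    def test_roundtrip_via_disk(self, tmp_path):
        store = self.make_store()
        store.save(tmp_path / "store")
        back = CandidateStore.load(tmp_path / "store")
        assert back.encoding == store.encoding
        assert np.array_equal(back.features, store.features)
        assert back.meta["pos"].tolist() == store.meta["pos"].tolist()

    def test_concat_rejects_encoding_mismatch(self):
        from somaspike.errors import EncodingMismatchError

        a, b = self.make_store(), self.make_store()
        b.encoding = "pileup-v1+ens5"
        with pytest.raises(EncodingMismatchError):
            a.concat(b)

    def test_spiked_sites_recovered_as_candidates(self):
        # every spiked site with VAF >= 0.05 at >= 80x should become a candidate
        from somaspike.experiment import build_spiked_pair

        pair = build_spiked_pair(
            seed=55, genome_length=400_000, coverage=80, n_snv=260, n_indel=0
        )
        sites = scan_candidates(pair.tumor_reads, pair.normal_reads, pair.ref,
                                encode=False)
        found = {s.key for s in sites}
        eligible = [s for s in pair.plan.sites if s.target_vaf >= 0.05]
        assert len(eligible) >= 200
        hit = sum(1 for s in eligible if s.key in found)
        assert hit / len(eligible) >= 0.99
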
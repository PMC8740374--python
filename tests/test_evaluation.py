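import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from somaspike.errors import ParameterError
from somaspike.evaluation import (
    STATUS_BLACKLISTED,
    STATUS_EXCLUDED,
    STATUS_FN,
    STATUS_FP,
    STATUS_TP,
    AdjudicatedCall,
    Call,
    adjudicate_private_calls,
    adjudication_threshold,
    compute_metrics,
    evaluate_calls,
    match_calls,
    normalize_variants,
    private_fn_analysis,
    stratify,
)
from somaspike.regions import RegionSet
from somaspike.synthgenome import Reference
from somaspike.titration import ReplicateSpec
from somaspike.variants import VariantRecord

from .oracles import brute_evaluate, brute_leftmost


def rec(pos, ref, alt, **kw):
    return VariantRecord("chr1", pos, ref, alt, **kw)


def call(pos, ref, alt, d=10, depth=50):
    return Call(record=rec(pos, ref, alt), alt_depth=d, depth=depth)


SPEC_50X = ReplicateSpec(1.0, 1.0, 50.0, label="50x")


class TestNormalization:
    @pytest.fixture()
    def homopolymer_ref(self):
        return Reference([("chr1", "GCAAAATCGGTTTTACGCAT")])

    def test_snv_unchanged(self, homopolymer_ref):
        r = rec(3, "A", "T")
        assert normalize_variants([r], homopolymer_ref) == [r]

    def test_right_aligned_deletion_shifts_left(self, homopolymer_ref):
        # 1-bp A deletion given right-aligned in the AAAA run (pos 5 "AA">"A")
        out = normalize_variants([rec(5, "AA", "A")], homopolymer_ref)[0]
        seq = homopolymer_ref.sequence("chr1")
        p, ra, aa = brute_leftmost(seq, 5, "AA", "A")
        assert (out.pos, out.ref, out.alt) == (p, ra, aa) == (2, "CA", "C")

    def test_right_aligned_insertion_shifts_left(self, homopolymer_ref):
        out = normalize_variants([rec(14, "T", "TT")], homopolymer_ref)[0]
        seq = homopolymer_ref.sequence("chr1")
        p, ra, aa = brute_leftmost(seq, 14, "T", "TT")
        assert (out.pos, out.ref, out.alt) == (p, ra, aa)
        assert out.pos == 10  # G anchor before the TTTT run

    def test_unparsimonious_record_trimmed(self, homopolymer_ref):
        # "CAA" > "CA" at pos 2 is a 1-bp A deletion in disguise
        out = normalize_variants([rec(2, "CAA", "CA")], homopolymer_ref)[0]
        assert (out.pos, out.ref, out.alt) == (2, "CA", "C")

    def test_idempotent(self, homopolymer_ref):
        records = [rec(5, "AA", "A"), rec(14, "T", "TT"), rec(3, "A", "T")]
        once = normalize_variants(records, homopolymer_ref)
        twice = normalize_variants(once, homopolymer_ref)
        assert once == twice

    def test_reference_mismatch_flagged_not_fixed(self, homopolymer_ref):
        bad = rec(3, "T", "G")  # reference has A at pos 3
        with pytest.raises(ParameterError):
            normalize_variants([bad], homopolymer_ref)
        kept = normalize_variants([bad], homopolymer_ref, on_mismatch="keep")
        assert kept == [bad]

    @given(
        run_len=st.integers(2, 8),
        del_len=st.integers(1, 3),
        offset=st.integers(0, 5),
    )
    def test_homopolymer_deletions_match_enumeration_oracle(
        self, run_len, del_len, offset
    ):
        if del_len >= run_len:
            return
        seq = "GC" + "A" * run_len + "TCGGA"
        ref_obj = Reference([("chr1", seq)])
        pos = 2 + min(offset, run_len - del_len)  # anchor inside the run
        ra = seq[pos - 1 : pos + del_len]
        out = normalize_variants([rec(pos, ra, ra[0])], ref_obj)[0]
        expect = brute_leftmost(seq, pos, ra, ra[0])
        assert (out.pos, out.ref, out.alt) == expect


class TestMatching:
    def truth(self):
        return [
            rec(100, "A", "T", tier="HighConf"),
            rec(200, "C", "G", tier="MedConf"),
            rec(300, "G", "GAT", tier="HighConf"),
        ]

    def test_exact_match_is_tp(self):
        settled, prov = match_calls([call(100, "A", "T")], self.truth())
        tp = [a for a in settled if a.status == STATUS_TP]
        assert len(tp) == 1 and prov == []

    def test_same_pos_different_alt_is_provisional_fp(self):
        settled, prov = match_calls([call(100, "A", "G")], self.truth())
        assert len(prov) == 1
        assert sum(a.status == STATUS_FN for a in settled) == 3

    def test_unmatched_truth_is_fn(self):
        settled, _ = match_calls([], self.truth())
        assert all(a.status == STATUS_FN for a in settled) and len(settled) == 3

    def test_low_tiers_not_in_reference_call_set(self):
        truth = self.truth() + [rec(400, "T", "C", tier="LowConf")]
        settled, prov = match_calls([call(400, "T", "C")], truth)
        assert len(prov) == 1  # LowConf is not truth; the call stays private

    def test_regions_restrict_both_sides(self):
        regions = RegionSet([("chr1", 0, 150)])
        settled, prov = match_calls(
            [call(100, "A", "T"), call(200, "C", "G")], self.truth(), regions
        )
        assert len(settled) == 1 and settled[0].status == STATUS_TP
        assert prov == []

    def test_exact_match_symmetry(self):
        calls = [call(100, "A", "T"), call(555, "G", "C")]
        truth = self.truth()
        settled_ab, prov_ab = match_calls(calls, truth)
        settled_ba, prov_ba = match_calls(
            [Call(record=t) for t in truth], [c.record for c in calls]
        )
        fns_ab = {a.record.key for a in settled_ab if a.status == STATUS_FN}
        prov_ba_keys = {c.key for c in prov_ba}
        assert fns_ab == prov_ba_keys  # FNs of one direction are the other's privates


class TestAdjudication:
    def test_threshold_at_50x_full_purity_is_three(self):
        assert adjudication_threshold(SPEC_50X) == 3.0
        out = adjudicate_private_calls([call(10, "A", "T", d=3)], [], SPEC_50X)
        assert out[0].status == STATUS_FP  # boundary inclusive
        out = adjudicate_private_calls([call(10, "A", "T", d=2)], [], SPEC_50X)
        assert out[0].status == STATUS_EXCLUDED

    def test_half_purity_100x_d2_excluded(self):
        spec = ReplicateSpec(0.5, 1.0, 100.0)
        out = adjudicate_private_calls([call(10, "A", "T", d=2)], [], spec)
        assert out[0].status == STATUS_EXCLUDED  # threshold 3 > 2

    def test_300x_boundary_at_18(self):
        spec = ReplicateSpec(1.0, 1.0, 300.0)
        d17, d18 = adjudicate_private_calls(
            [call(10, "A", "T", d=17), call(20, "A", "T", d=18)], [], spec
        )
        assert d17.status == STATUS_EXCLUDED
        assert d18.status == STATUS_FP

    def test_blacklist_wins(self):
        bl = [rec(10, "A", "T")]
        out = adjudicate_private_calls([call(10, "A", "T", d=30)], bl, SPEC_50X)
        assert out[0].status == STATUS_BLACKLISTED

    @given(
        d=st.integers(0, 40),
        c1=st.floats(10, 300),
        c2=st.floats(10, 300),
        p=st.floats(0.05, 1.0),
    )
    def test_monotone_in_coverage_purity(self, d, c1, c2, p):
        lo, hi = sorted([c1, c2])
        s_lo = adjudicate_private_calls([call(1, "A", "T", d=d)], [], ReplicateSpec(p, 1.0, lo))
        s_hi = adjudicate_private_calls([call(1, "A", "T", d=d)], [], ReplicateSpec(p, 1.0, hi))
        # raising C*P can only move FP -> excluded, never the reverse
        if s_lo[0].status == STATUS_EXCLUDED:
            assert s_hi[0].status == STATUS_EXCLUDED


class TestMetrics:
    def test_closed_form(self):
        adj = (
            [AdjudicatedCall(rec(i, "A", "T"), STATUS_TP) for i in range(1, 10)]
            + [AdjudicatedCall(rec(20, "A", "T"), STATUS_FP)]
            + [AdjudicatedCall(rec(30, "A", "T"), STATUS_FN)]
        )
        rep = compute_metrics(adj)
        assert rep.overall.precision == pytest.approx(0.9)
        assert rep.overall.recall == pytest.approx(0.9)
        assert rep.overall.f1 == pytest.approx(0.9)

    def test_degenerate_zero_calls(self):
        adj = [AdjudicatedCall(rec(1, "A", "T"), STATUS_FN)]
        rep = compute_metrics(adj)
        assert rep.overall.recall == 0.0
        assert rep.overall.precision is None
        assert rep.overall.f1 is None

    def test_excluded_calls_change_nothing(self):
        base = [
            AdjudicatedCall(rec(1, "A", "T"), STATUS_TP),
            AdjudicatedCall(rec(2, "A", "T"), STATUS_FP),
        ]
        excluded = AdjudicatedCall(rec(3, "A", "T"), STATUS_EXCLUDED)
        with_excl = compute_metrics(base + [excluded])
        without = compute_metrics(base)
        assert with_excl.overall.precision == without.overall.precision
        assert with_excl.overall.recall == without.overall.recall
        assert with_excl.overall.excluded == 1

    def test_snv_and_indel_reported_separately(self):
        adj = [
            AdjudicatedCall(rec(1, "A", "T"), STATUS_TP),
            AdjudicatedCall(rec(2, "AC", "A"), STATUS_FN),
        ]
        rep = compute_metrics(adj)
        assert rep.strata["SNV"].tp == 1 and rep.strata["SNV"].fn == 0
        assert rep.strata["INDEL"].fn == 1 and rep.strata["INDEL"].tp == 0


class TestStratification:
    def adj(self):
        def tp(pos, vaf, ref="A", alt="T"):
            t = rec(pos, ref, alt, target_vaf=vaf, tier="HighConf")
            return AdjudicatedCall(t, STATUS_TP, d=int(vaf * 100), depth=100, truth=t)

        return [
            tp(10, 0.15),
            tp(20, 0.07),
            tp(30, 0.6),
            AdjudicatedCall(rec(40, "A", "T"), STATUS_FP, d=8, depth=100),
            AdjudicatedCall(
                rec(50, "A", "T", target_vaf=0.3, tier="HighConf"), STATUS_FN
            ),
        ]

    def test_vaf_bins_membership(self):
        rep = stratify(self.adj(), "vaf_bins")
        assert rep.strata["[0.1,0.2)"].tp == 1  # the 0.15 record
        assert rep.strata["[0.05,0.1)"].tp == 1  # 0.07
        assert rep.strata["[0.5,1]"].tp == 1  # 0.6
        assert rep.strata["[0.05,0.1)"].fp == 1  # FP at observed 0.08
        assert rep.strata["[0.2,0.5)"].fn == 1

    def test_vaf_partition_conserves_totals(self):
        rep = stratify(self.adj(), "vaf_bins")
        assert sum(b.tp for b in rep.strata.values()) == rep.overall.tp
        assert sum(b.fp for b in rep.strata.values()) == rep.overall.fp
        assert sum(b.fn for b in rep.strata.values()) == rep.overall.fn

    def test_indel_size_signed(self):
        adj = [
            AdjudicatedCall(rec(1, "ACGT", "A"), STATUS_TP),  # 3-bp deletion
            AdjudicatedCall(rec(2, "A", "ACC"), STATUS_TP),  # 2-bp insertion
            AdjudicatedCall(rec(3, "A", "T"), STATUS_TP),
        ]
        rep = stratify(adj, "indel_size")
        assert rep.strata["-3"].tp == 1
        assert rep.strata["2"].tp == 1
        assert rep.strata["SNV"].tp == 1

    def test_region_scheme_counts_multi_membership(self):
        beds = {
            "tandem": RegionSet([("chr1", 0, 100)]),
            "segdup": RegionSet([("chr1", 0, 50)]),
        }
        adj = [
            AdjudicatedCall(rec(25, "A", "T"), STATUS_TP),  # in both
            AdjudicatedCall(rec(75, "A", "T"), STATUS_TP),  # tandem only
            AdjudicatedCall(rec(500, "A", "T"), STATUS_TP),  # outside
        ]
        rep = stratify(adj, "region_bed", region_beds=beds)
        assert rep.strata["tandem"].tp == 2
        assert rep.strata["segdup"].tp == 1
        assert rep.strata["outside"].tp == 1

    def test_region_scheme_requires_beds(self):
        with pytest.raises(ParameterError):
            stratify(self.adj(), "region_bed")


class TestPrivateFn:
    def test_set_difference(self):
        a, b = ("chr1", 1, "A", "T"), ("chr1", 2, "C", "G")
        fn_sets = {"X": [{a, b}, {a, b}], "Y": [{b}, {b}]}
        res = private_fn_analysis(fn_sets, "X", "Y", recurrence_fraction=0.5)
        assert res["x_private"] == {a}
        assert res["y_private"] == set()

    def test_identical_sets_yield_empty_privates(self):
        a = ("chr1", 1, "A", "T")
        fn_sets = {"X": [{a}, {a}], "Y": [{a}, {a}]}
        res = private_fn_analysis(fn_sets, "X", "Y", 0.5)
        assert res["x_private"] == res["y_private"] == set()

    def test_eleven_of_twentyone_recurrence(self):
        key = ("chr1", 5, "A", "T")
        # missed in only 10 of 21 replicates -> not recurrent
        fn_10 = {"X": [{key}] * 10 + [set()] * 11, "Y": [set()] * 21}
        res = private_fn_analysis(fn_10, "X", "Y")
        assert key not in res["x_fn"]
        fn_11 = {"X": [{key}] * 11 + [set()] * 10, "Y": [set()] * 21}
        res = private_fn_analysis(fn_11, "X", "Y")
        assert key in res["x_fn"] and key in res["x_private"]

    def test_vaf_distributions_reported(self):
        key = ("chr1", 5, "A", "T")
        truth = [rec(5, "A", "T", target_vaf=0.12)]
        fn_sets = {"X": [{key}, {key}], "Y": [set(), set()]}
        res = private_fn_analysis(fn_sets, "X", "Y", 0.5, truth=truth)
        assert res["x_private_vafs"] == [0.12]

    def test_unknown_caller_rejected(self):
        with pytest.raises(ParameterError):
            private_fn_analysis({"X": [set(), set()]}, "X", "Z", 0.5)


class TestOracleEquivalence:
    """Full pipeline vs plain set arithmetic on randomized fixtures."""

    @pytest.mark.parametrize("fixture_seed", range(20))
    def test_matches_brute_force(self, fixture_seed):
        rng = np.random.default_rng(1000 + fixture_seed)
        n_truth = int(rng.integers(5, 250))
        n_extra = int(rng.integers(5, 250))
        positions = rng.choice(100_000, size=n_truth + n_extra, replace=False) + 1
        truth = [
            rec(int(p), "A", "T", tier="HighConf") for p in positions[:n_truth]
        ]
        spec = ReplicateSpec(
            float(rng.choice([0.1, 0.5, 1.0])), 1.0,
            float(rng.choice([30, 50, 100, 300])),
        )
        calls = []
        # calls: a random subset of truth plus private calls at other loci
        for t in truth:
            if rng.random() < 0.7:
                calls.append(call(t.pos, t.ref, t.alt, d=int(rng.integers(1, 40))))
        for p in positions[n_truth:]:
            calls.append(call(int(p), "A", "T", d=int(rng.integers(1, 40))))
        blacklist = [c.record for c in calls if rng.random() < 0.05]
        adjudicated = evaluate_calls(calls, truth, None, spec, blacklist)
        got = compute_metrics(adjudicated).overall.as_dict()
        want = brute_evaluate(
            [(c.key, c.alt_depth) for c in calls],
            [t.key for t in truth],
            spec,
            blacklist=[b.key for b in blacklist],
        )
        assert got == want
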
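"""Report arithmetic: overlaps, burden, confusion, filter evaluation,
subfamily distributions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1locus import compare
from l1locus.types import CoverageRecord, CurationCall, L1Locus


def call(lid, verdict):
    reason = "PASS" if verdict == "authentic" else "UPSTREAM_SENSE_READS"
    return CurationCall(locus_id=lid, verdict=verdict, reason=reason)


def record(lid, sense=0, up1=0, up5=None):
    up5 = up1 if up5 is None else up5
    return CoverageRecord(
        locus_id=lid, sense_reads=sense, unstranded_reads=sense,
        upstream_sense_1k=up1, upstream_sense_5k=up5,
        upstream_unstranded_1k=up1, upstream_unstranded_5k=up5,
    )


class TestOverlapSets:
    def test_identical_sets(self):
        rep = compare.overlap_sets({"x", "y"}, {"x", "y"})
        assert (rep.shared, rep.only_a, rep.only_b, rep.total_distinct) == (2, 0, 0, 2)

    def test_disjoint_sets(self):
        rep = compare.overlap_sets({"a", "b", "c"}, {"d", "e", "f", "g"})
        assert rep.total_distinct == 7

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_identity_total_equals_union(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        rep = compare.overlap_sets(a, b)
        assert rep.total_distinct == len(a | b)
        assert rep.shared + rep.only_a == len(a)
        assert rep.shared + rep.only_b == len(b)


class TestCurationBurden:
    def make(self, n_true, n_false, reads_true=10, reads_false=10):
        calls = [call(f"t{i}", "authentic") for i in range(n_true)]
        calls += [call(f"f{i}", "rejected") for i in range(n_false)]
        recs = {c.locus_id: record(c.locus_id,
                                   reads_true if c.verdict == "authentic" else reads_false)
                for c in calls}
        return calls, recs

    def test_simple_percentages(self):
        burden = compare.curation_burden(*self.make(6, 4))
        assert burden.percent_authentic_loci == 60.0

    def test_zero_authentic(self):
        burden = compare.curation_burden(*self.make(0, 10))
        assert burden.percent_authentic_loci == 0.0

    def test_zero_candidates_warns_not_raises(self):
        burden = compare.curation_burden([], {})
        assert burden.curated_loci == 0 and burden.percent_authentic_loci == 0.0

    def test_read_percentages(self):
        calls, recs = self.make(2, 2, reads_true=30, reads_false=70)
        burden = compare.curation_burden(calls, recs)
        assert burden.percent_authentic_reads == 30.0


class TestUnstrandedConfusion:
    def build(self):
        # stranded truth: A,B authentic; C,D rejected; E only curated unstranded
        stranded = [call("A", "authentic"), call("B", "authentic"),
                    call("C", "rejected"), call("D", "rejected")]
        # unstranded: A accepted, B rejected (FN), C rejected, E accepted (FP)
        unstranded = [call("A", "authentic"), call("B", "rejected"),
                      call("C", "rejected"), call("D", "rejected"),
                      call("E", "authentic")]
        recs = {lid: record(lid, sense=10 * (i + 1))
                for i, lid in enumerate("ABCDE")}
        return unstranded, stranded, recs

    def test_categories_exclusive_exhaustive(self):
        rep = compare.unstranded_confusion(*self.build())
        assert (rep.true_loci, rep.false_loci,
                rep.false_positive_loci, rep.false_negative_loci) == (1, 2, 1, 1)
        assert rep.total_loci == 5
        ids = [x for v in rep.locus_ids.values() for x in v]
        assert sorted(ids) == list("ABCDE")

    def test_read_totals_sum(self):
        rep = compare.unstranded_confusion(*self.build())
        assert rep.total_reads == sum(10 * (i + 1) for i in range(5))

    def test_missing_records_rejected(self):
        unstranded, stranded, recs = self.build()
        del recs["E"]
        with pytest.raises(ValueError):
            compare.unstranded_confusion(unstranded, stranded, recs)


class TestEvaluateUpstreamFilter:
    def build(self, tz, th, fh, fz, window=1000):
        calls, recs = [], {}
        for n, verdict, up in ((tz, "authentic", 0), (th, "authentic", 2),
                               (fh, "rejected", 3), (fz, "rejected", 0)):
            for i in range(n):
                lid = f"{verdict}{up}_{i}"
                calls.append(call(lid, verdict))
                recs[lid] = record(lid, sense=20, up1=up)
        return compare.evaluate_upstream_filter(calls, recs, window)

    def test_no_authentic_lost_when_all_zero_upstream(self):
        ev = self.build(10, 0, 5, 2)
        assert ev.percent_authentic_lost == 0.0

    def test_cells_recovered(self):
        ev = self.build(9, 3, 6, 2)
        assert (ev.true_zero_upstream, ev.true_has_upstream,
                ev.false_has_upstream, ev.false_zero_upstream) == (9, 3, 6, 2)
        assert ev.total == 20
        assert ev.percent_reduction == pytest.approx(30.0)
        assert ev.percent_authentic_lost == pytest.approx(25.0)

    def test_window_nesting_reduction(self):
        # upstream reads at 3 kb only: invisible at 1 kb, visible at 5 kb
        calls = [call("x", "rejected")]
        recs = {"x": record("x", sense=20, up1=0, up5=4)}
        r1 = compare.evaluate_upstream_filter(calls, recs, 1000)
        r5 = compare.evaluate_upstream_filter(calls, recs, 5000)
        assert r1.percent_reduction <= r5.percent_reduction


class TestSubfamilyDistribution:
    def loci(self, spec):
        out = []
        for i, (sub, n) in enumerate(spec):
            for j in range(n):
                start = (i * 100 + j) * 10_000
                out.append(L1Locus("c", start, start + 6000, "+", sub,
                                   f"c:{start}-{start + 6000}:+"))
        return out

    def test_two_fold_enrichment(self):
        ann = self.loci([("L1HS", 5), ("L1PA2", 5)])
        auth = [l for l in ann if l.subfamily == "L1PA2"][:3]
        dist = compare.subfamily_distribution(auth, ann)
        assert dist["L1PA2"]["enrichment"] == pytest.approx(2.0)

    def test_empty_authentic_gives_na(self):
        ann = self.loci([("L1HS", 4)])
        dist = compare.subfamily_distribution([], ann)
        assert dist["L1HS"]["authentic"] == 0.0
        assert math.isnan(dist["L1HS"]["enrichment"])

    def test_hand_arithmetic_fixture(self):
        ann = self.loci([("L1HS", 10), ("L1PA2", 20), ("L1PA3", 70)])
        auth = (self.loci([("L1HS", 2)]) + self.loci([("L1PA2", 8)])
                + self.loci([("L1PA3", 10)]))
        dist = compare.subfamily_distribution(auth, ann)
        assert dist["L1HS"]["authentic"] == pytest.approx(0.10)
        assert dist["L1PA2"]["authentic"] == pytest.approx(0.40)
        assert dist["L1PA3"]["authentic"] == pytest.approx(0.50)
        assert dist["L1HS"]["enrichment"] == pytest.approx(1.0)
        assert dist["L1PA2"]["enrichment"] == pytest.approx(2.0)
        assert dist["L1PA3"]["enrichment"] == pytest.approx(0.714, abs=1e-3)

    def test_unnamed_collapse_to_other(self):
        ann = self.loci([("L1MA4A", 3), ("L1HS", 3)])
        dist = compare.subfamily_distribution(ann, ann)
        assert dist["Other"]["annotation"] == pytest.approx(0.5)
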
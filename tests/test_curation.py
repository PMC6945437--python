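"""Curation rules, candidate thresholds, ASP detection, upstream filter."""

import numpy as np
import pytest

from l1locus import curation
from l1locus.curation import CurationParams
from l1locus.types import (
    BELOW_READ_THRESHOLD,
    BROAD_UNANNOTATED_NEIGHBORHOOD,
    PASS,
    PASS_PROXIMAL_EXCEPTION,
    PATTERN_MAPPABILITY_MISMATCH,
    UPSTREAM_SENSE_READS,
    UPSTREAM_UNMAPPABLE,
    AlignedPair,
    CoverageRecord,
    L1Locus,
    NeighborhoodProfile,
)


def record(locus_id="L", sense=50, up1=0, up5=0):
    return CoverageRecord(
        locus_id=locus_id, sense_reads=sense, antisense_reads=0,
        unstranded_reads=sense, upstream_sense_1k=up1, upstream_sense_5k=up5,
        upstream_unstranded_1k=up1, upstream_unstranded_5k=up5,
    )


def profile(locus_id="L", n_flank=10, n_locus=12, upstream=(), offsets=(),
            locus_cover=None, up_map=1.0, loc_map=1.0, gene_up=(), downstream=()):
    up = np.zeros(n_flank, dtype=np.int64)
    for i, v in upstream:
        up[i] = v
    down = np.zeros(n_flank, dtype=np.int64)
    for i, v in downstream:
        down[i] = v
    loc = np.array(locus_cover if locus_cover is not None else [4] * n_locus,
                   dtype=np.int64)
    upg = np.zeros(n_flank, dtype=bool)
    for i in gene_up:
        upg[i] = True
    return NeighborhoodProfile(
        locus_id=locus_id, bin_size=500, upstream_bins=up, downstream_bins=down,
        locus_bins=loc, upstream_read_offsets=sorted(offsets),
        upstream_gene_bins=upg, downstream_gene_bins=np.zeros(n_flank, dtype=bool),
        upstream_mappable_frac=up_map, locus_mappable_frac=loc_map,
        locus_bin_mappable=np.ones(len(loc), dtype=bool),
    )


class TestCandidateLoci:
    def rec_map(self, reads):
        return {f"L{i}": record(f"L{i}", sense=r) for i, r in enumerate(reads)}

    def test_singleton_above_threshold(self):
        by_sample = {"s1": self.rec_map([12])}
        cands = curation.candidate_loci(by_sample, ["s1"])
        assert cands == {"s1": {"L0": True}}

    def test_group_rescue(self):
        by_sample = {"s1": self.rec_map([4]), "s2": self.rec_map([15])}
        alone = curation.candidate_loci({"s1": by_sample["s1"]}, ["s1"])
        assert alone == {"s1": {}}
        grouped = curation.candidate_loci(by_sample, ["s1", "s2"])
        assert grouped["s1"] == {"L0": False}
        assert grouped["s2"] == {"L0": True}

    def test_raised_threshold_on_pair(self):
        by_sample = {"s1": self.rec_map([12]), "s2": self.rec_map([15])}
        cands = curation.candidate_loci(by_sample, ["s1", "s2"], min_reads=13)
        assert cands["s1"] == {"L0": False} and cands["s2"] == {"L0": True}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            curation.candidate_loci({}, [])


class TestCurateLocus:
    def test_clean_locus_passes(self):
        call = curation.curate_locus(record(sense=50), profile())
        assert call.verdict == "authentic" and call.reason == PASS

    def test_below_threshold_unless_rescued(self):
        rej = curation.curate_locus(record(sense=4), profile())
        assert rej.reason == BELOW_READ_THRESHOLD
        ok = curation.curate_locus(record(sense=4), profile(), rescued=True)
        assert ok.verdict == "authentic"

    def test_distal_upstream_reads_reject(self):
        call = curation.curate_locus(
            record(sense=50, up5=8),
            profile(upstream=[(6, 8)], offsets=[3000] * 8),
        )
        assert call.reason == UPSTREAM_SENSE_READS

    def test_proximal_exception_accepts_minimal_reads(self):
        call = curation.curate_locus(
            record(sense=50, up1=3, up5=3),
            profile(upstream=[(0, 3)], offsets=[150, 120, 80]),
        )
        assert call.reason == PASS_PROXIMAL_EXCEPTION

    def test_proximal_exception_needs_minimal_fraction(self):
        # 10 of 50 reads exceeds the 10% cap even though all are proximal
        call = curation.curate_locus(
            record(sense=50, up1=10, up5=10),
            profile(upstream=[(0, 10)], offsets=[150] * 10),
        )
        assert call.reason == UPSTREAM_SENSE_READS

    def test_unmappable_upstream_rejects_before_upstream_rule(self):
        call = curation.curate_locus(
            record(sense=50, up5=8),
            profile(upstream=[(6, 8)], offsets=[3000] * 8, up_map=0.1),
        )
        assert call.reason == UPSTREAM_UNMAPPABLE

    def test_broad_unannotated_neighborhood(self):
        # two consecutive distal bins at locus-level coverage, no gene there
        call = curation.curate_locus(
            record(sense=48),  # per-bin mean 4
            profile(downstream=[(4, 4), (5, 5)]),
        )
        assert call.reason == BROAD_UNANNOTATED_NEIGHBORHOOD

    def test_gene_annotated_flank_is_exempt(self):
        call = curation.curate_locus(
            record(sense=48),
            profile(upstream=[(4, 4), (5, 5)], gene_up=[4, 5]),
        )
        assert call.verdict == "authentic"

    def test_pattern_mappability_mismatch(self):
        cover = [0] * 12
        cover[6] = 40  # a single mid-element pile on a fully mappable locus
        call = curation.curate_locus(
            record(sense=40), profile(locus_cover=cover, loc_map=1.0),
        )
        assert call.reason == PATTERN_MAPPABILITY_MISMATCH

    def test_pile_on_low_mappability_locus_not_suspicious(self):
        cover = [0] * 12
        cover[6] = 40
        call = curation.curate_locus(
            record(sense=40), profile(locus_cover=cover, loc_map=0.3),
        )
        assert call.verdict == "authentic"

    def test_every_candidate_gets_exactly_one_reason(self):
        calls = [
            curation.curate_locus(record(sense=50), profile()),
            curation.curate_locus(record(sense=4), profile()),
            curation.curate_locus(record(sense=50, up5=8),
                                  profile(upstream=[(6, 8)], offsets=[3000] * 8)),
        ]
        assert all((c.verdict == "authentic") == (c.reason in (PASS, PASS_PROXIMAL_EXCEPTION))
                   for c in calls)


def frag(fid, start, end, strand):
    read1 = "-" if strand == "+" else "+"
    return AlignedPair(fid, "c", start, end, read1, strand, True,
                       ((start, min(start + 100, end)), (max(end - 100, start), end)))


class TestDetectAsp:
    LOC = L1Locus("c", 20_000, 26_000, "+", "L1HS", "L")

    def test_asp_pattern_detected(self):
        pairs = [frag(f"a{i}", 19_800 + i * 20, 20_300 + i * 20, "-") for i in range(10)]
        assert curation.detect_asp(record(), pairs, self.LOC) is True

    def test_three_prime_antisense_ignored(self):
        pairs = [frag(f"a{i}", 25_000, 25_300, "-") for i in range(10)]
        assert curation.detect_asp(record(), pairs, self.LOC) is False

    def test_too_few_reads(self):
        pairs = [frag("a0", 20_100, 20_400, "-")]
        assert curation.detect_asp(record(), pairs, self.LOC) is False

    def test_unstranded_data_rejected(self):
        with pytest.raises(ValueError):
            curation.detect_asp(record(), [], self.LOC, stranded=False)


class TestUpstreamFilter:
    def test_partition_both_windows(self):
        recs = {"a": record("a", up1=0, up5=3), "b": record("b", up1=0, up5=0)}
        zero1, has1 = curation.upstream_filter(recs, ["a", "b"], 1000)
        assert zero1 == {"a", "b"} and has1 == set()
        zero5, has5 = curation.upstream_filter(recs, ["a", "b"], 5000)
        assert zero5 == {"b"} and has5 == {"a"}

    def test_fixture_partition_sizes(self):
        ups = (0, 0, 1, 0, 4, 0)
        recs = {f"l{i}": record(f"l{i}", up1=u, up5=u) for i, u in enumerate(ups)}
        zero, has = curation.upstream_filter(recs, list(recs), 1000)
        assert (len(zero), len(has)) == (4, 2)

    def test_window_nesting_property(self):
        recs = {f"l{i}": record(f"l{i}", up1=u1, up5=u5)
                for i, (u1, u5) in enumerate([(0, 0), (0, 2), (1, 3), (2, 2)])}
        _, has1 = curation.upstream_filter(recs, list(recs), 1000)
        _, has5 = curation.upstream_filter(recs, list(recs), 5000)
        assert has1 <= has5

    def test_unsupported_window(self):
        with pytest.raises(ValueError):
            curation.upstream_filter({}, [], 2000)
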
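"""Promoter search and full-length annotation construction."""

import numpy as np
import pytest

from l1locus import annotation, io
from l1locus._seq import revcomp
from l1locus.types import PromoterHit, RepeatFeature

from conftest import random_genome


def brute_force_hits(genome: dict, query: str, min_identity: float):
    """Independent oracle: Hamming identity at every full-length offset."""
    hits = []
    for chrom, seq in genome.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            for s in range(len(seq) - len(query) + 1):
                window = seq[s : s + len(query)]
                ident = sum(a == b for a, b in zip(window, q)) / len(q)
                if ident >= min_identity:
                    hits.append((chrom, s, strand, round(ident, 6)))
    return hits


def mutate(seq: str, rate: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


QUERY = random_genome(seed=11, length=300)


class TestFindPromoterHits:
    def test_exact_copy_plus_strand(self):
        genome = {"c": random_genome(1, 500) + QUERY + random_genome(2, 500)}
        hits = annotation.find_promoter_hits(genome, QUERY)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (500, 800, "+")
        assert h.identity == 1.0 and h.query_coverage == 1.0

    def test_reverse_complement_found_on_minus(self):
        genome = {"c": random_genome(3, 400) + revcomp(QUERY) + random_genome(4, 400)}
        hits = annotation.find_promoter_hits(genome, QUERY)
        assert [(h.start, h.end, h.strand) for h in hits] == [(400, 700, "-")]

    def test_diverged_copy_thresholds(self):
        # ~5% substitutions: found at 0.90 identity, not at 0.99
        copy = mutate(QUERY, 0.05, seed=5)
        genome = {"c": random_genome(6, 300) + copy + random_genome(8, 300)}
        hits = annotation.find_promoter_hits(genome, QUERY, min_identity=0.90)
        assert len(hits) == 1
        assert 0.90 <= hits[0].identity < 1.0
        assert annotation.find_promoter_hits(genome, QUERY, min_identity=0.99) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = QUERY
        pieces = [random_genome(seed * 10 + 1, 200)]
        for i in range(3):
            c = mutate(q, float(rng.uniform(0, 0.2)), seed=seed * 10 + i)
            pieces.append(c if rng.random() < 0.5 else revcomp(c))
            pieces.append(random_genome(seed * 10 + 5 + i, 350))
        genome = {"chr": "".join(pieces)}
        got = {(h.chrom, h.start, h.strand) for h in
               annotation.find_promoter_hits(genome, q, min_identity=0.85)}
        expect = {(c, s, st) for c, s, st, _ in
                  brute_force_hits(genome, q, 0.85)}
        # the scan suppresses overlapping placements; every kept hit must be
        # an oracle hit and every oracle hit must overlap a kept hit
        assert got <= expect
        for c, s, st, _ in brute_force_hits(genome, q, 0.85):
            assert any(hc == c and hst == st and abs(hs - s) < len(q)
                       for hc, hs, hst in got)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            annotation.find_promoter_hits({}, QUERY)
        with pytest.raises(ValueError):
            annotation.find_promoter_hits({"c": "ACGT" * 100}, "")
        with pytest.raises(ValueError):
            annotation.find_promoter_hits({"c": "ACGT" * 100}, QUERY, min_identity=1.5)
        with pytest.raises(ValueError):
            annotation.find_promoter_hits({"c": "ACGT" * 100}, QUERY[:30])


def _hit(chrom, start, end, strand):
    return PromoterHit(chrom=chrom, start=start, end=end, strand=strand,
                       identity=1.0, query_coverage=1.0)


class TestBuildFullLength:
    def test_direct_construction(self):
        rep = RepeatFeature("c", 1000, 7000, "+", "L1HS", "r1")
        loci = annotation.build_full_length_annotation(
            [rep], [_hit("c", 1000, 1300, "+")])
        assert len(loci) == 1
        loc = loci[0]
        assert (loc.start, loc.end, loc.subfamily) == (1000, 7000, "L1HS")
        assert loc.locus_id == "c:1000-7000:+"

    def test_truncated_repeat_excluded(self):
        rep = RepeatFeature("c", 1000, 3000, "+", "L1HS", "r1")
        assert annotation.build_full_length_annotation(
            [rep], [_hit("c", 1000, 1300, "+")]) == []

    def test_non_l1_family_excluded(self):
        rep = RepeatFeature("c", 1000, 7000, "+", "AluY", "r1")
        assert annotation.build_full_length_annotation(
            [rep], [_hit("c", 1000, 1300, "+")]) == []

    @pytest.mark.parametrize("strand,hit_at_start,expect", [
        # element-space 5' end: genome-left for +, genome-right for -
        ("+", True, 1), ("+", False, 0), ("-", True, 0), ("-", False, 1),
    ])
    def test_promoter_must_overlap_element_5prime(self, strand, hit_at_start, expect):
        rep = RepeatFeature("c", 1000, 7000, strand, "L1PA2", "r1")
        pos = (1000, 1300) if hit_at_start else (6700, 7000)
        hits = [_hit("c", *pos, strand)]
        got = annotation.build_full_length_annotation([rep], hits)
        assert len(got) == expect

    def test_strand_mismatch_excluded_not_error(self):
        rep = RepeatFeature("c", 1000, 7000, "+", "L1HS", "r1")
        assert annotation.build_full_length_annotation(
            [rep], [_hit("c", 1000, 1300, "-")]) == []

    def test_output_subset_of_input_and_monotone(self):
        reps = [
            RepeatFeature("c", i * 10000, i * 10000 + 4000 + 700 * i, "+",
                          "L1PA3", f"r{i}")
            for i in range(1, 6)
        ]
        hits = [_hit("c", r.start, r.start + 300, "+") for r in reps]
        keys = {(r.chrom, r.start, r.end, r.strand) for r in reps}
        prev = None
        for fmin in (4000, 5000, 5900, 7000):
            loci = annotation.build_full_length_annotation(
                reps, hits, full_length_min=fmin)
            assert all((l.chrom, l.start, l.end, l.strand) in keys for l in loci)
            if prev is not None:
                assert len(loci) <= prev
            prev = len(loci)

    def test_gff3_round_trip(self, tmp_path):
        reps = [RepeatFeature("c", 1000, 7000, "+", "L1HS", "r1"),
                RepeatFeature("c", 20000, 26100, "-", "L1PA4", "r2")]
        hits = [_hit("c", 1000, 1300, "+"), _hit("c", 25800, 26100, "-")]
        loci = annotation.build_full_length_annotation(reps, hits)
        path = tmp_path / "loci.gff3"
        io.write_loci_gff3(loci, path)
        assert io.read_loci_gff3(path) == loci
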
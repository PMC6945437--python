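"""Simulator: determinism, divergence targets, transcript geometry,
and agreement between written SAM and ground truth."""

import numpy as np
import pytest

from l1locus import mappability
from l1locus.simulate import (
    AUTHENTIC,
    CHROM,
    SimConfig,
    l1_consensus,
    simulate_alignments,
    simulate_genome,
    simulate_transcripts,
)


def minimal_config(**kw):
    base = dict(
        genome_length=160_000, subfamily_divergence={"L1HS": 0.0},
        copies_per_subfamily=1, n_truncated=0, n_genes=6,
        n_promoter_driven=1, n_asp_coupled=0, n_unmappable_upstream=0,
        n_asp_only=0, n_co_transcribed=0, n_intronic_opposite=0,
        n_readthrough=0, n_unannotated_upstream=0,
        fragments_per_sample=400, seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenome:
    def test_zero_divergence_copy_equals_consensus(self):
        sim = simulate_genome(minimal_config())
        [locus] = sim.full_length_loci()
        seq = sim.genome[CHROM][locus.start : locus.end]
        if locus.strand == "-":
            from l1locus._seq import revcomp
            seq = revcomp(seq)
        assert seq == sim.consensus

    def test_identical_copies_reduce_mappability(self):
        cfg = minimal_config(copies_per_subfamily=2, genome_length=180_000)
        sim = simulate_genome(cfg)
        track = mappability.compute_mappability(sim.genome, read_length=100)
        for loc in sim.full_length_loci():
            frac = track.fraction(CHROM, loc.start, loc.end)
            assert frac < 1.0

    def test_divergence_within_tolerance(self, small_scenario):
        sim = small_scenario.sim
        from l1locus._seq import revcomp
        for rep in sim.repeats:
            if rep.length_bp < len(sim.consensus):
                continue  # truncated negatives
            seq = sim.genome[CHROM][rep.start : rep.end]
            if rep.strand == "-":
                seq = revcomp(seq)
            dist = sum(a != b for a, b in zip(seq, sim.consensus)) / len(sim.consensus)
            target = sim.config.subfamily_divergence[rep.family]
            # substitution process: observed divergence tracks the rate
            assert dist == pytest.approx(target, abs=0.02)

    def test_deterministic_per_seed(self, small_config):
        a = simulate_genome(small_config)
        b = simulate_genome(small_config)
        assert a.genome == b.genome
        assert a.repeats == b.repeats
        assert {k: vars(v) for k, v in a.loci_truth.items()} == \
               {k: vars(v) for k, v in b.loci_truth.items()}

    def test_oversized_config_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_genome(minimal_config(genome_length=50_000))

    def test_consensus_is_stable(self):
        assert l1_consensus(100) == l1_consensus(100)
        assert len(l1_consensus()) == 6000


class TestSimulateTranscripts:
    def test_promoter_transcript_geometry(self, small_scenario):
        sim = small_scenario.sim
        loci = {l.locus_id: l for l in sim.full_length_loci()}
        ts = [t for t in small_scenario.transcripts if t.tclass == "promoter_driven"]
        assert ts
        for t in ts:
            loc = loci[t.locus_id]
            assert t.strand == loc.strand
            start = t.start if loc.strand == "+" else t.end
            assert abs(start - loc.five_prime) <= sim.config.promoter_jitter

    def test_asp_transcript_geometry(self, small_scenario):
        sim = small_scenario.sim
        loci = {l.locus_id: l for l in sim.full_length_loci()}
        ts = [t for t in small_scenario.transcripts if t.tclass == "asp"]
        assert ts
        for t in ts:
            loc = loci[t.locus_id]
            assert t.strand != loc.strand
            # the antisense transcript's 5' end lies inside the first 900 bp
            # of the element (element orientation)
            five = t.end if t.strand == "-" else t.start
            if loc.strand == "+":
                assert loc.start < five <= loc.start + 900
            else:
                assert loc.end - 900 <= five < loc.end

    def test_unannotated_upstream_produces_upstream_fragments(self, small_scenario):
        sim = small_scenario.sim
        targets = [lid for lid, t in sim.loci_truth.items()
                   if t.class_detail == "unannotated_upstream"]
        assert targets
        ana = small_scenario.result.stranded["cytoplasmic_1"]
        for lid in targets:
            assert ana.records[lid].upstream_sense_5k >= 1


class TestSimulateAlignments:
    def test_byte_identical_sam_per_seed(self, small_config, tmp_path):
        sim = simulate_genome(small_config)
        ts = simulate_transcripts(sim)
        only = (("cytoplasmic_1", "cytoplasmic"),)
        s1 = simulate_alignments(sim, ts, tmp_path / "a", samples=only)
        s2 = simulate_alignments(sim, ts, tmp_path / "b", samples=only)
        b1 = open(s1[0].path, "rb").read()
        b2 = open(s2[0].path, "rb").read()
        assert b1 == b2 and len(b1) > 0

    def test_fragment_count_near_depth(self, small_scenario):
        s = small_scenario.samples[0]
        assert s.n_pairs == pytest.approx(
            small_scenario.config.fragments_per_sample, abs=10)

    def test_qnames_carry_class_truth(self, small_scenario):
        import pysam

        classes = set()
        with pysam.AlignmentFile(small_scenario.samples[0].path) as fh:
            for rec in fh:
                classes.add(rec.query_name.split("|")[1])
        assert "promoter_driven" in classes and "gene_mrna" in classes

    def test_unstranded_counts_equal_sense_plus_antisense(self, small_scenario):
        ana = small_scenario.result.stranded["cytoplasmic_1"]
        assert ana.records
        for rec in ana.records.values():
            assert rec.unstranded_reads == rec.sense_reads + rec.antisense_reads

    def test_duplicated_locus_reads_filtered_by_uniqueness(self, tmp_path):
        # two identical L1 copies: promoter-driven reads from the element
        # body tie between the copies and are discarded by the unique filter
        cfg = minimal_config(copies_per_subfamily=2, genome_length=180_000,
                             n_promoter_driven=2, fragments_per_sample=300)
        sim = simulate_genome(cfg)
        ts = simulate_transcripts(sim)
        [s] = simulate_alignments(sim, ts, tmp_path,
                                  samples=(("c", "cytoplasmic"),))
        from l1locus.alignio import filter_unique_concordant, read_alignments

        pairs, stats, _ = read_alignments(s.path)
        unique = filter_unique_concordant(pairs)
        dup_loci = sim.full_length_loci()
        in_dup = [p for p in unique
                  for l in dup_loci if p.start < l.end and l.start < p.end
                  # interior fragments only: junction-spanning ones can be unique
                  if l.start + 200 < p.start and p.end < l.end - 200]
        assert in_dup == []
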
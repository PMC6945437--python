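"""Read counting over L1 loci, upstream windows, FPKM, and exon:intron QC.

Counting is fragment-level (one concordant pair = one count), with the
>= 1 bp overlap rule.  A fragment overlapping two loci counts toward both.
In stranded mode a fragment is *sense* for a locus when its transcript
strand (under the library protocol) equals the locus strand.
"""

from __future__ import annotations

import logging

from intervaltree import IntervalTree

from .types import AlignedPair, CoverageRecord, GeneModel, L1Locus, SampleStats

log = logging.getLogger(__name__)

UPSTREAM_WINDOWS = (1000, 5000)
DEFAULT_LOCUS_KB = 6.0


def _locus_trees(loci: list[L1Locus]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for loc in loci:
        trees.setdefault(loc.chrom, IntervalTree()).addi(loc.start, loc.end, loc)
    return trees


def count_locus_reads(
    pairs: list[AlignedPair],
    loci: list[L1Locus],
    mode: str = "stranded",
) -> list[CoverageRecord]:
    """Count overlapping fragments per locus.

    Stranded mode fills sense/antisense (and their sum as unstranded);
    unstranded mode fills only ``unstranded_reads``, modelling a library
    where orientation is unavailable.  Every locus gets a record, zeros
    included, in annotation order.
    """
    if mode not in ("stranded", "unstranded"):
        raise ValueError(f"mode must be stranded|unstranded, got {mode!r}")
    records = {loc.locus_id: CoverageRecord(locus_id=loc.locus_id) for loc in loci}
    trees = _locus_trees(loci)
    multi = 0
    for p in pairs:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        overlaps = tree.overlap(p.start, p.end)
        if len(overlaps) > 1:
            multi += 1
        for iv in overlaps:
            loc: L1Locus = iv.data
            rec = records[loc.locus_id]
            rec.unstranded_reads += 1
            if mode == "stranded":
                if p.fragment_strand == loc.strand:
                    rec.sense_reads += 1
                else:
                    rec.antisense_reads += 1
    if multi:
        log.info("%d fragments overlapped more than one locus", multi)
    return [records[loc.locus_id] for loc in loci]


def count_upstream_reads(
    pairs: list[AlignedPair],
    loci: list[L1Locus],
    records: list[CoverageRecord] | None = None,
    windows: tuple[int, ...] = UPSTREAM_WINDOWS,
    chrom_lengths: dict[str, int] | None = None,
) -> list[CoverageRecord]:
    """Fill the strand-aware upstream window counts of the coverage records.

    A fragment counts toward an upstream window when it overlaps the window
    but NOT the locus itself.  Windows sit 5' of the locus in element
    orientation and are truncated at the chromosome boundary.
    """
    for w in windows:
        if w not in UPSTREAM_WINDOWS:
            raise ValueError(f"unsupported upstream window {w}")
    if records is None:
        records = [CoverageRecord(locus_id=loc.locus_id) for loc in loci]
    by_id = {r.locus_id: r for r in records}

    frag_tree: dict[str, IntervalTree] = {}
    for p in pairs:
        frag_tree.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    for loc in loci:
        rec = by_id[loc.locus_id]
        tree = frag_tree.get(loc.chrom)
        if tree is None:
            continue
        clen = chrom_lengths.get(loc.chrom) if chrom_lengths else None
        for w in windows:
            lo, hi = loc.upstream_window(w, clen)
            if lo >= hi:
                continue
            sense = unstranded = 0
            for iv in tree.overlap(lo, hi):
                p: AlignedPair = iv.data
                if p.start < loc.end and loc.start < p.end:
                    continue  # overlaps the locus itself
                unstranded += 1
                if p.fragment_strand == loc.strand:
                    sense += 1
            if w == 1000:
                rec.upstream_sense_1k = sense
                rec.upstream_unstranded_1k = unstranded
            else:
                rec.upstream_sense_5k = max(sense, rec.upstream_sense_1k)
                rec.upstream_unstranded_5k = max(unstranded, rec.upstream_unstranded_1k)
    return records


def coverage(
    pairs: list[AlignedPair],
    loci: list[L1Locus],
    mode: str = "stranded",
    chrom_lengths: dict[str, int] | None = None,
) -> list[CoverageRecord]:
    """Locus plus upstream counting in one call."""
    records = count_locus_reads(pairs, loci, mode=mode)
    return count_upstream_reads(pairs, loci, records, chrom_lengths=chrom_lengths)


def fpkm(read_count: int, stats: SampleStats, locus_kb: float = DEFAULT_LOCUS_KB) -> float:
    """Fragments per kilobase per million mapped fragments.

    Full-length L1 loci are all ~6 kb, so the locus length is fixed at
    ``locus_kb`` (default 6) rather than measured per locus:
    ``reads / (million_mapped * locus_kb)``.
    """
    if stats.million_mapped <= 0:
        raise ValueError("million_mapped must be > 0 for FPKM")
    if locus_kb <= 0:
        raise ValueError("locus_kb must be > 0")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count / (stats.million_mapped * locus_kb)


def exon_intron_ratio(
    pairs: list[AlignedPair],
    genes: list[GeneModel],
) -> tuple[dict[str, float], float, list[str]]:
    """Per-gene exon:intron fragment ratios and their arithmetic mean.

    A fragment overlapping both an exon and an intron of a gene counts once,
    to the exon (exon priority).  Genes with zero intron fragments are
    excluded from the mean and reported in the third return value.  A low
    mean indicates unprocessed (nuclear) RNA in the sample.
    """
    if not genes:
        raise ValueError("at least one gene model is required")
    frag_tree: dict[str, IntervalTree] = {}
    for p in pairs:
        frag_tree.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    ratios: dict[str, float] = {}
    excluded: list[str] = []
    counts: dict[str, tuple[int, int]] = {}
    for g in genes:
        tree = frag_tree.get(g.chrom)
        exon_n = intron_n = 0
        if tree is not None:
            for iv in tree.overlap(g.start, g.end):
                p: AlignedPair = iv.data
                in_exon = any(p.start < e and s < p.end for s, e in g.exons)
                in_intron = any(p.start < e and s < p.end for s, e in g.introns)
                if in_exon:
                    exon_n += 1
                elif in_intron:
                    intron_n += 1
        counts[g.name] = (exon_n, intron_n)
        if intron_n == 0:
            excluded.append(g.name)
            log.info("gene %s excluded from exon:intron mean (0 intron reads)", g.name)
        else:
            ratios[g.name] = exon_n / intron_n
    if not ratios:
        raise ValueError("exon:intron ratio undefined: all genes had 0 intron reads")
    mean = sum(ratios.values()) / len(ratios)
    return ratios, mean, excluded
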
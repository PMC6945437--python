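"""Automated curation of candidate L1 loci.

The curation question is whether the reads over a full-length L1 are
consistent with transcription initiated at the element's own promoter, as
opposed to passive co-transcription (the element sitting inside another
transcribed unit), gene readthrough, or an un-annotated upstream promoter.
The visual-review heuristics of locus-by-locus inspection are encoded here
as a deterministic, ordered rule set producing one reason code per
candidate:

R0  below the read threshold (unless rescued by a grouped sample);
R2  the immediate upstream flank is too unmappable to exclude upstream
    transcription;
R1  same-strand reads in the 5 kb upstream window reject the locus, unless
    all of them sit within the proximal window (100-200 bp) of the
    promoter start and are few relative to the locus (the proximal
    exception);
R3  broad un-annotated same-strand expression in the flanks at a level
    comparable to the locus itself;
R4  a read pile-up pattern inconsistent with the locus's (good)
    mappability, e.g. all reads in one mid-element bin.

First match wins; anything that survives is authentic (PASS).  Antisense
promoter (ASP) activity is detected independently of the verdict, so
antisense-only loci can be flagged while still being rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .types import (
    BELOW_READ_THRESHOLD,
    BROAD_UNANNOTATED_NEIGHBORHOOD,
    PASS,
    PASS_PROXIMAL_EXCEPTION,
    PATTERN_MAPPABILITY_MISMATCH,
    UPSTREAM_SENSE_READS,
    UPSTREAM_UNMAPPABLE,
    AlignedPair,
    CoverageRecord,
    CurationCall,
    GeneModel,
    L1Locus,
    MappabilityTrack,
    NeighborhoodProfile,
)

log = logging.getLogger(__name__)


@dataclass
class CurationParams:
    """Tunable quantifications of the curation rules.

    The qualitative criteria ("minimal reads", "similar expression levels",
    a suspicious pile-up) are made operational with the thresholds below;
    all are configurable.
    """

    min_reads: int = 10
    upstream_window: int = 5000
    proximal_window: int = 200
    proximal_max_fraction: float = 0.10
    upstream_unmappable_window: int = 1000
    min_upstream_mappability: float = 0.5
    bin_size: int = 500
    neighborhood_ratio: float = 0.5
    broad_min_bins: int = 2
    pattern_mappability_min: float = 0.9
    pattern_peak_share: float = 0.8
    asp_min_reads: int = 5
    asp_utr_window: int = 900


def candidate_loci(
    records_by_sample: dict[str, dict[str, CoverageRecord]],
    group: list[str],
    min_reads: int = 10,
    stranded: bool = True,
) -> dict[str, dict[str, bool]]:
    """Candidate loci per sample under the grouped read threshold.

    A locus is a candidate in a sample when it reaches ``min_reads`` there,
    or in any other sample of the group (a "rescued" candidate).  Returns
    ``{sample: {locus_id: reached_threshold_directly}}``.
    """
    if not group:
        raise ValueError("sample group is empty")
    missing = [s for s in group if s not in records_by_sample]
    if missing:
        raise ValueError(f"no coverage records for samples {missing}")
    reached: dict[str, set[str]] = {
        s: {
            lid
            for lid, rec in records_by_sample[s].items()
            if rec.reads(stranded) >= min_reads
        }
        for s in group
    }
    union: set[str] = set().union(*reached.values())
    return {
        s: {lid: (lid in reached[s]) for lid in sorted(union)}
        for s in group
    }


def _strand_dir(locus: L1Locus) -> int:
    """+1 if element-space downstream is genome-rightward, else -1."""
    return 1 if locus.strand == "+" else -1


def _bin_interval(locus: L1Locus, flank: str, i: int, bin_size: int) -> tuple[int, int]:
    """Genome interval of flank bin i (element-space distance i*bs..(i+1)*bs)."""
    d = _strand_dir(locus)
    if flank == "up":
        anchor, sign = locus.five_prime, -d
    else:
        anchor = locus.end if locus.strand == "+" else locus.start
        sign = d
    a = anchor + sign * i * bin_size
    b = anchor + sign * (i + 1) * bin_size
    return (min(a, b), max(a, b))


def build_neighborhood_profile(
    locus: L1Locus,
    pairs: list[AlignedPair] | IntervalTree,
    track: MappabilityTrack,
    genes: list[GeneModel],
    params: CurationParams = CurationParams(),
    stranded: bool = True,
) -> NeighborhoodProfile:
    """Binned strand-matched coverage around one locus plus mappability.

    Flank bins count fragments overlapping the bin but not the locus;
    locus bins count locus-overlapping fragments in every bin they touch.
    In unstranded mode all fragments count regardless of orientation.
    """
    if track is None:
        raise ValueError("a mappability track is required for curation")
    bs = params.bin_size
    n_flank = -(-params.upstream_window // bs)
    tree = pairs if isinstance(pairs, IntervalTree) else _fragment_tree(pairs).get(locus.chrom, IntervalTree())
    chrom_len = len(track.arrays[locus.chrom])

    def matches(p: AlignedPair) -> bool:
        return (not stranded) or p.fragment_strand == locus.strand

    up = np.zeros(n_flank, dtype=np.int64)
    down = np.zeros(n_flank, dtype=np.int64)
    up_gene = np.zeros(n_flank, dtype=bool)
    down_gene = np.zeros(n_flank, dtype=bool)
    same_strand_genes = [
        g for g in genes if g.chrom == locus.chrom and g.strand == locus.strand
    ]
    for flank, cov, gcov in (("up", up, up_gene), ("down", down, down_gene)):
        for i in range(n_flank):
            lo, hi = _bin_interval(locus, flank, i, bs)
            lo, hi = max(0, lo), min(chrom_len, hi)
            if lo >= hi:
                continue
            for iv in tree.overlap(lo, hi):
                p: AlignedPair = iv.data
                if p.start < locus.end and locus.start < p.end:
                    continue  # locus-overlapping fragments belong to the locus
                if matches(p):
                    cov[i] += 1
            gcov[i] = any(g.start < hi and lo < g.end for g in same_strand_genes)

    # element-space offsets of pure-upstream fragments within the window
    offsets: list[int] = []
    ulo, uhi = locus.upstream_window(params.upstream_window, chrom_len)
    if ulo < uhi:
        for iv in tree.overlap(ulo, uhi):
            p = iv.data
            if p.start < locus.end and locus.start < p.end:
                continue
            if not matches(p):
                continue
            if locus.strand == "+":
                offsets.append(locus.start - p.end)
            else:
                offsets.append(p.start - locus.end)
    offsets = sorted(max(o, 0) for o in offsets)

    # locus bins assign each fragment once, by element-space midpoint, so a
    # bin's share of locus reads is a true proportion
    n_locus_bins = -(-locus.length_bp // bs)
    locus_bins = np.zeros(n_locus_bins, dtype=np.int64)
    bin_mappable = np.zeros(n_locus_bins, dtype=bool)
    for iv in tree.overlap(locus.start, locus.end):
        p = iv.data
        if not matches(p):
            continue
        mid = (p.start + p.end) // 2
        off = mid - locus.start if locus.strand == "+" else locus.end - mid
        b = min(max(off // bs, 0), n_locus_bins - 1)
        locus_bins[b] += 1
    for i in range(n_locus_bins):
        if locus.strand == "+":
            lo = locus.start + i * bs
            hi = min(locus.end, lo + bs)
        else:
            hi = locus.end - i * bs
            lo = max(locus.start, hi - bs)
        bin_mappable[i] = track.fraction(locus.chrom, lo, hi) >= 0.5

    w = params.upstream_unmappable_window
    mlo, mhi = locus.upstream_window(w, chrom_len)
    up_frac = track.fraction(locus.chrom, mlo, mhi) if mlo < mhi else 0.0
    return NeighborhoodProfile(
        locus_id=locus.locus_id,
        bin_size=bs,
        upstream_bins=up,
        downstream_bins=down,
        locus_bins=locus_bins,
        upstream_read_offsets=offsets,
        upstream_gene_bins=up_gene,
        downstream_gene_bins=down_gene,
        upstream_mappable_frac=up_frac,
        locus_mappable_frac=track.fraction(locus.chrom, locus.start, locus.end),
        locus_bin_mappable=bin_mappable,
    )


def _has_broad_run(cov: np.ndarray, gene_bins: np.ndarray, eligible: np.ndarray,
                   threshold: float, min_bins: int) -> bool:
    run = 0
    for c, g, ok in zip(cov, gene_bins, eligible):
        if ok and not g and c > 0 and c >= threshold:
            run += 1
            if run >= min_bins:
                return True
        else:
            run = 0
    return False


def curate_locus(
    record: CoverageRecord,
    profile: NeighborhoodProfile,
    params: CurationParams = CurationParams(),
    stranded: bool = True,
    rescued: bool = False,
    asp_active: bool = False,
) -> CurationCall:
    """Apply the ordered rules R0, R2, R1(+exception), R3, R4 to one candidate."""
    reads = record.reads(stranded)
    upstream = record.upstream(params.upstream_window, stranded)
    metrics = {
        "locus_reads": reads,
        "upstream_reads_5k": record.upstream(5000, stranded),
        "upstream_reads_1k": record.upstream(1000, stranded),
        "upstream_mappable_frac": round(profile.upstream_mappable_frac, 4),
        "locus_mappable_frac": round(profile.locus_mappable_frac, 4),
    }

    def call(verdict: str, reason: str) -> CurationCall:
        return CurationCall(
            locus_id=record.locus_id, verdict=verdict, reason=reason,
            asp_active=asp_active, metrics=metrics,
        )

    # R0: read threshold (grouped samples may rescue a locus below it)
    if reads < params.min_reads and not rescued:
        return call("rejected", BELOW_READ_THRESHOLD)

    # R2: cannot exclude upstream transcription when the immediate upstream
    # flank is unmappable
    if profile.upstream_mappable_frac < params.min_upstream_mappability:
        return call("rejected", UPSTREAM_UNMAPPABLE)

    # R1: same-strand reads upstream within the window, with the proximal
    # exception for a few reads hugging the promoter start
    if upstream > 0:
        offsets = profile.upstream_read_offsets
        all_proximal = bool(offsets) and max(offsets) <= params.proximal_window
        if all_proximal and upstream <= params.proximal_max_fraction * max(reads, 1):
            return call("authentic", PASS_PROXIMAL_EXCEPTION)
        return call("rejected", UPSTREAM_SENSE_READS)

    # R3: broad un-annotated neighborhood expression at locus-like levels
    n_locus_bins = max(len(profile.locus_bins), 1)
    per_bin_mean = reads / n_locus_bins
    threshold = params.neighborhood_ratio * per_bin_mean
    bs = profile.bin_size
    n_flank = len(profile.upstream_bins)
    up_eligible = np.array(
        [(i + 1) * bs > params.proximal_window for i in range(n_flank)]
    )
    down_eligible = np.ones(n_flank, dtype=bool)
    if per_bin_mean > 0 and (
        _has_broad_run(profile.upstream_bins, profile.upstream_gene_bins,
                       up_eligible, threshold, params.broad_min_bins)
        or _has_broad_run(profile.downstream_bins, profile.downstream_gene_bins,
                          down_eligible, threshold, params.broad_min_bins)
    ):
        return call("rejected", BROAD_UNANNOTATED_NEIGHBORHOOD)

    # R4: expression pattern unrelated to mappability (a single pile-up on a
    # locus that is mappable nearly everywhere)
    if profile.locus_mappable_frac >= params.pattern_mappability_min and reads > 0:
        peak_share = float(profile.locus_bins.max()) / max(reads, 1)
        mappable_bins = int(profile.locus_bin_mappable.sum())
        zero_mappable = int(
            np.count_nonzero((profile.locus_bins == 0) & profile.locus_bin_mappable)
        )
        metrics["peak_share"] = round(peak_share, 4)
        if (
            peak_share >= params.pattern_peak_share
            and mappable_bins > 0
            and zero_mappable * 2 >= mappable_bins
        ):
            return call("rejected", PATTERN_MAPPABILITY_MISMATCH)

    return call("authentic", PASS)


def detect_asp(
    record: CoverageRecord,
    pairs: list[AlignedPair] | IntervalTree,
    locus: L1Locus,
    params: CurationParams = CurationParams(),
    stranded: bool = True,
    chrom_len: int | None = None,
) -> bool:
    """Antisense-promoter activity: antisense fragments over the 5'UTR.

    True iff at least one antisense fragment overlaps the element-space
    first ``asp_utr_window`` bp and, together with antisense fragments in
    the first 1 kb of upstream flank (the ASP transcript running out of the
    element), they number >= ``asp_min_reads``.
    """
    if not stranded:
        raise ValueError("ASP detection requires stranded data")
    tree = pairs if isinstance(pairs, IntervalTree) else _fragment_tree(pairs).get(locus.chrom, IntervalTree())
    if locus.strand == "+":
        utr = (locus.start, min(locus.end, locus.start + params.asp_utr_window))
    else:
        utr = (max(locus.start, locus.end - params.asp_utr_window), locus.end)
    flank = locus.upstream_window(1000, chrom_len)
    in_utr = in_flank = 0
    for iv in tree.overlap(min(utr[0], flank[0]), max(utr[1], flank[1])):
        p: AlignedPair = iv.data
        if p.fragment_strand == locus.strand:
            continue
        if p.start < utr[1] and utr[0] < p.end:
            in_utr += 1
        elif p.start < flank[1] and flank[0] < p.end:
            in_flank += 1
    return in_utr >= 1 and (in_utr + in_flank) >= params.asp_min_reads


def upstream_filter(
    records: dict[str, CoverageRecord],
    candidates: set[str] | list[str],
    window: int,
    stranded: bool = True,
) -> tuple[set[str], set[str]]:
    """Partition candidates by zero vs non-zero upstream reads at ``window``.

    This is the automation surrogate for full curation: loci with any
    same-strand upstream read within the window would be filtered out.
    """
    if window not in (1000, 5000):
        raise ValueError(f"unsupported window {window}; use 1000 or 5000")
    zero, has = set(), set()
    for lid in candidates:
        if records[lid].upstream(window, stranded) == 0:
            zero.add(lid)
        else:
            has.add(lid)
    return zero, has


def _fragment_tree(pairs: list[AlignedPair]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in pairs:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def curate_sample(
    loci: list[L1Locus],
    pairs: list[AlignedPair],
    records: list[CoverageRecord],
    track: MappabilityTrack,
    genes: list[GeneModel],
    params: CurationParams = CurationParams(),
    stranded: bool = True,
    candidates: dict[str, bool] | None = None,
) -> list[CurationCall]:
    """Curate every candidate locus of one sample.

    ``candidates`` maps locus_id -> reached-threshold-directly (from
    :func:`candidate_loci`); when omitted, candidacy is computed from this
    sample alone.  ASP detection runs on stranded data only.
    """
    by_id = {r.locus_id: r for r in records}
    loci_by_id = {l.locus_id: l for l in loci}
    if candidates is None:
        candidates = {
            lid: True
            for lid, rec in by_id.items()
            if rec.reads(stranded) >= params.min_reads
        }
    trees = _fragment_tree(pairs)
    calls: list[CurationCall] = []
    for lid in sorted(candidates):
        locus = loci_by_id[lid]
        rec = by_id[lid]
        tree = trees.get(locus.chrom, IntervalTree())
        profile = build_neighborhood_profile(locus, tree, track, genes, params, stranded)
        asp = False
        if stranded:
            asp = detect_asp(rec, tree, locus, params, stranded=True,
                             chrom_len=len(track.arrays[locus.chrom]))
        calls.append(curate_locus(
            rec, profile, params, stranded=stranded,
            rescued=not candidates[lid], asp_active=asp,
        ))
    return calls
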
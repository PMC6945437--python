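"""Full-length L1 annotation: promoter search and repeat intersection.

The annotation of interest is the set of repeats that are (a) an L1
subfamily, (b) long enough to be full length (~6 kb) and (c) carry an
intact internal promoter, operationalised as a sequence-similarity hit of
the first 300 bp of an L1 consensus overlapping the element-space 5' end.

The promoter search is a seeded, ungapped scan: exact seed k-mers nominate
candidate offsets and each candidate is scored by Hamming identity over the
full query.  The hit is used only as an interval, so gapped alignment and
E-value scoring are deliberately out of scope.
"""

from __future__ import annotations

import logging
import re

import numpy as np

from ._seq import KmerIndex, encode, kmer_code, revcomp
from .types import L1Locus, PromoterHit, RepeatFeature

log = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_MIN_QUERY_COVERAGE = 0.80
DEFAULT_FULL_LENGTH_MIN = 5900
DEFAULT_PROMOTER_WINDOW = 300
DEFAULT_FAMILY_PATTERN = "L1"

_SEED_K = 12
_SEED_STEP = 4


def _scan_one_strand(
    chrom: str,
    index: KmerIndex,
    chrom_arr: np.ndarray,
    query_arr: np.ndarray,
    strand: str,
    min_identity: float,
) -> list[PromoterHit]:
    """Seed-and-extend scan of one query orientation against one chromosome."""
    qlen = len(query_arr)
    k = min(_SEED_K, qlen)
    candidates: set[int] = set()
    for off in range(0, qlen - k + 1, _SEED_STEP):
        code = kmer_code(query_arr[off : off + k])
        if code < 0:
            continue
        for pos in index.lookup(code):
            start = int(pos) - off
            if 0 <= start <= len(chrom_arr) - qlen:
                candidates.add(start)
    hits = []
    for start in sorted(candidates):
        window = chrom_arr[start : start + qlen]
        matches = int(np.count_nonzero(window == query_arr))
        identity = matches / qlen
        if identity >= min_identity:
            hits.append(PromoterHit(
                chrom=chrom, start=start, end=start + qlen, strand=strand,
                identity=identity, query_coverage=1.0,
            ))
    return hits


def _suppress_overlaps(hits: list[PromoterHit]) -> list[PromoterHit]:
    """Greedy non-maximum suppression of overlapping same-strand hits."""
    kept: list[PromoterHit] = []
    for h in sorted(hits, key=lambda h: (-h.identity, h.chrom, h.start, h.strand)):
        if any(
            k.chrom == h.chrom and k.strand == h.strand
            and k.start < h.end and h.start < k.end
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return kept


def find_promoter_hits(
    genome: dict[str, str],
    query: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE,
) -> list[PromoterHit]:
    """Locate promoter-like intervals on both strands of every chromosome.

    Hits are full-length ungapped placements of the query, so
    ``query_coverage`` is 1.0 and the coverage threshold only validates the
    parameter range.  Deterministic given inputs.
    """
    if not genome:
        raise ValueError("genome is empty")
    if not query:
        raise ValueError("promoter query is empty")
    if len(query) < 50:
        raise ValueError("promoter query must be at least 50 bp")
    for name, thr in (("min_identity", min_identity), ("min_query_coverage", min_query_coverage)):
        if not 0.0 < thr <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {thr}")

    q_fwd = encode(query)
    q_rev = encode(revcomp(query))
    hits: list[PromoterHit] = []
    for chrom, seq in genome.items():
        if len(seq) < len(query):
            continue
        arr = encode(seq)
        index = KmerIndex(arr, min(_SEED_K, len(query)))
        hits.extend(_scan_one_strand(chrom, index, arr, q_fwd, "+", min_identity))
        hits.extend(_scan_one_strand(chrom, index, arr, q_rev, "-", min_identity))
    return _suppress_overlaps(hits)


def promoter_region(repeat: RepeatFeature | L1Locus, window: int) -> tuple[int, int]:
    """The strand-aware element-space 5'-most ``window`` bases of a repeat."""
    if repeat.strand == "+":
        return repeat.start, min(repeat.end, repeat.start + window)
    return max(repeat.start, repeat.end - window), repeat.end


def build_full_length_annotation(
    repeats: list[RepeatFeature],
    hits: list[PromoterHit],
    full_length_min: int = DEFAULT_FULL_LENGTH_MIN,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    family_pattern: str = DEFAULT_FAMILY_PATTERN,
) -> list[L1Locus]:
    """Intersect repeats with promoter hits to produce full-length L1 loci.

    A repeat becomes a locus iff its family matches ``family_pattern`` (a
    regex anchored at the start of the family name), its length is at least
    ``full_length_min``, and a same-strand hit overlaps its 5'-most
    ``promoter_window`` bases by >= 1 bp.
    """
    pat = re.compile(family_pattern)
    seen_intervals: set[tuple[str, int, int, str]] = set()
    loci: list[L1Locus] = []
    hits_by_key: dict[tuple[str, str], list[PromoterHit]] = {}
    for h in hits:
        hits_by_key.setdefault((h.chrom, h.strand), []).append(h)

    for rep in repeats:
        if not pat.match(rep.family):
            continue
        if rep.length_bp < full_length_min:
            continue
        p_lo, p_hi = promoter_region(rep, promoter_window)
        same_strand = hits_by_key.get((rep.chrom, rep.strand), [])
        if not any(h.start < p_hi and p_lo < h.end for h in same_strand):
            continue
        key = (rep.chrom, rep.start, rep.end, rep.strand)
        if key in seen_intervals:
            log.warning("duplicate repeat interval kept: %s", key)
        seen_intervals.add(key)
        loci.append(L1Locus(
            chrom=rep.chrom, start=rep.start, end=rep.end, strand=rep.strand,
            subfamily=rep.family,
            locus_id=L1Locus.make_id(rep.chrom, rep.start, rep.end, rep.strand),
        ))
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.strand))
    return loci
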
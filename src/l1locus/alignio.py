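"""Paired-end alignment ingest and the built-in exhaustive read placer.

Two routes produce :class:`~l1locus.types.AlignedPair` streams:

* :func:`read_alignments` parses SAM/BAM written by an external aligner and
  takes each pair's uniqueness from the file under a configurable tag
  dialect (the pipeline never re-aligns external data);
* :func:`place_reads` scores every mate at every genomic offset on both
  strands and keeps a pair only if exactly one concordant placement attains
  the strictly minimal total mismatch count — a desk-scale equivalent of an
  exhaustive best-match aligner, also used as the uniqueness oracle by the
  simulator and the mappability track.

The default strand protocol is the dUTP convention (read1 antisense to the
transcript), so the fragment strand is the strand of read2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from ._seq import KmerIndex, MAX_INDEX_K, N_CODE, encode, revcomp_arr
from .types import AlignedPair, SampleStats

log = logging.getLogger(__name__)

PROTOCOLS = ("read1-antisense", "read1-sense")
DIALECTS = ("NH", "XS", "MAPQ")
DEFAULT_MAX_INSERT = 1000
DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MAPQ_THRESHOLD = 10

_VALID_BASES = frozenset("ACGTN")


@dataclass
class SkipCounts:
    """Why records were dropped during ingest."""

    unmapped: int = 0
    discordant: int = 0
    unpaired: int = 0
    secondary: int = 0


def fragment_strand_for(read1_strand: str, protocol: str) -> str:
    if protocol == "read1-sense":
        return read1_strand
    if protocol == "read1-antisense":
        return "-" if read1_strand == "+" else "+"
    raise ValueError(f"unknown strand protocol {protocol!r}; supported: {PROTOCOLS}")


def _is_unique(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment,
               dialect: str, mapq_threshold: int) -> bool:
    if dialect == "XS":
        return not (r1.has_tag("XS") or r2.has_tag("XS"))
    if dialect == "NH":
        nh = max(
            r1.get_tag("NH") if r1.has_tag("NH") else 1,
            r2.get_tag("NH") if r2.has_tag("NH") else 1,
        )
        return nh <= 1
    if dialect == "MAPQ":
        return min(r1.mapping_quality, r2.mapping_quality) >= mapq_threshold
    raise ValueError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")


def _parse_sample_header(header: pysam.AlignmentHeader, path: str) -> dict:
    meta = {"sample_id": Path(path).stem, "stranded": True, "compartment": "unknown"}
    for co in header.to_dict().get("CO", []):
        if not co.startswith("l1locus"):
            continue
        for part in co.split()[1:]:
            k, _, v = part.partition("=")
            if k == "sample_id":
                meta["sample_id"] = v
            elif k == "stranded":
                meta["stranded"] = v.lower() in ("1", "true", "yes")
            elif k == "compartment":
                meta["compartment"] = v
    return meta


def read_alignments(
    path: str | Path,
    dialect: str = "NH",
    protocol: str = "read1-antisense",
    max_insert: int = DEFAULT_MAX_INSERT,
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
) -> tuple[list[AlignedPair], SampleStats, SkipCounts]:
    """Read SAM/BAM into concordant fragment records plus sample stats.

    Mates are paired by query name.  Unmapped, secondary/supplementary and
    discordant records are skipped with counts.  ``million_mapped`` is the
    unique concordant pair count / 1e6.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown strand protocol {protocol!r}; supported: {PROTOCOLS}")

    pairs: list[AlignedPair] = []
    skips = SkipCounts()
    unmapped_names: set[str] = set()
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        meta = _parse_sample_header(fh.header, str(path))
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                skips.secondary += 1
                continue
            if rec.is_unmapped or rec.mate_is_unmapped:
                unmapped_names.add(rec.query_name)  # counted per fragment
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
            pair = _pair_from_records(r1, r2, dialect, protocol, max_insert,
                                      mapq_threshold, skips)
            if pair is not None:
                pairs.append(pair)
    skips.unmapped = len(unmapped_names)
    skips.unpaired += len(pending)
    n_unique = sum(1 for p in pairs if p.unique)
    stats = SampleStats(
        sample_id=meta["sample_id"], million_mapped=n_unique / 1e6,
        stranded=meta["stranded"], compartment=meta["compartment"],
    )
    if skips.unmapped or skips.discordant or skips.unpaired:
        log.info("skipped records in %s: %s", path, skips)
    return pairs, stats, skips


def _pair_from_records(r1, r2, dialect, protocol, max_insert, mapq_threshold,
                       skips) -> AlignedPair | None:
    if r1.reference_name != r2.reference_name:
        skips.discordant += 1
        return None
    s1 = "-" if r1.is_reverse else "+"
    s2 = "-" if r2.is_reverse else "+"
    span1 = (r1.reference_start, r1.reference_end)
    span2 = (r2.reference_start, r2.reference_end)
    start, end = min(span1[0], span2[0]), max(span1[1], span2[1])
    concordant = r1.is_proper_pair or (
        s1 != s2
        and end - start <= max_insert
        # inward orientation: the + mate is the leftmost one
        and (span1 if s1 == "+" else span2)[0] <= (span1 if s1 == "-" else span2)[0]
    )
    if not concordant:
        skips.discordant += 1
        return None
    return AlignedPair(
        fragment_id=r1.query_name,
        chrom=r1.reference_name,
        start=start,
        end=end,
        read1_strand=s1,
        fragment_strand=fragment_strand_for(s1, protocol),
        unique=_is_unique(r1, r2, dialect, mapq_threshold),
        mate_spans=tuple(sorted((span1, span2))),
    )


def filter_unique_concordant(pairs):
    """Keep exactly the unique pairs, preserving order (idempotent)."""
    return [p for p in pairs if p.unique]


# -- exhaustive placement ----------------------------------------------------

@dataclass
class GenomeSearcher:
    """Seeded exhaustive matcher over a small genome.

    Pigeonhole seeding: a pattern placed with <= m mismatches must contain
    an exact copy of at least one of m+1 disjoint segments, so exact-match
    k-mer lookups of segment prefixes nominate every qualifying offset.
    """

    genome: dict[str, str]
    arrays: dict[str, np.ndarray] = field(init=False)
    _indexes: dict[tuple[str, int], KmerIndex] = field(init=False, default_factory=dict)

    def __post_init__(self):
        self.arrays = {c: encode(s) for c, s in self.genome.items()}

    def _index(self, chrom: str, k: int) -> KmerIndex:
        key = (chrom, k)
        if key not in self._indexes:
            self._indexes[key] = KmerIndex(self.arrays[chrom], k)
        return self._indexes[key]

    def _candidates(self, chrom: str, pattern: np.ndarray, max_mm: int) -> set[int]:
        arr = self.arrays[chrom]
        plen = len(pattern)
        n_seg = max_mm + 1
        bounds = np.linspace(0, plen, n_seg + 1).astype(int)
        cands: set[int] = set()
        any_seed = False
        for i in range(n_seg):
            off = int(bounds[i])
            seg_len = int(bounds[i + 1]) - off
            k = min(seg_len, MAX_INDEX_K)
            if k < 1:
                continue
            seed = pattern[off : off + k]
            if np.any(seed == N_CODE):
                continue
            any_seed = True
            code = 0
            for v in seed:
                code = (code << 2) | int(v & 3)
            for pos in self._index(chrom, k).lookup(code):
                start = int(pos) - off
                if 0 <= start <= len(arr) - plen:
                    cands.add(start)
        if not any_seed:
            # degenerate all-N seeds: fall back to a full scan
            cands.update(range(0, len(arr) - plen + 1))
        return cands

    def find(self, read_arr: np.ndarray, max_mm: int) -> list[tuple[str, int, str, int]]:
        """All placements (chrom, start, strand, mismatches) with mm <= max_mm."""
        placements = []
        rc = revcomp_arr(read_arr)
        for chrom, arr in self.arrays.items():
            if len(read_arr) > len(arr):
                continue
            for strand, pattern in (("+", read_arr), ("-", rc)):
                for start in self._candidates(chrom, pattern, max_mm):
                    window = arr[start : start + len(pattern)]
                    mm = int(np.count_nonzero(
                        (window != pattern) | (window == N_CODE) | (pattern == N_CODE)
                    ))
                    if mm <= max_mm:
                        placements.append((chrom, start, strand, mm))
        placements.sort()
        return placements


def _validate_read(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty read")
    bad = set(seq.upper()) - _VALID_BASES
    if bad:
        raise ValueError(f"{label}: non-ACGTN symbols {sorted(bad)}")


def place_reads(
    genome: dict[str, str] | GenomeSearcher,
    read_pairs: list[tuple[str, str, str]],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_insert: int = DEFAULT_MAX_INSERT,
    protocol: str = "read1-antisense",
) -> list[AlignedPair]:
    """Place read pairs exhaustively; retain only strict-best placements.

    ``read_pairs`` is ``(fragment_id, read1_seq, read2_seq)``.  A pair is
    concordant when both mates sit on the same chromosome on opposite
    strands, facing inward, with a fragment span <= ``max_insert``.  The
    pair is unique iff exactly one concordant placement attains the minimal
    total mismatch count; on ties the pair is reported with
    ``unique=False`` at the lexicographically first best placement.  Pairs
    with no concordant placement are dropped.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown strand protocol {protocol!r}; supported: {PROTOCOLS}")
    searcher = genome if isinstance(genome, GenomeSearcher) else GenomeSearcher(genome)

    out: list[AlignedPair] = []
    for frag_id, seq1, seq2 in read_pairs:
        _validate_read(seq1, frag_id)
        _validate_read(seq2, frag_id)
        placements = _best_concordant(
            searcher, encode(seq1.upper()), encode(seq2.upper()),
            max_mismatches, max_insert,
        )
        if not placements:
            continue
        (chrom, start, end, s1, span1, span2, mm) = placements[0]
        out.append(AlignedPair(
            fragment_id=frag_id, chrom=chrom, start=start, end=end,
            read1_strand=s1,
            fragment_strand=fragment_strand_for(s1, protocol),
            unique=len(placements) == 1,
            mate_spans=tuple(sorted((span1, span2))),
            mismatches=mm,
        ))
    return out


def _best_concordant(searcher, arr1, arr2, max_mm, max_insert):
    """All minimal-total-mismatch concordant placements, sorted."""
    p1 = searcher.find(arr1, max_mm)
    p2 = searcher.find(arr2, max_mm)
    by_chrom2: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, start, strand, mm in p2:
        by_chrom2.setdefault((chrom, strand), []).append((start, mm))
    best: list = []
    best_mm = None
    for chrom, start1, strand1, mm1 in p1:
        other = "-" if strand1 == "+" else "+"
        for start2, mm2 in by_chrom2.get((chrom, other), []):
            end1, end2 = start1 + len(arr1), start2 + len(arr2)
            lo, hi = min(start1, start2), max(end1, end2)
            if hi - lo > max_insert:
                continue
            # inward: the + mate must be the leftmost
            plus_start = start1 if strand1 == "+" else start2
            minus_start = start2 if strand1 == "+" else start1
            if plus_start > minus_start:
                continue
            total = mm1 + mm2
            cand = (chrom, lo, hi, strand1, (start1, end1), (start2, end2), total)
            if best_mm is None or total < best_mm:
                best, best_mm = [cand], total
            elif total == best_mm:
                best.append(cand)
    best.sort()
    return best


# -- SAM writing (used by the simulator and tests) ---------------------------

def write_sam(
    path: str | Path,
    chrom_lengths: dict[str, int],
    rows: list[tuple],
    sample: SampleStats,
) -> None:
    """Write already-placed concordant pairs as SAM.

    Each row is ``(qname, chrom, r1_start, r1_strand, r1_seq, r2_start,
    r2_strand, r2_seq, nh)`` with sequences given as forward-strand genome
    text (SAM convention).  Sample metadata goes into an ``@CO`` line that
    :func:`read_alignments` round-trips.
    """
    refs = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
        "CO": [
            "l1locus sample_id={} stranded={} compartment={}".format(
                sample.sample_id, str(sample.stranded).lower(), sample.compartment
            )
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for qname, chrom, s1, st1, seq1, s2, st2, seq2, nh in rows:
            tid = refs.index(chrom)
            lo = min(s1, s2)
            hi = max(s1 + len(seq1), s2 + len(seq2))
            tlen = hi - lo
            for is_read1, (start, strand, seq, ostrand) in (
                (True, (s1, st1, seq1, st2)),
                (False, (s2, st2, seq2, st1)),
            ):
                a = pysam.AlignedSegment()
                a.query_name = qname
                a.reference_id = tid
                a.reference_start = start
                a.mapping_quality = 255 if nh == 1 else 0
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = seq
                a.flag = (
                    0x1 | 0x2
                    | (0x40 if is_read1 else 0x80)
                    | (0x10 if strand == "-" else 0)
                    | (0x20 if ostrand == "-" else 0)
                )
                a.next_reference_id = tid
                a.next_reference_start = s2 if is_read1 else s1
                a.template_length = tlen if start == lo else -tlen
                a.set_tag("NH", int(nh))
                fh.write(a)
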
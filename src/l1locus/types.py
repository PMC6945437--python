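"""Domain types shared across the pipeline.

Coordinates are 0-based half-open throughout the package; GFF3 I/O converts
to and from the 1-based inclusive convention at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-")


def _check_interval(start: int, end: int) -> None:
    if not start < end:
        raise ValueError(f"interval start must be < end, got [{start}, {end})")


def _check_strand(strand: str) -> None:
    if strand not in STRANDS:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker-style repeat interval."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    id: str

    def __post_init__(self):
        _check_interval(self.start, self.end)
        _check_strand(self.strand)
        if not self.family:
            raise ValueError("repeat family must be non-empty")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterHit:
    """A promoter-sequence search hit on the genome."""

    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    query_coverage: float

    def __post_init__(self):
        _check_interval(self.start, self.end)
        _check_strand(self.strand)
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("query_coverage must lie in [0, 1]")


@dataclass(frozen=True)
class L1Locus:
    """A full-length L1 interval with an intact promoter.

    ``locus_id`` is stable and derived from coordinates
    (``chrom:start-end:strand``).  The 5' end in element orientation is
    ``start`` for ``+`` loci and ``end`` for ``-`` loci.
    """

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    locus_id: str
    promoter_intact: bool = True

    def __post_init__(self):
        _check_interval(self.start, self.end)
        _check_strand(self.strand)
        if not self.promoter_intact:
            raise ValueError("final annotation only holds promoter-intact loci")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genome coordinate of the element-space 5' start (a point)."""
        return self.start if self.strand == "+" else self.end

    def upstream_window(self, size: int, chrom_len: int | None = None) -> tuple[int, int]:
        """Strand-aware upstream window of ``size`` bp, clipped at 0 / chrom end."""
        if self.strand == "+":
            lo, hi = max(0, self.start - size), self.start
        else:
            lo, hi = self.end, self.end + size
            if chrom_len is not None:
                hi = min(hi, chrom_len)
        return lo, hi

    @staticmethod
    def make_id(chrom: str, start: int, end: int, strand: str) -> str:
        return f"{chrom}:{start}-{end}:{strand}"


@dataclass
class AlignedPair:
    """One concordantly aligned paired-end fragment."""

    fragment_id: str
    chrom: str
    start: int
    end: int
    read1_strand: str
    fragment_strand: str
    unique: bool
    mate_spans: tuple[tuple[int, int], tuple[int, int]]
    mismatches: int = 0

    def __post_init__(self):
        _check_interval(self.start, self.end)
        _check_strand(self.read1_strand)
        _check_strand(self.fragment_strand)
        for s, e in self.mate_spans:
            if s < self.start or e > self.end:
                raise ValueError("mate spans must lie within the fragment span")


@dataclass
class SampleStats:
    """Per-sample metadata, including the FPKM depth denominator."""

    sample_id: str
    million_mapped: float
    stranded: bool
    compartment: str = "unknown"

    def __post_init__(self):
        # zero is tolerated for freshly ingested empty samples; FPKM
        # normalisation rejects it where it would divide by zero
        if self.million_mapped < 0:
            raise ValueError("million_mapped must be non-negative")
        if self.compartment not in ("cytoplasmic", "whole_cell", "nuclear", "unknown"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass
class CoverageRecord:
    """Per-locus read counts over the locus and its upstream windows.

    For records produced by stranded counting, ``unstranded_reads`` always
    equals ``sense_reads + antisense_reads``.  Records produced in
    unstranded mode carry only ``unstranded_reads`` (sense/antisense stay 0
    because the orientation is withheld).
    """

    locus_id: str
    sense_reads: int = 0
    antisense_reads: int = 0
    unstranded_reads: int = 0
    upstream_sense_1k: int = 0
    upstream_sense_5k: int = 0
    upstream_unstranded_1k: int = 0
    upstream_unstranded_5k: int = 0

    def __post_init__(self):
        for name in (
            "sense_reads", "antisense_reads", "unstranded_reads",
            "upstream_sense_1k", "upstream_sense_5k",
            "upstream_unstranded_1k", "upstream_unstranded_5k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.upstream_sense_1k > self.upstream_sense_5k:
            raise ValueError("1 kb upstream count cannot exceed the 5 kb count")
        if self.upstream_unstranded_1k > self.upstream_unstranded_5k:
            raise ValueError("1 kb upstream count cannot exceed the 5 kb count")

    def reads(self, stranded: bool) -> int:
        """The curation read metric: sense reads (stranded) or all reads."""
        return self.sense_reads if stranded else self.unstranded_reads

    def upstream(self, window: int, stranded: bool) -> int:
        if window == 1000:
            return self.upstream_sense_1k if stranded else self.upstream_unstranded_1k
        if window == 5000:
            return self.upstream_sense_5k if stranded else self.upstream_unstranded_5k
        raise ValueError(f"unsupported upstream window {window}")


@dataclass
class GeneModel:
    """A gene with exon/intron structure; introns are the gaps between exons."""

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self):
        _check_strand(self.strand)
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in self.exons:
            _check_interval(s, e)
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be disjoint")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 > e1
        ]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


# Curation reason codes, in rule order.
PASS = "PASS"
PASS_PROXIMAL_EXCEPTION = "PASS_PROXIMAL_EXCEPTION"
BELOW_READ_THRESHOLD = "BELOW_READ_THRESHOLD"
UPSTREAM_UNMAPPABLE = "UPSTREAM_UNMAPPABLE"
UPSTREAM_SENSE_READS = "UPSTREAM_SENSE_READS"
BROAD_UNANNOTATED_NEIGHBORHOOD = "BROAD_UNANNOTATED_NEIGHBORHOOD"
PATTERN_MAPPABILITY_MISMATCH = "PATTERN_MAPPABILITY_MISMATCH"

ACCEPT_REASONS = frozenset({PASS, PASS_PROXIMAL_EXCEPTION})
REJECT_REASONS = frozenset({
    BELOW_READ_THRESHOLD,
    UPSTREAM_UNMAPPABLE,
    UPSTREAM_SENSE_READS,
    BROAD_UNANNOTATED_NEIGHBORHOOD,
    PATTERN_MAPPABILITY_MISMATCH,
})


@dataclass
class CurationCall:
    """Accept/reject verdict for one candidate locus with a reason code."""

    locus_id: str
    verdict: str  # "authentic" | "rejected"
    reason: str
    asp_active: bool = False
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.verdict not in ("authentic", "rejected"):
            raise ValueError(f"bad verdict {self.verdict!r}")
        if self.reason not in ACCEPT_REASONS | REJECT_REASONS:
            raise ValueError(f"unknown reason code {self.reason!r}")
        if (self.verdict == "authentic") != (self.reason in ACCEPT_REASONS):
            raise ValueError("verdict and reason code disagree")


@dataclass
class NeighborhoodProfile:
    """Binned strand-matched coverage around a locus, for the curation rules.

    ``upstream_bins``/``downstream_bins`` run outward from the element-space
    5'/3' edges.  ``upstream_read_offsets`` holds, for every counted upstream
    fragment (overlapping the 5 kb window but not the locus), the distance
    from the locus 5' start to the fragment edge nearest the locus.
    """

    locus_id: str
    bin_size: int
    upstream_bins: np.ndarray
    downstream_bins: np.ndarray
    locus_bins: np.ndarray
    upstream_read_offsets: list[int]
    upstream_gene_bins: np.ndarray  # bool: bin overlaps an annotated same-strand gene
    downstream_gene_bins: np.ndarray
    upstream_mappable_frac: float
    locus_mappable_frac: float
    locus_bin_mappable: np.ndarray  # bool per locus bin: majority-mappable

    def __post_init__(self):
        if np.any(self.upstream_bins < 0) or np.any(self.downstream_bins < 0):
            raise ValueError("bin counts must be non-negative")


@dataclass
class MappabilityTrack:
    """Per-base boolean unique-mappability arrays, one per chromosome."""

    read_length: int
    arrays: dict[str, np.ndarray]

    def fraction(self, chrom: str, start: int, end: int) -> float:
        arr = self.arrays[chrom]
        if start < 0 or end > len(arr) or start >= end:
            raise ValueError(f"interval [{start}, {end}) outside {chrom}")
        return float(np.count_nonzero(arr[start:end])) / (end - start)
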
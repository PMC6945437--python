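"""Comparative reports: overlaps, curation burden, stranded-vs-unstranded
confusion categories, upstream-filter evaluation, subfamily distributions.

Percentages are reported at one decimal; the integer-rounded figures that
headline summaries use are provided alongside where relevant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .types import CoverageRecord, CurationCall, L1Locus

log = logging.getLogger(__name__)

# subfamilies reported individually; everything else collapses to "Other"
NAMED_SUBFAMILIES = (
    "L1HS", "L1PA2", "L1PA3", "L1PA4", "L1PA5", "L1PA6", "L1PA7", "L1PA8",
)


@dataclass
class OverlapReport:
    """Two-set overlap accounting (a proportional Venn in table form)."""

    shared: int
    only_a: int
    only_b: int

    @property
    def total_distinct(self) -> int:
        return self.shared + self.only_a + self.only_b


@dataclass
class ConfusionReport:
    """Unstranded-vs-stranded curation outcome categories.

    ``true``: accepted in both; ``false``: rejected in both;
    ``false_positive``: accepted unstranded without stranded sense support;
    ``false_negative``: authentic per stranded calls but rejected
    unstranded (strand-blind upstream reads mimic co-transcription).
    Counts are kept for loci and for reads.
    """

    true_loci: int
    false_loci: int
    false_positive_loci: int
    false_negative_loci: int
    true_reads: int = 0
    false_reads: int = 0
    false_positive_reads: int = 0
    false_negative_reads: int = 0
    locus_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total_loci(self) -> int:
        return (self.true_loci + self.false_loci
                + self.false_positive_loci + self.false_negative_loci)

    @property
    def total_reads(self) -> int:
        return (self.true_reads + self.false_reads
                + self.false_positive_reads + self.false_negative_reads)


@dataclass
class FilterEvaluation:
    """Cross-tabulation of curation verdict x upstream-read partition."""

    window: int
    true_zero_upstream: int
    true_has_upstream: int
    false_has_upstream: int
    false_zero_upstream: int

    @property
    def total(self) -> int:
        return (self.true_zero_upstream + self.true_has_upstream
                + self.false_has_upstream + self.false_zero_upstream)

    @property
    def percent_reduction(self) -> float:
        """Curation workload removed: false loci auto-filtered / all curated."""
        if self.total == 0:
            return 0.0
        return round(100.0 * self.false_has_upstream / self.total, 1)

    @property
    def percent_authentic_lost(self) -> float:
        n_auth = self.true_zero_upstream + self.true_has_upstream
        if n_auth == 0:
            return 0.0
        return round(100.0 * self.true_has_upstream / n_auth, 1)


def overlap_sets(calls_a: set[str], calls_b: set[str]) -> OverlapReport:
    """Set algebra between two authentic locus-ID sets."""
    a, b = set(calls_a), set(calls_b)
    return OverlapReport(
        shared=len(a & b), only_a=len(a - b), only_b=len(b - a),
    )


@dataclass
class CurationBurden:
    curated_loci: int
    authentic_loci: int
    curated_reads: int
    authentic_reads: int

    @property
    def percent_authentic_loci(self) -> float:
        if self.curated_loci == 0:
            return 0.0
        return round(100.0 * self.authentic_loci / self.curated_loci, 1)

    @property
    def percent_authentic_reads(self) -> float:
        if self.curated_reads == 0:
            return 0.0
        return round(100.0 * self.authentic_reads / self.curated_reads, 1)


def curation_burden(
    calls: list[CurationCall],
    records: dict[str, CoverageRecord],
    stranded: bool = True,
) -> CurationBurden:
    """How much curation was needed and what fraction survived it."""
    if not calls:
        log.warning("curation burden over zero candidates")
        return CurationBurden(0, 0, 0, 0)
    authentic = [c for c in calls if c.verdict == "authentic"]
    reads = lambda c: records[c.locus_id].reads(stranded)
    return CurationBurden(
        curated_loci=len(calls),
        authentic_loci=len(authentic),
        curated_reads=sum(reads(c) for c in calls),
        authentic_reads=sum(reads(c) for c in authentic),
    )


def unstranded_confusion(
    unstranded_calls: list[CurationCall],
    stranded_calls: list[CurationCall],
    records_unstranded: dict[str, CoverageRecord],
) -> ConfusionReport:
    """Classify each candidate by agreement between the two curation modes.

    Both call sets must derive from the same sample's alignments; the
    candidate universes may differ (unstranded counting pools antisense
    reads, so it generally curates more loci) and the union is classified.
    Read tallies use the unstranded read counts, the metric of the
    unstranded analysis being evaluated.
    """
    s_auth = {c.locus_id for c in stranded_calls if c.verdict == "authentic"}
    s_all = {c.locus_id for c in stranded_calls}
    u_auth = {c.locus_id for c in unstranded_calls if c.verdict == "authentic"}
    u_all = {c.locus_id for c in unstranded_calls}
    universe = sorted(s_all | u_all)
    missing = [lid for lid in universe if lid not in records_unstranded]
    if missing:
        raise ValueError(f"candidate universes disagree with records: {missing[:5]}")

    cats: dict[str, list[str]] = {
        "true": [], "false": [], "false_positive": [], "false_negative": [],
    }
    for lid in universe:
        if lid in s_auth:
            cats["true" if lid in u_auth else "false_negative"].append(lid)
        else:
            cats["false_positive" if lid in u_auth else "false"].append(lid)

    nreads = lambda ids: sum(records_unstranded[l].unstranded_reads for l in ids)
    return ConfusionReport(
        true_loci=len(cats["true"]),
        false_loci=len(cats["false"]),
        false_positive_loci=len(cats["false_positive"]),
        false_negative_loci=len(cats["false_negative"]),
        true_reads=nreads(cats["true"]),
        false_reads=nreads(cats["false"]),
        false_positive_reads=nreads(cats["false_positive"]),
        false_negative_reads=nreads(cats["false_negative"]),
        locus_ids=cats,
    )


def evaluate_upstream_filter(
    calls: list[CurationCall],
    records: dict[str, CoverageRecord],
    window: int,
    stranded: bool = True,
) -> FilterEvaluation:
    """Would filtering on zero upstream reads have replaced curation?

    ``percent_reduction`` is the share of the curated candidates that the
    filter removes and that were indeed false; ``percent_authentic_lost``
    is the share of authentic loci the filter would discard.
    """
    if window not in (1000, 5000):
        raise ValueError(f"unsupported window {window}; use 1000 or 5000")
    cells = dict(tz=0, th=0, fh=0, fz=0)
    for c in calls:
        has = records[c.locus_id].upstream(window, stranded) > 0
        if c.verdict == "authentic":
            cells["th" if has else "tz"] += 1
        else:
            cells["fh" if has else "fz"] += 1
    return FilterEvaluation(
        window=window,
        true_zero_upstream=cells["tz"],
        true_has_upstream=cells["th"],
        false_has_upstream=cells["fh"],
        false_zero_upstream=cells["fz"],
    )


def subfamily_distribution(
    authentic: list[L1Locus],
    annotation: list[L1Locus],
    named: tuple[str, ...] = NAMED_SUBFAMILIES,
) -> dict[str, dict[str, float]]:
    """Per-subfamily proportions among authentic vs annotated loci.

    Subfamilies outside ``named`` collapse to "Other".  Enrichment is the
    ratio authentic-proportion / annotation-proportion; NaN marks
    undefined ratios (reported downstream as NA).
    """
    def bucket(sub: str) -> str:
        return sub if sub in named else "Other"

    def props(loci: list[L1Locus]) -> dict[str, float]:
        counts: dict[str, int] = {}
        for l in loci:
            counts[bucket(l.subfamily)] = counts.get(bucket(l.subfamily), 0) + 1
        total = sum(counts.values())
        keys = [*named, "Other"]
        return {k: (counts.get(k, 0) / total if total else 0.0) for k in keys}

    p_auth = props(authentic)
    p_ann = props(annotation)
    out: dict[str, dict[str, float]] = {}
    for k in [*named, "Other"]:
        if p_ann[k] > 0 and authentic:
            enr = p_auth[k] / p_ann[k]
        else:
            enr = math.nan
        out[k] = {
            "annotation": round(p_ann[k], 4),
            "authentic": round(p_auth[k], 4),
            "enrichment": round(enr, 4) if not math.isnan(enr) else math.nan,
        }
    return out
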
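"""End-to-end orchestration: annotation -> mappability -> per-sample
quantification and curation -> cross-sample comparison reports.

This is the library engine behind the command-line interface; each stage is
also callable on its own.  Outputs are TSV/JSON with a manifest recording
input hashes and parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import alignio, annotation, compare, curation, io, mappability, quantify
from .curation import CurationParams
from .types import (
    AlignedPair, CoverageRecord, CurationCall, GeneModel, L1Locus,
    MappabilityTrack, SampleStats,
)

log = logging.getLogger(__name__)


@dataclass
class SampleAnalysis:
    """Everything the pipeline derived from one sample in one mode."""

    sample_id: str
    mode: str  # "stranded" | "unstranded"
    stats: SampleStats
    records: dict[str, CoverageRecord]
    calls: list[CurationCall]
    authentic: set[str] = field(init=False)

    def __post_init__(self):
        self.authentic = {c.locus_id for c in self.calls if c.verdict == "authentic"}

    @property
    def calls_by_id(self) -> dict[str, CurationCall]:
        return {c.locus_id: c for c in self.calls}


def analyze_sample(
    pairs: list[AlignedPair],
    stats: SampleStats,
    loci: list[L1Locus],
    track: MappabilityTrack,
    genes: list[GeneModel],
    params: CurationParams = CurationParams(),
    mode: str = "stranded",
    candidates: dict[str, bool] | None = None,
) -> SampleAnalysis:
    """Quantify and curate one sample's unique fragments in one mode."""
    unique = alignio.filter_unique_concordant(pairs)
    chrom_lengths = {c: len(a) for c, a in track.arrays.items()}
    records = quantify.coverage(unique, loci, mode=mode, chrom_lengths=chrom_lengths)
    calls = curation.curate_sample(
        loci, unique, records, track, genes, params,
        stranded=(mode == "stranded"), candidates=candidates,
    )
    return SampleAnalysis(
        sample_id=stats.sample_id, mode=mode, stats=stats,
        records={r.locus_id: r for r in records}, calls=calls,
    )


def build_annotation_stage(
    genome: dict[str, str],
    repeats,
    query: str,
    min_identity: float = annotation.DEFAULT_MIN_IDENTITY,
    min_query_coverage: float = annotation.DEFAULT_MIN_QUERY_COVERAGE,
    full_length_min: int = annotation.DEFAULT_FULL_LENGTH_MIN,
    promoter_window: int = annotation.DEFAULT_PROMOTER_WINDOW,
) -> list[L1Locus]:
    hits = annotation.find_promoter_hits(
        genome, query, min_identity=min_identity,
        min_query_coverage=min_query_coverage,
    )
    return annotation.build_full_length_annotation(
        repeats, hits, full_length_min=full_length_min,
        promoter_window=promoter_window,
    )


@dataclass
class PipelineResult:
    loci: list[L1Locus]
    track: MappabilityTrack
    stranded: dict[str, SampleAnalysis]
    unstranded: dict[str, SampleAnalysis]
    comparison: dict


def run_pipeline(
    genome: dict[str, str],
    repeats,
    query: str,
    genes: list[GeneModel],
    sam_paths: dict[str, str | Path],
    params: CurationParams = CurationParams(),
    read_length: int = mappability.DEFAULT_READ_LENGTH,
    dialect: str = "NH",
    protocol: str = "read1-antisense",
    run_unstranded: bool = True,
    loci: list[L1Locus] | None = None,
) -> PipelineResult:
    """The full analysis over a set of SAM/BAM samples.

    Every sample is analysed in stranded mode and (optionally) re-analysed
    with strand information withheld, enabling the stranded-vs-unstranded
    confusion report on identical alignments.
    """
    if loci is None:
        loci = build_annotation_stage(genome, repeats, query)
    log.info("annotation: %d full-length promoter-intact loci", len(loci))
    track = mappability.compute_mappability(genome, read_length=read_length)

    stranded: dict[str, SampleAnalysis] = {}
    unstranded: dict[str, SampleAnalysis] = {}
    for sample_id, path in sam_paths.items():
        pairs, stats, _skips = alignio.read_alignments(
            path, dialect=dialect, protocol=protocol,
        )
        stats.sample_id = sample_id
        stranded[sample_id] = analyze_sample(
            pairs, stats, loci, track, genes, params, mode="stranded",
        )
        if run_unstranded:
            unstranded[sample_id] = analyze_sample(
                pairs, stats, loci, track, genes, params, mode="unstranded",
            )

    comparison = build_comparison(loci, stranded, unstranded, params)
    return PipelineResult(
        loci=loci, track=track, stranded=stranded, unstranded=unstranded,
        comparison=comparison,
    )


def build_comparison(
    loci: list[L1Locus],
    stranded: dict[str, SampleAnalysis],
    unstranded: dict[str, SampleAnalysis],
    params: CurationParams,
) -> dict:
    """Cross-sample and cross-mode report block (JSON-serialisable)."""
    out: dict = {"samples": {}, "overlaps": {}, "confusion": {}}
    by_id = {l.locus_id: l for l in loci}
    for sid, ana in stranded.items():
        burden = compare.curation_burden(ana.calls, ana.records, stranded=True)
        evals = {}
        for w in (1000, 5000):
            ev = compare.evaluate_upstream_filter(ana.calls, ana.records, w)
            evals[w] = asdict(ev) | {
                "percent_reduction": ev.percent_reduction,
                "percent_authentic_lost": ev.percent_authentic_lost,
            }
        authentic_loci = [by_id[l] for l in sorted(ana.authentic)]
        out["samples"][sid] = {
            "stranded_burden": asdict(burden) | {
                "percent_authentic_loci": burden.percent_authentic_loci,
                "percent_authentic_reads": burden.percent_authentic_reads,
            },
            "upstream_filter": evals,
            "n_authentic": len(ana.authentic),
            "asp_active": sorted(
                c.locus_id for c in ana.calls if c.asp_active
            ),
            "subfamily_distribution": compare.subfamily_distribution(
                authentic_loci, loci,
            ),
        }
        if sid in unstranded:
            u = unstranded[sid]
            conf = compare.unstranded_confusion(u.calls, ana.calls, u.records)
            uburden = compare.curation_burden(u.calls, u.records, stranded=False)
            out["confusion"][sid] = {
                "loci": {
                    "true": conf.true_loci, "false": conf.false_loci,
                    "false_positive": conf.false_positive_loci,
                    "false_negative": conf.false_negative_loci,
                    "total": conf.total_loci,
                },
                "reads": {
                    "true": conf.true_reads, "false": conf.false_reads,
                    "false_positive": conf.false_positive_reads,
                    "false_negative": conf.false_negative_reads,
                    "total": conf.total_reads,
                },
                "unstranded_burden": asdict(uburden) | {
                    "percent_authentic_loci": uburden.percent_authentic_loci,
                },
                "n_authentic_unstranded": len(u.authentic),
            }
    sids = sorted(stranded)
    for i, a in enumerate(sids):
        for b in sids[i + 1:]:
            rep = compare.overlap_sets(stranded[a].authentic, stranded[b].authentic)
            out["overlaps"][f"{a}|{b}"] = asdict(rep) | {
                "total_distinct": rep.total_distinct,
            }
    return out


# -- report files ------------------------------------------------------------

def write_coverage_tsv(
    ana: SampleAnalysis,
    loci: list[L1Locus],
    path: str | Path,
    locus_kb: float = quantify.DEFAULT_LOCUS_KB,
) -> None:
    """Per-locus counts + FPKM table (stranded layout)."""
    stranded = ana.mode == "stranded"
    with open(path, "w") as fh:
        fh.write("locus_id\tsubfamily\tsense\tantisense\tunstranded"
                 "\tupstream_1k\tupstream_5k\tfpkm\n")
        for loc in loci:
            r = ana.records[loc.locus_id]
            reads = r.reads(stranded)
            val = (quantify.fpkm(reads, ana.stats, locus_kb)
                   if ana.stats.million_mapped > 0 else 0.0)
            fh.write(
                f"{loc.locus_id}\t{loc.subfamily}\t{r.sense_reads}"
                f"\t{r.antisense_reads}\t{r.unstranded_reads}"
                f"\t{r.upstream(1000, stranded)}\t{r.upstream(5000, stranded)}"
                f"\t{val:.6g}\n"
            )


def write_curation_tsv(ana: SampleAnalysis, path: str | Path) -> None:
    """The machine analogue of a curated locus table with verdict colours."""
    with open(path, "w") as fh:
        fh.write("locus_id\tverdict\treason\tasp_active\tmetrics\n")
        for c in ana.calls:
            metrics = ";".join(f"{k}={v}" for k, v in sorted(c.metrics.items()))
            fh.write(f"{c.locus_id}\t{c.verdict}\t{c.reason}"
                     f"\t{int(c.asp_active)}\t{metrics}\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, inputs: dict[str, str | Path],
                   params: dict, outputs: list[str]) -> None:
    from . import __version__

    manifest = {
        "version": __version__,
        "inputs": {k: {"path": str(p), "sha256": file_sha256(p)}
                   for k, p in inputs.items() if Path(p).exists()},
        "parameters": params,
        "outputs": sorted(str(o) for o in outputs),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def write_reports(
    result: PipelineResult,
    out_dir: str | Path,
    inputs: dict[str, str | Path] | None = None,
    params: dict | None = None,
) -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    p = out_dir / "loci.gff3"
    io.write_loci_gff3(result.loci, p)
    outputs.append(str(p))
    for sid, ana in result.stranded.items():
        p = out_dir / f"coverage_{sid}.tsv"
        write_coverage_tsv(ana, result.loci, p)
        outputs.append(str(p))
        p = out_dir / f"curation_{sid}.tsv"
        write_curation_tsv(ana, p)
        outputs.append(str(p))
    for sid, ana in result.unstranded.items():
        p = out_dir / f"curation_{sid}.unstranded.tsv"
        write_curation_tsv(ana, p)
        outputs.append(str(p))
    p = out_dir / "comparison.json"
    with open(p, "w") as fh:
        json.dump(result.comparison, fh, indent=2, sort_keys=True)
    outputs.append(str(p))
    write_manifest(out_dir / "manifest.json", inputs or {}, params or {}, outputs)
    outputs.append(str(out_dir / "manifest.json"))
    return outputs
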
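# l1locus

Locus-specific LINE-1 (L1) expression analysis from paired-end RNA-seq.

## The problem

L1 is the only autonomous human retrotransposon; its ~500,000 genomic
copies mean that L1 sequence appears in RNA-seq data constantly — inside
gene introns and exons, in readthrough transcripts, and from the L1
antisense promoter — while only a handful of full-length loci are actually
transcribed from their own promoter. Those promoter-driven sense
transcripts are the only ones that matter for the retrotransposition life
cycle, and they are outnumbered by passive "background" L1 sequence by
more than 100:1. `l1locus` is a pipeline for calling **authentically
expressed** full-length L1 loci at single-locus resolution, for
transcriptomics researchers who want to know *which* L1 copies are
transcriptionally active in a sample rather than how much bulk L1 RNA it
contains.

The approach is deliberately stringent and rule-based:

1. **Annotation** — full-length loci (≥ 5.9 kb) whose element-space 5′ end
   matches the first 300 bp of an L1 consensus (the internal promoter),
   built by intersecting a RepeatMasker-style repeat list with
   promoter-sequence search hits.
2. **Unique mapping** — only concordant read pairs whose best placement
   strictly beats every alternative placement in the genome are kept. A
   built-in exhaustive placer provides this contract for desk-scale
   genomes; external SAM/BAM is accepted with uniqueness taken from
   aligner tags (`NH`, `XS`, or MAPQ).
3. **Quantification** — fragment counts per locus and per strand-aware
   1 kb / 5 kb upstream window; per-locus normalisation
   `FPKM = reads / (million mapped fragments × 6)` since full-length loci
   are all ~6 kb; housekeeping exon:intron ratios as a cytoplasmic-purity
   QC.
4. **Curation** — an ordered, deterministic rule set replacing visual
   review: reject loci below the read threshold, with unmappable upstream
   flanks, with same-strand reads in the 5 kb upstream window (except a
   few reads hugging the promoter start), bordering broad un-annotated
   expression, or with read pile-ups inconsistent with their mappability.
   Every call carries a machine-readable reason code, plus an independent
   antisense-promoter (ASP) activity flag.
5. **Comparison** — overlap accounting between samples, curation-burden
   metrics, upstream-filter automation estimates, subfamily enrichment,
   and the stranded-vs-unstranded confusion report (true / false /
   false-positive / false-negative loci and reads).

A ground-truthed simulator generates complete desk-scale scenarios —
diverged L1 subfamilies, genes with intronic elements, promoter-driven,
co-transcribed, readthrough, ASP and unannotated-upstream transcripts,
compartment-dependent intronic background — so every pipeline stage is
testable against known truth.

## Worked example

`examples/03_simulate_and_curate.py` builds a small scenario with one
locus of every transcript class and curates it:

```
10 annotated loci, 7 candidates curated

locus                        verdict    reason                       truth
chr1:143414-149414:-         rejected   UPSTREAM_SENSE_READS         unannotated_upstream
chr1:184402-190402:+         rejected   UPSTREAM_SENSE_READS         co_transcribed
chr1:255725-261725:-         rejected   UPSTREAM_SENSE_READS         readthrough
chr1:26811-32811:+           rejected   UPSTREAM_UNMAPPABLE          promoter_driven
chr1:334376-340376:-         authentic  PASS                         promoter_driven +ASP
chr1:352344-358344:+         rejected   UPSTREAM_SENSE_READS         co_transcribed
chr1:384246-390246:+         authentic  PASS                         promoter_driven

authentic called: 2  promoter-driven truth (mappable upstream): 2  agreement: True
```

Both promoter-driven loci with clean, mappable upstream flanks are
accepted (one also shows antisense-promoter activity); every locus covered
by another transcription unit is rejected by the upstream-reads rule, and
the promoter-driven locus whose upstream flank is unmappable cannot be
confidently called — exactly the judgement a manual curator would make.

`examples/04_stranded_vs_unstranded.py` re-analyses the same alignments
with strand withheld: the authentic set shrinks from 7 to 6 loci, all
three ASP-coupled authentic loci become false negatives, and two
antisense-only loci become false positives — the mechanism by which
unstranded libraries lose and fabricate L1 calls.

The other examples demonstrate annotation construction
(`01_build_annotation.py`) and the divergence-dependence of unique
mappability (`02_mappability.py`: identical copies are 5% mappable;
at 2% divergence, 99%).

## Command line

```sh
l1locus simulate --out-dir sim --seed 1
l1locus run-all --genome sim/genome.fa --repeats sim/repeats.gff3 \
    --query sim/query.fa --genes sim/genes.gff3 \
    --sam sim/whole_cell_1.sam --out-dir results
```

`run-all` writes the locus annotation (GFF3), per-sample coverage and
curation TSVs, a comparison JSON and a manifest with input hashes.
Individual stages (`build-annotation`, `mappability`, `quantify`,
`compare`) are also exposed.

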
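# Methods

This note documents the models, rules and numerical choices behind
`l1locus`: what each stage computes, the parameters that matter, what the
simulator does and does not emulate, and the known limitations.

## Coordinates and conventions

All internal coordinates are 0-based half-open; GFF3 I/O converts to
1-based inclusive at the file boundary. "Element space" orients an L1 by
its own transcription: the 5′ end is the genomic start for `+` loci and
the genomic end for `-` loci, and "upstream" always means 5′ of the
element in that orientation. Counting is fragment-level: one concordant
read pair contributes one count, with a ≥ 1 bp overlap rule (the default
semantics of interval-overlap counting tools).

## Full-length annotation

A repeat becomes a full-length, promoter-intact L1 locus when (a) its
family name matches the L1 family pattern (default: starts with `L1`),
(b) it is at least `full_length_min` = 5900 bp long (full-length L1 is
~6 kb), and (c) a same-strand promoter-sequence hit overlaps its
element-space first `promoter_window` = 300 bp — the span of the internal
promoter at the start of the consensus. Locus IDs are stable coordinate
strings (`chrom:start-end:strand`).

The promoter search is a seeded, ungapped scan: exact 12-mer seeds taken
every 4 bp of the query nominate candidate offsets, each candidate is
scored by full-query Hamming identity, and overlapping same-strand hits
are reduced by non-maximum suppression. Gapped alignment and E-value
statistics are not reproduced because the hit is used only as an interval.
Hits are full-length query placements, so query coverage is always 1.0;
the identity threshold (default 0.80, configurable) is the operative
filter. An indel in a promoter region shifts the downstream register and
depresses identity, so heavily rearranged promoters are (correctly) not
matched, but a single early indel can also hide an otherwise intact
promoter — a deliberate trade-off of the ungapped design.

## Unique-best concordant mapping

The mapping contract is: a pair is retained as *unique* iff exactly one
concordant placement attains the strictly minimal total mismatch count
over the whole genome. Concordance means both mates on one chromosome, on
opposite strands, facing inward, with a fragment span ≤ `max_insert`
(default 1000 bp).

The built-in placer implements this exhaustively for desk-scale genomes
using pigeonhole seeding: a mate placed with ≤ m mismatches must contain
an exact copy of one of m+1 disjoint segments, so exact k-mer lookups of
segment prefixes (sorted-array index, 2-bit codes, k ≤ 31) enumerate every
qualifying offset, which are then verified by vectorised Hamming counts.
This is exact — the test suite checks equivalence against a brute-force
all-offsets scan — and is used both as the desk-scale aligner and as the
uniqueness oracle for simulated reads. `max_mismatches` defaults to 2 per
mate; N never matches anything, including itself. Indels and base
qualities are out of scope.

External SAM/BAM is ingested without re-alignment; uniqueness is taken
from the file under a tag dialect: `NH` (unique iff NH ≤ 1, the default),
`XS` (unique iff the tag is absent), or `MAPQ` (unique iff both mates are
at or above a threshold, default 10). `million_mapped` is the unique
concordant pair count / 10⁶ and is the FPKM denominator.

The strand protocol is configurable; the default, `read1-antisense`,
is the dUTP convention of common strand-specific kits: the transcript
strand of a fragment is the strand of read 2.

## Mappability

The mappability track answers, per base: would an error-free read of
length L starting here place uniquely? A position is mappable when some
L-mer covering it occurs exactly once in the genome plus its reverse
complement; a palindromic L-mer counts once per orientation and is
therefore never unique. Tiled error-free L-mers replace real whole-genome
reads — a deterministic, download-free equivalent. Defaults: L = 100
(a typical short-read length), step = 1.

Implementation: dual 64-bit polynomial rolling hashes (moduli 2⁶¹−1 and a
second prime) of every window on both strands, multiplicities by sorting.
The collision probability at the default scale (~4 M windows) is ~10⁻⁶;
the test suite verifies exact agreement with a dictionary-based k-mer
counting oracle on small genomes.

## Quantification

Per locus: sense / antisense fragment counts (stranded mode) or a single
unstranded count (orientation withheld); strand-aware upstream window
counts at 1 kb and 5 kb, where a fragment counts toward a window only if
it overlaps the window *and not* the locus; windows truncate at chromosome
boundaries. A fragment overlapping two loci counts toward both (logged).

FPKM uses a fixed locus length of 6 kb — full-length loci are all
approximately that length, and a common denominator keeps per-locus values
comparable — so `FPKM = reads / (million_mapped × 6)`.

The exon:intron QC computes, per housekeeping gene, the ratio of
exon-overlapping to intron-overlapping fragments, with exon priority for
junction-spanning fragments (conservative for cytoplasmic purity: a
fragment touching any exon is treated as processed RNA). Genes with zero
intron fragments are excluded from the arithmetic mean and reported; if
every gene is excluded the ratio is undefined and an error is raised. Low
means indicate unprocessed nuclear RNA in the sample.

## Curation

Candidates are loci with ≥ `min_reads` = 10 reads (sense reads in
stranded mode, all reads in unstranded mode) in the sample — or in any
other sample of a replicate group, which "rescues" the locus into
candidacy. Rules are applied in a fixed order with first-match-wins so
reason attribution is deterministic:

* **R0 `BELOW_READ_THRESHOLD`** — fewer than `min_reads` reads and not
  group-rescued. (Rescued loci skip R0; otherwise grouping would be dead
  code.)
* **R2 `UPSTREAM_UNMAPPABLE`** — mappable fraction of the first
  `upstream_unmappable_window` = 1000 bp of upstream flank below
  `min_upstream_mappability` = 0.5: upstream transcription cannot be
  excluded when the flank is invisible to unique mapping.
* **R1 `UPSTREAM_SENSE_READS`** — any same-strand fragment in the 5 kb
  upstream window, **unless** the proximal exception applies: all upstream
  fragments lie within `proximal_window` = 200 bp of the promoter start
  *and* number at most `proximal_max_fraction` = 10% of the locus reads
  → `PASS_PROXIMAL_EXCEPTION` (transcription-start scatter around the
  promoter, not an upstream promoter).
* **R3 `BROAD_UNANNOTATED_NEIGHBORHOOD`** — a run of ≥ `broad_min_bins`
  = 2 consecutive flank bins (bin size 500 bp, ±5 kb), outside annotated
  same-strand genes and beyond the proximal window, each with coverage at
  least `neighborhood_ratio` = 0.5 × the locus per-bin mean: the locus
  sits inside a broader transcribed region that happens to lack
  annotation.
* **R4 `PATTERN_MAPPABILITY_MISMATCH`** — locus mappable fraction ≥ 0.9
  yet a single bin holds ≥ `pattern_peak_share` = 80% of the locus reads
  while at least half the mappable bins have zero coverage: a pile-up
  that mappability cannot explain.
* Otherwise **`PASS`**.

Flank bins count fragments overlapping the bin but not the locus; locus
bins assign each fragment once, by element-space midpoint, so a bin's
share of locus reads is a true proportion (this choice quantifies the
qualitative "pile of reads in the middle" criterion; overlap-counting
would let ordinary edge-spanning fragments inflate the peak share).

ASP detection is independent of the verdict and requires stranded data: a
locus is flagged `asp_active` when at least one antisense fragment
overlaps the element-space first `asp_utr_window` = 900 bp (the 5′UTR,
where the antisense promoter lives) and, together with antisense fragments
in the first 1 kb of upstream flank (the ASP transcript running out of the
element), they number ≥ `asp_min_reads` = 5. Because the flag is
independent, antisense-only loci are reported as ASP-active even though
they are rejected for sense expression — the uncoupled-ASP case.

The upstream filter (`upstream_filter` / `evaluate_upstream_filter`)
partitions candidates by zero vs non-zero upstream reads at 1 kb or 5 kb
and cross-tabulates against verdicts; it is the automation surrogate for
full curation. `percent_reduction` = false loci removed / all curated;
`percent_authentic_lost` = authentic loci removed / all authentic.
Percentages are reported at one decimal.

## Stranded-vs-unstranded comparison

Re-analysing the same alignments with orientation withheld pools sense and
antisense reads everywhere (locus counts, upstream windows, flank bins).
Each locus curated in either mode is classified by the 2×2 agreement
table: accepted in both (*true*), rejected in both (*false*), accepted
only unstranded (*false positive* — typically antisense-only loci whose
ASP reads masquerade as sense), rejected only unstranded (*false
negative* — typically authentic loci whose ASP flank reads masquerade as
upstream co-transcription). Read tallies use the unstranded counts, the
metric of the analysis being evaluated.

## The simulator

The generator emulates the data features the analysis must disentangle,
on a scale where the exhaustive placer is exact and fast. Defaults (the
standard study conditions): a 2 Mb genome; 5 subfamilies × 6 full-length
copies mutated from a stored 6 kb consensus at subfamily divergences of
2–15% (younger subfamilies more homogeneous, hence less mappable); 6
truncated 5′-less copies as negatives; 20 genes including 6 L1-free
housekeeping genes; 50,000 fragments per sample (fragment length
N(300, 50²) clipped to [160, 600], reads 100 bp, error-free, dUTP strand
flags); three samples — cytoplasmic, nuclear, and whole-cell as a 50:50
mixture of the two compartments' class weights.

Transcript classes: promoter-driven sense transcripts starting within
±100 bp of the locus 5′ start; gene pre-mRNAs spanning same- or
opposite-strand intronic copies (co-transcription); readthrough
transcripts extending a driver gene 1–2 kb past its terminator through a
downstream L1; ASP transcripts running antisense from 750–900 bp inside
the 5′UTR, either confined to the element (uncoupled ASP) or extending
400–1500 bp into the upstream flank (coupled); transcripts from an
unannotated promoter 1–4 kb upstream running through the element; spliced
housekeeping mRNA (exonic); and intronic background weighted into the
nuclear compartment (cytoplasmic class weights put 2% of fragments in
introns versus 30% nuclear, giving housekeeping exon:intron means of ~25
and ~0.4 respectively). One promoter-driven locus has its upstream 1 kb
duplicated elsewhere in the genome, making the flank unmappable — the R2
case. ASP geometry spans most of the 5′UTR so that an uncoupled ASP locus
presents, in unstranded mode, the read pattern a curator would accept
(the false-positive phenomenon), while coupled ASP flank reads trigger
the upstream rule (the false-negative phenomenon).

Uniqueness of every simulated pair is assigned by the exhaustive placer
against the simulated genome and written as an `NH` tag; fragment names
carry the source transcript and class, and per-locus truth labels
(authentic promoter-driven / co-transcribed-only / ASP-only / silent,
plus class detail) are written as TSV. Everything is deterministic per
seed, down to byte-identical SAM.

What the simulator does **not** emulate: sequencing errors and base
qualities (uniqueness logic, not error correction, is under study),
indels and structural variation within elements, polyA-selection
efficiency, RNA degradation, splice-junction fragments (mRNA fragments
are drawn within single exons), and real transcript-abundance
distributions (class weights are scenario parameters, not estimates of
any cell line). Passing tests therefore demonstrate the logic of the
pipeline under clean mapping conditions, not its robustness to alignment
artefacts in real data.

## Numerical and design choices

* Problem sizes: the default scenario (2 Mb, 3 × 50k fragments) runs the
  whole pipeline in about two minutes on one CPU; unit tests use smaller
  scenarios with one locus per class.
* Ties in the placer are resolved by discarding the pair's uniqueness and
  recording the lexicographically first best placement, so outputs are
  order-independent.
* The curation rule order (threshold → mappability → upstream → broad
  neighborhood → pattern) fixes reason attribution; visual curation
  applies the same criteria without an order.
* "Minimal reads" in the proximal exception is quantified as 10% of locus
  reads; "similar expression levels" in R3 as 50% of the locus per-bin
  mean over ≥ 2 consecutive 500 bp bins. Both are configurable and the
  defaults are stated, not learned.
* Upstream windows and flank bins truncate at chromosome boundaries;
  degenerate windows contribute zero counts and a mappable fraction of 0.
* A locus with zero reads can still be a group-rescued candidate; all its
  rules evaluate on zeros and it passes or fails on its flanks.

## Limitations

* Unique mapping systematically undercounts the youngest subfamilies;
  the mappability track quantifies but does not correct this (no
  fractional multi-mapper assignment by design).
* The ungapped promoter search misses promoters disrupted by early
  indels and cannot annotate polymorphic (non-reference) insertions.
* Curation thresholds are heuristics standing in for expert judgement;
  on real data they should be reviewed against a curated sample before
  being trusted at scale.
* The exhaustive placer is for desk-scale genomes (tens of Mb at most);
  real genome analyses should bring external alignments.
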
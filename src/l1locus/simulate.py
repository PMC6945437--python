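"""Ground-truthed synthetic data for the L1 expression pipeline.

The generator emulates the features of real data that the analysis has to
disentangle: full-length L1 copies of several subfamilies at subfamily-
dependent divergence from a consensus (younger subfamilies are harder to
map uniquely), genes hosting intronic L1s on either strand, and one
transcript population per origin class —

* ``promoter_driven``   sense transcripts starting at an L1's own promoter;
* ``co_transcribed``    gene pre-mRNAs spanning embedded same-strand L1s;
* ``readthrough``       transcription running past a gene terminator into a
                        downstream L1;
* ``asp``               antisense-promoter transcripts out of an L1 5'UTR,
                        either coupled to sense expression or uncoupled;
* ``unannotated_upstream``  transcripts from an unannotated promoter 1-4 kb
                        5' of an L1 running through it;
* ``gene_mrna``         spliced housekeeping output (exonic);
* ``intronic_background``  unspliced intron signal, weighted into the
                        nuclear compartment.

Fragments are written as already-placed concordant SAM pairs under the
dUTP protocol; each pair's uniqueness is assigned by the exhaustive placer
against the simulated genome.  Everything is deterministic per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import alignio
from ._seq import decode, revcomp
from .types import AlignedPair, GeneModel, L1Locus, RepeatFeature, SampleStats

log = logging.getLogger(__name__)

CHROM = "chr1"

# labels for per-locus ground truth
AUTHENTIC = "authentic_promoter_driven"
CO_ONLY = "co_transcribed_only"
ASP_ONLY = "asp_only"
SILENT = "silent"


def l1_consensus(length: int = 6000) -> str:
    """The stored L1 consensus all simulated copies descend from.

    Generated once from a fixed generator so the consensus — and hence the
    300-bp promoter query derived from it — is identical across runs and
    independent of the scenario seed.
    """
    rng = np.random.default_rng(0xC0FFEE)
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


@dataclass
class SimConfig:
    """Scenario parameters; the defaults are the standard study conditions.

    The toy scale (2 Mb genome, 30 full-length L1 copies, 20 genes, 50k
    fragments per sample) keeps a full multi-sample run in minutes while
    exercising every transcript class.
    """

    genome_length: int = 2_000_000
    seed: int = 0
    # subfamily -> divergence from consensus (older subfamilies drift more)
    subfamily_divergence: dict = field(default_factory=lambda: {
        "L1HS": 0.02, "L1PA2": 0.045, "L1PA3": 0.07, "L1PA4": 0.10, "L1PA5": 0.15,
    })
    copies_per_subfamily: int = 6
    n_truncated: int = 6
    n_genes: int = 20
    # class composition of the full-length copies
    n_promoter_driven: int = 8       # includes the asp-coupled loci
    n_asp_coupled: int = 3           # subset of promoter_driven
    n_unmappable_upstream: int = 1   # subset of promoter_driven
    n_asp_only: int = 2              # ASP without sense expression (uncoupled)
    n_co_transcribed: int = 5        # same-strand intronic
    n_intronic_opposite: int = 2     # opposite-strand intronic
    n_readthrough: int = 3
    n_unannotated_upstream: int = 3
    consensus_length: int = 6000
    promoter_query_length: int = 300
    # transcript class weights per compartment (fractions of fragments)
    class_weights: dict = field(default_factory=lambda: {
        "cytoplasmic": {
            "gene_mrna": 0.41, "promoter_driven": 0.20, "co_transcribed": 0.12,
            "readthrough": 0.08, "asp": 0.07, "unannotated_upstream": 0.10,
            "intronic_background": 0.02,
        },
        "nuclear": {
            "gene_mrna": 0.10, "promoter_driven": 0.10, "co_transcribed": 0.25,
            "readthrough": 0.10, "asp": 0.10, "unannotated_upstream": 0.05,
            "intronic_background": 0.30,
        },
    })
    # whole_cell = mixture of the two compartments
    compartment_mix: dict = field(default_factory=lambda: {
        "cytoplasmic": 0.5, "nuclear": 0.5,
    })
    fragments_per_sample: int = 50_000
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 50.0
    fragment_length_min: int = 160
    fragment_length_max: int = 600
    read_length: int = 100
    promoter_jitter: int = 100
    asp_coupled_ext: tuple = (400, 1500)  # upstream run-out of coupled ASP
    max_mismatches: int = 2
    max_insert: int = 1000

    def __post_init__(self):
        for comp, w in self.class_weights.items():
            tot = sum(w.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"class weights for {comp} sum to {tot}, not 1")
        if abs(sum(self.compartment_mix.values()) - 1.0) > 1e-6:
            raise ValueError("compartment mix must sum to 1")
        for name in ("n_asp_coupled", "n_unmappable_upstream"):
            if getattr(self, name) > self.n_promoter_driven:
                raise ValueError(f"{name} cannot exceed n_promoter_driven")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "asp_coupled_ext" in data:
            data["asp_coupled_ext"] = tuple(data["asp_coupled_ext"])
        return cls(**data)


@dataclass
class LocusTruth:
    locus_id: str
    label: str          # AUTHENTIC | CO_ONLY | ASP_ONLY | SILENT
    class_detail: str   # the generating transcript class (or "silent")
    asp_coupled: bool = False
    unmappable_upstream: bool = False


@dataclass
class SimGenome:
    """Genome artifacts plus the ground-truth skeleton."""

    genome: dict[str, str]
    repeats: list[RepeatFeature]
    genes: list[GeneModel]
    loci_truth: dict[str, LocusTruth]
    consensus: str
    promoter_query: str
    config: SimConfig

    def full_length_loci(self) -> list[L1Locus]:
        out = []
        for r in self.repeats:
            lid = L1Locus.make_id(r.chrom, r.start, r.end, r.strand)
            if lid in self.loci_truth:
                out.append(L1Locus(
                    chrom=r.chrom, start=r.start, end=r.end, strand=r.strand,
                    subfamily=r.family, locus_id=lid,
                ))
        return out


@dataclass
class Transcript:
    id: str
    tclass: str
    chrom: str
    start: int
    end: int
    strand: str
    weight: float
    locus_id: str | None = None
    gene: str | None = None


# -- genome construction -----------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = lut[int(arr[i])][rng.integers(0, 3)]
    return arr.tobytes().decode()


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n).astype(np.uint8))


@dataclass
class _Entity:
    """A sequence block to splice into the genome, with local features."""

    kind: str
    seq: str
    # features in entity-local coordinates
    repeats: list[tuple[int, int, str, str]] = field(default_factory=list)
    gene: tuple[str, str, list[tuple[int, int]]] | None = None  # name, strand, exons
    locus_class: list[tuple[int, str]] = field(default_factory=list)  # repeat idx, class


def _make_gene(rng, name: str, strand: str, host: str | None = None,
               l1_seq: str | None = None, l1_strand: str | None = None) -> _Entity:
    """A gene entity, optionally hosting a full-length L1 in an intron."""
    n_exons = int(rng.integers(3, 6))
    exon_lens = rng.integers(500, 1500, size=n_exons)
    intron_lens = rng.integers(1600, 3200, size=n_exons - 1)
    host_intron = int(rng.integers(0, n_exons - 1)) if host else None
    parts, exons, repeats, pos = [], [], [], 0
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        parts.append(_random_seq(rng, int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            ilen = int(intron_lens[i])
            if host_intron == i:
                # margin on both sides so the L1's element-space upstream
                # stays inside the intron
                m1 = int(rng.integers(1500, ilen - 1400)) if ilen > 2900 else 1500
                parts.append(_random_seq(rng, m1))
                repeats.append((pos + m1, pos + m1 + len(l1_seq), l1_strand, host))
                parts.append(l1_seq)
                parts.append(_random_seq(rng, 1500))
                pos += m1 + len(l1_seq) + 1500
            else:
                parts.append(_random_seq(rng, ilen))
                pos += ilen
    return _Entity(kind="gene", seq="".join(parts),
                   repeats=[(s, e, st, "") for s, e, st, _ in repeats],
                   gene=(name, strand, exons),
                   locus_class=[(0, host)] if host else [])


HOUSEKEEPING = ("B2M", "GAPDH", "GUSB", "HPRT", "PGK1", "TK1")


def simulate_genome(config: SimConfig) -> SimGenome:
    """Build the genome, repeat annotation, gene models and truth skeleton."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    consensus = l1_consensus(config.consensus_length)
    query = consensus[: config.promoter_query_length]

    # assign full-length copies to subfamilies and classes
    subs = list(config.subfamily_divergence)
    copies = [s for s in subs for _ in range(config.copies_per_subfamily)]
    rng.shuffle(copies)
    n_full = len(copies)
    classes = (
        ["promoter_driven"] * config.n_promoter_driven
        + ["asp_only"] * config.n_asp_only
        + ["co_transcribed"] * config.n_co_transcribed
        + ["intronic_opposite"] * config.n_intronic_opposite
        + ["readthrough"] * config.n_readthrough
        + ["unannotated_upstream"] * config.n_unannotated_upstream
    )
    if len(classes) > n_full:
        raise ValueError("more transcript classes requested than full-length copies")
    classes += ["silent"] * (n_full - len(classes))
    # promoter-driven loci need mappable bodies to reach the read
    # threshold, so keep them out of the youngest (most homogeneous)
    # subfamily where possible: sort copies old->young for assignment
    order = np.argsort([-config.subfamily_divergence[s] for s in copies], kind="stable")
    assignment = list(zip([copies[i] for i in order], classes))
    rng.shuffle(assignment)

    def make_copy(sub: str) -> str:
        return _mutate(rng, consensus, config.subfamily_divergence[sub])

    entities: list[_Entity] = []
    # housekeeping genes (L1-free, for the exon:intron QC)
    for name in HOUSEKEEPING[: min(6, config.n_genes)]:
        entities.append(_make_gene(rng, name, "+" if rng.random() < 0.5 else "-"))

    gene_no = len(entities)
    pending_intronic = [a for a in assignment
                       if a[1] in ("co_transcribed", "intronic_opposite")]
    standalone = [a for a in assignment
                  if a[1] not in ("co_transcribed", "intronic_opposite")]

    # host genes for intronic copies
    for sub, cls in pending_intronic:
        gene_no += 1
        gstrand = "+" if rng.random() < 0.5 else "-"
        l1_strand = gstrand if cls == "co_transcribed" else ("-" if gstrand == "+" else "+")
        seq = make_copy(sub)
        if l1_strand == "-":
            seq = revcomp(seq)
        ent = _make_gene(rng, f"GENE{gene_no}", gstrand, host=cls,
                         l1_seq=seq, l1_strand=l1_strand)
        ent.repeats = [(s, e, st, sub) for (s, e, st, _f) in ent.repeats]
        entities.append(ent)

    # plain filler genes up to n_genes
    while gene_no < config.n_genes:
        gene_no += 1
        entities.append(_make_gene(rng, f"GENE{gene_no}", "+" if rng.random() < 0.5 else "-"))

    # standalone L1 entities (readthrough copies get their driver gene fused)
    for sub, cls in standalone:
        strand = "+" if rng.random() < 0.5 else "-"
        seq = make_copy(sub)
        body = seq if strand == "+" else revcomp(seq)
        if cls == "readthrough":
            gene_no += 1
            gent = _make_gene(rng, f"GENE{gene_no}", strand)
            gap = _random_seq(rng, int(rng.integers(1000, 2000)))
            if strand == "+":
                full = gent.seq + gap + body
                rep = (len(gent.seq) + len(gap), len(full), strand, sub)
                gene_local = gent.gene
            else:
                full = body + gap + gent.seq
                rep = (0, len(body), strand, sub)
                off = len(body) + len(gap)
                name, gstrand, exons = gent.gene
                gene_local = (name, gstrand, [(s + off, e + off) for s, e in exons])
            entities.append(_Entity(kind="readthrough", seq=full, repeats=[rep],
                                    gene=gene_local, locus_class=[(0, cls)]))
        else:
            entities.append(_Entity(kind="l1", seq=body,
                                    repeats=[(0, len(body), strand, sub)],
                                    locus_class=[(0, cls)]))

    # truncated negatives: 5'-truncated, so no promoter
    for i in range(config.n_truncated):
        sub = subs[int(rng.integers(0, len(subs)))]
        cut = int(rng.integers(3000, 4500))
        seq = _mutate(rng, consensus[cut:], config.subfamily_divergence[sub])
        strand = "+" if rng.random() < 0.5 else "-"
        body = seq if strand == "+" else revcomp(seq)
        entities.append(_Entity(kind="truncated", seq=body,
                                repeats=[(0, len(body), strand, sub)]))

    rng.shuffle(entities)
    total_len = sum(len(e.seq) for e in entities)
    n_gaps = len(entities) + 1
    min_gap = 6000
    spare = config.genome_length - total_len - n_gaps * min_gap
    if spare < 0:
        raise ValueError(
            f"entities ({total_len} bp + gaps) do not fit in genome_length "
            f"{config.genome_length}"
        )
    extra = rng.multinomial(spare, np.ones(n_gaps) / n_gaps)
    gaps = [min_gap + int(x) for x in extra]

    # assemble and lift features to genome coordinates
    parts: list[str] = []
    pos = 0
    repeats: list[RepeatFeature] = []
    genes: list[GeneModel] = []
    loci_truth: dict[str, LocusTruth] = {}
    unmappable_left = config.n_unmappable_upstream
    rep_no = 0
    for ent, gap in zip(entities, gaps[:-1]):
        parts.append(_random_seq(rng, gap))
        pos += gap
        ent_start = pos
        class_by_idx = dict(ent.locus_class)
        for idx, (s, e, strand, fam) in enumerate(ent.repeats):
            rep_no += 1
            gstart, gend = ent_start + s, ent_start + e
            repeats.append(RepeatFeature(
                chrom=CHROM, start=gstart, end=gend, strand=strand,
                family=fam, id=f"rep{rep_no}",
            ))
            cls = class_by_idx.get(idx)
            if cls is None and ent.kind == "truncated":
                continue
            if cls is None:
                cls = "silent"
            lid = L1Locus.make_id(CHROM, gstart, gend, strand)
            label = {
                "promoter_driven": AUTHENTIC,
                "asp_only": ASP_ONLY,
                "co_transcribed": CO_ONLY,
                "readthrough": CO_ONLY,
                "unannotated_upstream": CO_ONLY,
                "intronic_opposite": SILENT,
                "silent": SILENT,
            }[cls]
            loci_truth[lid] = LocusTruth(locus_id=lid, label=label, class_detail=cls)
        if ent.gene is not None:
            name, gstrand, exons = ent.gene
            genes.append(GeneModel(
                name=name, chrom=CHROM, strand=gstrand,
                exons=[(ent_start + s, ent_start + e) for s, e in exons],
            ))
        parts.append(ent.seq)
        pos += len(ent.seq)
    parts.append(_random_seq(rng, gaps[-1]))
    pos += gaps[-1]
    if pos < config.genome_length:
        parts.append(_random_seq(rng, config.genome_length - pos))
    genome_seq = "".join(parts)

    # mark ASP-coupled and unmappable-upstream promoter loci, and break the
    # upstream mappability of the chosen loci by duplicating their flank
    auth = sorted(l for l, t in loci_truth.items() if t.label == AUTHENTIC)
    rng.shuffle(auth)
    for lid in auth[: config.n_asp_coupled]:
        loci_truth[lid].asp_coupled = True
    arr = bytearray(genome_seq.encode())
    for lid in auth[config.n_asp_coupled:
                    config.n_asp_coupled + unmappable_left]:
        loci_truth[lid].unmappable_upstream = True
        loc = next(r for r in repeats
                   if L1Locus.make_id(r.chrom, r.start, r.end, r.strand) == lid)
        lo, hi = (max(0, loc.start - 1000), loc.start) if loc.strand == "+" \
            else (loc.end, min(len(arr), loc.end + 1000))
        # plant an exact copy of the flank far away in a gap (start of genome)
        arr[100 : 100 + (hi - lo)] = arr[lo:hi]
    genome_seq = arr.decode()

    return SimGenome(
        genome={CHROM: genome_seq}, repeats=repeats, genes=genes,
        loci_truth=loci_truth, consensus=consensus, promoter_query=query,
        config=config,
    )


# -- transcripts -------------------------------------------------------------

def simulate_transcripts(sim: SimGenome, config: SimConfig | None = None) -> list[Transcript]:
    """One transcript per simulated expression unit, with abundance weights."""
    config = config or sim.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    loci = {l.locus_id: l for l in sim.full_length_loci()}
    genes = {g.name: g for g in sim.genes}
    out: list[Transcript] = []
    tno = 0

    def add(tclass, start, end, strand, locus_id=None, gene=None):
        nonlocal tno
        tno += 1
        out.append(Transcript(
            id=f"t{tno:03d}", tclass=tclass, chrom=CHROM,
            start=int(start), end=int(end), strand=strand,
            weight=float(rng.uniform(0.5, 2.0)), locus_id=locus_id, gene=gene,
        ))

    # genes hosting intronic copies, keyed by the repeat they contain
    def hosting_gene(loc: L1Locus) -> GeneModel:
        for g in sim.genes:
            if g.start <= loc.start and loc.end <= g.end:
                return g
        raise ValueError(f"no hosting gene found for {loc.locus_id}")

    for lid, truth in sorted(sim.loci_truth.items()):
        loc = loci.get(lid)
        if loc is None:
            raise ValueError(f"truth locus {lid} missing from annotation")
        cls = truth.class_detail
        if cls == "promoter_driven":
            j = int(rng.integers(-config.promoter_jitter, config.promoter_jitter + 1))
            if loc.strand == "+":
                add(cls, max(0, loc.start + j), loc.end, "+", locus_id=lid)
            else:
                add(cls, loc.start, loc.end - j, "-", locus_id=lid)
            if truth.asp_coupled:
                _add_asp(add, rng, loc, config, coupled=True)
        elif cls == "asp_only":
            _add_asp(add, rng, loc, config, coupled=False)
        elif cls == "co_transcribed":
            g = hosting_gene(loc)
            add(cls, g.start, g.end, g.strand, locus_id=lid, gene=g.name)
        elif cls == "intronic_opposite":
            g = hosting_gene(loc)
            add("co_transcribed", g.start, g.end, g.strand, locus_id=lid, gene=g.name)
        elif cls == "readthrough":
            # the driver gene sits adjacent in element-space upstream
            if loc.strand == "+":
                g = max((g for g in sim.genes if g.strand == "+" and g.end <= loc.start),
                        key=lambda g: g.end, default=None)
                if g is None or loc.start - g.end > 2500:
                    raise ValueError(f"no driver gene upstream of readthrough locus {lid}")
                add(cls, g.start, loc.end + 500, "+", locus_id=lid, gene=g.name)
            else:
                g = min((g for g in sim.genes if g.strand == "-" and g.start >= loc.end),
                        key=lambda g: g.start, default=None)
                if g is None or g.start - loc.end > 2500:
                    raise ValueError(f"no driver gene upstream of readthrough locus {lid}")
                add(cls, max(0, loc.start - 500), g.end, "-", locus_id=lid, gene=g.name)
        elif cls == "unannotated_upstream":
            d = int(rng.integers(1000, 4000))
            if loc.strand == "+":
                add(cls, max(0, loc.start - d), loc.end, "+", locus_id=lid)
            else:
                add(cls, loc.start, loc.end + d, "-", locus_id=lid)

    for g in sim.genes:
        add("gene_mrna", g.start, g.end, g.strand, gene=g.name)
        if g.introns:
            add("intronic_background", g.start, g.end, g.strand, gene=g.name)
    return out


def _add_asp(add, rng, loc: L1Locus, config: SimConfig, coupled: bool) -> None:
    """Antisense transcript out of the 5'UTR, optionally into the flank.

    ASP transcription initiates deep in the 5'UTR, so the transcript spans
    most of it; uncoupled ASPs (ext 0) stay within the element.
    """
    depth_into = int(rng.integers(750, 900))
    ext = int(rng.integers(*config.asp_coupled_ext)) if coupled else 0
    if loc.strand == "+":
        add("asp", max(0, loc.start - ext), loc.start + depth_into, "-",
            locus_id=loc.locus_id)
    else:
        add("asp", loc.end - depth_into, loc.end + ext, "+", locus_id=loc.locus_id)


# -- alignments --------------------------------------------------------------

DEFAULT_SAMPLES = (
    ("cytoplasmic_1", "cytoplasmic"),
    ("nuclear_1", "nuclear"),
    ("whole_cell_1", "whole_cell"),
)


@dataclass
class SimSample:
    sample_id: str
    compartment: str
    path: str
    stats: SampleStats
    n_pairs: int


def _sample_weights(config: SimConfig, compartment: str) -> dict[str, float]:
    if compartment in config.class_weights:
        return config.class_weights[compartment]
    if compartment == "whole_cell":
        mixed: dict[str, float] = {}
        for comp, w in config.compartment_mix.items():
            for cls, v in config.class_weights[comp].items():
                mixed[cls] = mixed.get(cls, 0.0) + w * v
        return mixed
    raise ValueError(f"unknown compartment {compartment!r}")


def simulate_alignments(
    sim: SimGenome,
    transcripts: list[Transcript],
    out_dir: str | Path,
    config: SimConfig | None = None,
    samples: tuple[tuple[str, str], ...] = DEFAULT_SAMPLES,
    stranded: bool = True,
) -> list[SimSample]:
    """Draw fragments per sample and write placed, uniqueness-tagged SAM.

    Fragment counts per transcript class follow the compartment's class
    weights; within a class, counts are multinomial over transcript
    abundances.  Each pair is written at its true position with an NH tag
    from the exhaustive placer (NH=1 unique, NH>1 tied).  Fragment names
    encode the source transcript and class (``frag<N>|<class>|<tid>``) so
    per-fragment truth travels with the SAM.
    """
    config = config or sim.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    searcher = alignio.GenomeSearcher(sim.genome)
    genome_seq = sim.genome[CHROM]
    chrom_lengths = {CHROM: len(genome_seq)}
    genes = {g.name: g for g in sim.genes}
    by_class: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_class.setdefault(t.tclass, []).append(t)
    unique_cache: dict[tuple[int, int], bool] = {}
    results: list[SimSample] = []

    for si, (sample_id, compartment) in enumerate(samples):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, si]))
        weights = _sample_weights(config, compartment)
        rows = []
        frag_no = 0
        for cls in sorted(weights):
            ts = by_class.get(cls, [])
            n_cls = int(round(weights[cls] * config.fragments_per_sample))
            if not ts or n_cls == 0:
                continue
            tw = np.array([t.weight for t in ts])
            counts = rng.multinomial(n_cls, tw / tw.sum())
            for t, n in zip(ts, counts):
                for _ in range(int(n)):
                    frag_no += 1
                    row = _draw_fragment(
                        rng, t, genes, genome_seq, config, searcher,
                        unique_cache, f"frag{frag_no:06d}|{t.tclass}|{t.id}",
                    )
                    if row is not None:
                        rows.append(row)
        n_unique = sum(1 for r in rows if r[8] == 1)
        stats = SampleStats(
            sample_id=sample_id, million_mapped=n_unique / 1e6,
            stranded=stranded, compartment=compartment,
        )
        path = out_dir / f"{sample_id}.sam"
        rows.sort(key=lambda r: (min(r[2], r[5]), r[0]))
        alignio.write_sam(path, chrom_lengths, rows, stats)
        results.append(SimSample(
            sample_id=sample_id, compartment=compartment, path=str(path),
            stats=stats, n_pairs=len(rows),
        ))
        log.info("sample %s: %d pairs (%d unique)", sample_id, len(rows), n_unique)
    return results


def _draw_fragment(rng, t: Transcript, genes, genome_seq, config, searcher,
                   unique_cache, qname):
    flen = int(np.clip(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd),
        config.fragment_length_min, config.fragment_length_max,
    ))
    if t.tclass == "gene_mrna":
        g = genes[t.gene]
        lens = np.array([e - s for s, e in g.exons], dtype=float)
        s, e = g.exons[rng.choice(len(lens), p=lens / lens.sum())]
        flen = min(flen, e - s)
        start = int(rng.integers(s, e - flen + 1))
    elif t.tclass == "intronic_background":
        g = genes[t.gene]
        introns = g.introns
        lens = np.array([e - s for s, e in introns], dtype=float)
        s, e = introns[rng.choice(len(lens), p=lens / lens.sum())]
        flen = min(flen, e - s)
        start = int(rng.integers(s, e - flen + 1))
    else:
        span = t.end - t.start
        flen = min(flen, span)
        start = int(rng.integers(t.start, t.end - flen + 1))
    end = start + flen
    rl = min(config.read_length, flen)
    left = genome_seq[start : start + rl]
    right = genome_seq[end - rl : end]
    key = (start, end)
    if key not in unique_cache:
        # as-sequenced mates: the rightmost mate reads off the minus strand
        placed = alignio.place_reads(
            searcher, [(qname, revcomp(right), left)],
            max_mismatches=config.max_mismatches, max_insert=config.max_insert,
        )
        unique_cache[key] = bool(placed and placed[0].unique)
    nh = 1 if unique_cache[key] else 2
    # dUTP protocol: read1 is antisense to the transcript
    if t.strand == "+":
        r1 = (end - rl, "-", right)
        r2 = (start, "+", left)
    else:
        r1 = (start, "+", left)
        r2 = (end - rl, "-", right)
    return (qname, CHROM, r1[0], r1[1], r1[2], r2[0], r2[1], r2[2], nh)


def write_truth_tsv(sim: SimGenome, path: str | Path) -> None:
    """Per-locus ground-truth labels as TSV."""
    with open(path, "w") as fh:
        fh.write("locus_id\tlabel\tclass_detail\tasp_coupled\tunmappable_upstream\n")
        for lid in sorted(sim.loci_truth):
            t = sim.loci_truth[lid]
            fh.write(f"{t.locus_id}\t{t.label}\t{t.class_detail}"
                     f"\t{int(t.asp_coupled)}\t{int(t.unmappable_upstream)}\n")
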
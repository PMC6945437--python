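"""File-format boundaries: FASTA, GFF3, BED6, BedGraph and TSV reports.

Internally everything is 0-based half-open; GFF3 is 1-based inclusive and
the conversion happens only here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GeneModel, L1Locus, MappabilityTrack, RepeatFeature

log = logging.getLogger(__name__)


# -- FASTA -------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# -- GFF3 --------------------------------------------------------------------

def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={quote(str(v), safe=' :/-')}" for k, v in attrs.items())


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        k, _, v = part.partition("=")
        out[k.strip()] = unquote(v.strip())
    return out


def write_loci_gff3(loci: list[L1Locus], path: str | Path) -> None:
    """Write the full-length L1 annotation (attributes ID, subfamily)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = _fmt_attrs({"ID": loc.locus_id, "subfamily": loc.subfamily})
            fh.write(
                f"{loc.chrom}\tl1locus\tL1_full_length\t{loc.start + 1}\t{loc.end}"
                f"\t.\t{loc.strand}\t.\t{attrs}\n"
            )


def read_loci_gff3(path: str | Path) -> list[L1Locus]:
    loci = []
    for lineno, line in enumerate(open(path), 1):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        if f[2] != "L1_full_length":
            continue
        attrs = _parse_attrs(f[8])
        start, end = int(f[3]) - 1, int(f[4])
        loci.append(L1Locus(
            chrom=f[0], start=start, end=end, strand=f[6],
            subfamily=attrs.get("subfamily", "L1"),
            locus_id=attrs.get("ID", L1Locus.make_id(f[0], start, end, f[6])),
        ))
    return loci


def write_repeats_gff3(repeats: list[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in repeats:
            attrs = _fmt_attrs({"ID": r.id, "family": r.family})
            fh.write(
                f"{r.chrom}\tl1locus\tdispersed_repeat\t{r.start + 1}\t{r.end}"
                f"\t.\t{r.strand}\t.\t{attrs}\n"
            )


def read_repeats(path: str | Path) -> list[RepeatFeature]:
    """Read a repeat annotation from GFF3 (family attribute) or BED6 (name)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_repeats_bed6(path)
    repeats = []
    for lineno, line in enumerate(open(path), 1):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        attrs = _parse_attrs(f[8])
        family = attrs.get("family") or attrs.get("repeat_family") or attrs.get("Name")
        if not family:
            raise ValueError(f"{path}:{lineno}: no repeat family attribute")
        repeats.append(RepeatFeature(
            chrom=f[0], start=int(f[3]) - 1, end=int(f[4]), strand=f[6],
            family=family, id=attrs.get("ID", f"rep{lineno}"),
        ))
    return repeats


def _read_repeats_bed6(path: Path) -> list[RepeatFeature]:
    repeats = []
    for lineno, line in enumerate(open(path), 1):
        if line.startswith(("#", "track", "browser")) or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 6:
            raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
        repeats.append(RepeatFeature(
            chrom=f[0], start=int(f[1]), end=int(f[2]), strand=f[5],
            family=f[3], id=f"{f[0]}:{f[1]}-{f[2]}:{f[5]}",
        ))
    return repeats


def write_genes_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models with gene + exon rows (introns are implicit)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tl1locus\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                + _fmt_attrs({"ID": g.name, "Name": g.name}) + "\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tl1locus\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    + _fmt_attrs({"ID": f"{g.name}.exon{i}", "Parent": g.name}) + "\n"
                )


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    meta: dict[str, tuple[str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(open(path), 1):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        attrs = _parse_attrs(f[8])
        if f[2] == "gene":
            name = attrs.get("Name") or attrs["ID"]
            meta[attrs["ID"]] = (name, f[0], f[6])
            order.append(attrs["ID"])
        elif f[2] == "exon":
            exons.setdefault(attrs["Parent"], []).append((int(f[3]) - 1, int(f[4])))
    genes = []
    for gid in order:
        name, chrom, strand = meta[gid]
        if gid not in exons:
            raise ValueError(f"gene {gid} has no exon rows")
        genes.append(GeneModel(name=name, chrom=chrom, strand=strand, exons=exons[gid]))
    return genes


# -- BedGraph ----------------------------------------------------------------

def write_bedgraph(track: MappabilityTrack, path: str | Path) -> None:
    """Write the 0/1 mappability track as run-length BedGraph intervals."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="mappability_L{track.read_length}"\n')
        for chrom, arr in track.arrays.items():
            if len(arr) == 0:
                continue
            vals = arr.astype(int)
            import numpy as np

            change = np.nonzero(np.diff(vals))[0] + 1
            starts = [0, *change.tolist()]
            ends = [*change.tolist(), len(vals)]
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]}\n")
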
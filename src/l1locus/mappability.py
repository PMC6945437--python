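"""Per-base unique-mappability track from tiled genome-derived reads.

The track answers: if an error-free read of length L started at this
position, would it place uniquely in the genome (both strands considered)?
Positions covered by any uniquely placing L-mer are marked mappable.  This
is the deterministic, download-free equivalent of aligning real whole
genome sequencing reads back to the genome and keeping unique hits, and is
exactly the k-mer multiplicity criterion: an L-mer places uniquely iff it
occurs exactly once in the genome plus its reverse complement (a
palindromic L-mer therefore counts twice and is never unique).

Implementation: dual 64-bit polynomial rolling hashes of every window on
the forward and reverse-complement strands, multiplicities by sorting; no
quadratic scans.
"""

from __future__ import annotations

import numpy as np

from ._seq import encode, revcomp_arr, window_hashes
from .types import MappabilityTrack

DEFAULT_READ_LENGTH = 100


def compute_mappability(
    genome: dict[str, str],
    read_length: int = DEFAULT_READ_LENGTH,
    step: int = 1,
) -> MappabilityTrack:
    """Tile error-free L-mers every ``step`` bp and mark unique placements."""
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not genome:
        raise ValueError("genome is empty")
    L = read_length
    for chrom, seq in genome.items():
        if L > len(seq):
            raise ValueError(f"read_length {L} exceeds length of {chrom}")

    arrays = {c: encode(s) for c, s in genome.items()}
    fwd = {c: window_hashes(a, L) for c, a in arrays.items()}
    rev = {c: window_hashes(revcomp_arr(a), L) for c, a in arrays.items()}

    # multiplicity of each hash among all forward-strand windows
    all_f = np.concatenate([h for h in fwd.values()])
    all_r = np.concatenate([h for h in rev.values()])
    uniq, inverse = np.unique(
        np.concatenate([all_f, all_r]), axis=0, return_inverse=True
    )
    counts_f = np.bincount(inverse[: len(all_f)], minlength=len(uniq))

    # slice the inverse array back per chromosome
    inv_f: dict[str, np.ndarray] = {}
    inv_r: dict[str, np.ndarray] = {}
    off = 0
    for c, h in fwd.items():
        inv_f[c] = inverse[off : off + len(h)]
        off += len(h)
    for c, h in rev.items():
        inv_r[c] = inverse[off : off + len(h)]
        off += len(h)

    out: dict[str, np.ndarray] = {}
    for c, arr in arrays.items():
        n = len(arr)
        nwin = n - L + 1
        # occurrences of the L-mer at s: forward copies + reverse-complement
        # copies (the rc of window s is window n-L-s of the rc strand)
        occ = counts_f[inv_f[c]] + counts_f[inv_r[c]][::-1]
        starts = np.arange(0, nwin, step)
        unique_starts = starts[occ[starts] == 1]
        cover = np.zeros(n + 1, dtype=np.int32)
        np.add.at(cover, unique_starts, 1)
        np.add.at(cover, unique_starts + L, -1)
        out[c] = np.cumsum(cover[:-1]) > 0
    return MappabilityTrack(read_length=L, arrays=out)


def interval_mappability(track: MappabilityTrack, chrom: str, start: int, end: int) -> float:
    """Fraction of positions in [start, end) marked uniquely mappable."""
    return track.fraction(chrom, start, end)
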
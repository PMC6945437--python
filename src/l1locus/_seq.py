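"""Shared sequence primitives: 2-bit encoding, k-mer indexing, rolling hashes.

Everything downstream (the exhaustive read placer, the promoter search and
the mappability track) works on numpy ``uint8`` arrays with the encoding
A=0, C=1, G=2, T=3, N=4.  N never matches anything, including itself, when
mismatches are counted; for hashing it is kept as a literal fifth symbol.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
# complement: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

N_CODE = 4
MAX_INDEX_K = 31  # 2-bit codes must fit in a signed 64-bit integer


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to a uint8 array (A0 C1 G2 T3, other->4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_arr(encode(seq)))


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Mismatch count between equal-length encoded arrays; N mismatches all."""
    if a.shape != b.shape:
        raise ValueError("hamming: length mismatch")
    return int(np.count_nonzero((a != b) | (a == N_CODE)))


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit codes of every k-mer plus a validity mask (no N in window).

    Returns (codes, valid) of length ``len(arr) - k + 1``.
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    a = arr.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for i in range(k):
        codes = (codes << 2) | (a[i : i + n] & 3)
    is_n = (arr == N_CODE).astype(np.int64)
    cn = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cn[k:] - cn[:-k]) == 0
    return codes, valid


class KmerIndex:
    """Sorted exact-match index of all k-mers of one sequence (k <= 31)."""

    def __init__(self, arr: np.ndarray, k: int):
        if not 1 <= k <= MAX_INDEX_K:
            raise ValueError(f"k must be in [1, {MAX_INDEX_K}]")
        self.k = k
        codes, valid = _kmer_codes(arr, k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order].astype(np.int64)

    def lookup(self, code: int) -> np.ndarray:
        """Start positions where this exact k-mer occurs (unsorted order ok)."""
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._pos[lo:hi]


def kmer_code(arr: np.ndarray) -> int:
    """2-bit code of a short encoded array, or -1 if it contains N."""
    if np.any(arr == N_CODE):
        return -1
    code = 0
    for v in arr:
        code = (code << 2) | int(v & 3)
    return code


# -- dual polynomial rolling hash (for long k-mers, e.g. 100-mers) -----------

_HASH_P = (2305843009213693951, 4611686018427387847)  # 2^61-1 and a prime
_HASH_B = (1315423911, 2654435761)


def window_hashes(arr: np.ndarray, L: int) -> np.ndarray:
    """Dual polynomial hash of every length-L window.

    Returns an (n, 2) int64 array, n = len(arr) - L + 1.  Computed by a
    Horner pass per base, so cost is O(L) vectorised passes.
    """
    n = len(arr) - L + 1
    out = np.zeros((max(n, 0), 2), dtype=np.int64)
    if n <= 0:
        return out
    a = arr.astype(np.int64) + 1  # 1..5, keep N distinct from padding
    for j, (p, b) in enumerate(zip(_HASH_P, _HASH_B)):
        h = np.zeros(n, dtype=np.int64)
        for i in range(L):
            h = (h * b + a[i : i + n]) % p
        out[:, j] = h
    return out
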
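"""Vectorized k-mer encoding over the {A,C,G,T} alphabet.

K-mers are packed into non-negative integers base 4 with the 5'-most base
most significant, so the numeric order of codes equals lexicographic order
of the k-mer strings (A < C < G < T).  Every counting and scoring routine
in the package works on these codes; strings only appear at the API edges.
"""

from __future__ import annotations

import numpy as np

BASES = b"ACGT"
INVALID = np.uint8(255)

# byte -> 2-bit code; anything outside ACGT (N, lowercase, gaps) maps to INVALID
_LUT = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[_b] = _i

_DECODE = np.frombuffer(BASES, dtype=np.uint8)


def n_kmers(k: int) -> int:
    """Size of the k-mer universe, 4**k."""
    return 4 ** k


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Per-base 2-bit codes for one sequence; invalid bases become 255."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def seqs_to_code_matrix(seqs) -> np.ndarray:
    """(n, L) code matrix for equal-length sequences.

    Accepts a numpy array of fixed-width bytes (dtype ``S<L>``) or any
    iterable of strings/bytes of one common length.
    """
    arr = np.asarray(seqs, dtype=bytes)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d collection of sequences")
    if arr.size == 0:
        return np.empty((0, 0), dtype=np.uint8)
    width = arr.dtype.itemsize
    raw = arr.view(np.uint8).reshape(arr.size, width)
    # trailing NULs mark ragged (shorter) entries; treat them as invalid
    return _LUT[raw]


def codes_to_indices(codes: np.ndarray, start: int, end: int):
    """Pack columns [start, end) of a code matrix into k-mer indices.

    Returns ``(indices, valid)`` where ``valid`` flags rows free of
    invalid bases inside the window.
    """
    window = codes[:, start:end]
    valid = (window != INVALID).all(axis=1)
    k = end - start
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    idx = (window.astype(np.int64) * weights).sum(axis=1)
    return idx, valid


def indices_to_kmers(indices, k: int) -> np.ndarray:
    """Decode integer indices back to k-mer byte strings (dtype S<k>)."""
    idx = np.asarray(indices, dtype=np.int64)
    shifts = 2 * np.arange(k - 1, -1, -1)
    cols = (idx[:, None] >> shifts[None, :]) & 3
    return _DECODE[cols].view(f"S{k}").reshape(idx.shape)


def codes_to_seqs(codes: np.ndarray) -> np.ndarray:
    """Decode an (n, L) 2-bit code matrix to fixed-width byte strings."""
    codes = np.ascontiguousarray(codes)
    n, width = codes.shape
    return _DECODE[codes].view(f"S{width}").reshape(n)


def kmer_to_index(kmer: str | bytes) -> int:
    """Index of a single k-mer; raises on non-ACGT bases."""
    codes = seq_to_codes(kmer)
    if (codes == INVALID).any():
        raise ValueError(f"k-mer {kmer!r} contains a base outside ACGT")
    k = len(codes)
    return int((codes.astype(np.int64) * (4 ** np.arange(k - 1, -1, -1))).sum())


def all_kmers(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic order."""
    return [s.decode() for s in indices_to_kmers(np.arange(n_kmers(k)), k)]


def section_indices(indices: np.ndarray, k: int, start: int, end: int) -> np.ndarray:
    """Sub-k-mer index for slice [start, end) of each packed k-mer index."""
    width = end - start
    return (np.asarray(indices, dtype=np.int64) >> (2 * (k - end))) & (4 ** width - 1)


def gc_count(indices, k: int) -> np.ndarray:
    """Number of G/C bases in each packed k-mer index."""
    idx = np.asarray(indices, dtype=np.int64)
    out = np.zeros(idx.shape, dtype=np.int64)
    for pos in range(k):
        base = (idx >> (2 * pos)) & 3
        out += (base == 1) | (base == 2)  # C=1, G=2
    return out
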
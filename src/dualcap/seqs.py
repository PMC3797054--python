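"""Low-level nucleotide sequence machinery.

Sequences are handled in two forms: Python strings over ``ACGT`` at the API
surface, and numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3) internally.
k-mers of up to 64 bases are bit-packed, two bits per base, into a pair of
``uint64`` columns (``hi`` carries the 5'-most bases); a packed pair viewed as
16 big-endian bytes compares lexicographically exactly like the k-mer itself,
which lets sorted-array set operations stand in for hash tables.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.max(initial=0) > 3:
        bad = chr(raw[int(np.argmax(codes > 3))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (last axis)."""
    return (3 - codes)[..., ::-1]


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(COMPLEMENT)[::-1]


def _shift_in(hi: np.ndarray, lo: np.ndarray, base, k: int):
    """Append one base (3' end) to packed k-mers, dropping the 5'-most base.

    ``lo`` holds the 3'-most ``w = min(k, 32)`` bases, ``hi`` the remaining
    ``k - w``. Works elementwise on arrays.
    """
    w = min(k, 32)
    lo_mask = np.uint64((1 << (2 * w)) - 1)
    carry = lo >> np.uint64(2 * (w - 1))
    if k > 32:
        hi_mask = np.uint64((1 << (2 * (k - 32))) - 1)
        hi = ((hi << np.uint64(2)) | carry) & hi_mask
    else:
        hi = np.zeros_like(lo)
    lo = ((lo << np.uint64(2)) | base.astype(np.uint64)) & lo_mask
    return hi, lo


def window_keys_lo(mat: np.ndarray, k: int) -> np.ndarray:
    """Packed keys of every k-window for k <= 32 (single uint64 per window)."""
    if mat.ndim == 1:
        mat = mat[None, :]
    n, length = mat.shape
    if not 1 <= k <= 32:
        raise ValueError("k must be in 1..32")
    if length < k:
        raise ValueError("rows shorter than k")
    r = length - k + 1
    mask = np.uint64((1 << (2 * k)) - 1)
    lo = np.zeros(n, dtype=np.uint64)
    out = np.empty((n, r), dtype=np.uint64)
    for j in range(length):
        lo = ((lo << np.uint64(2)) | mat[:, j]) & mask
        if j >= k - 1:
            out[:, j - k + 1] = lo
    return out


def window_keys(mat: np.ndarray, k: int):
    """Packed keys of every k-window of every row of a code matrix.

    Parameters
    ----------
    mat : (N, L) uint8 code matrix.
    k : window size, 1..64.

    Returns
    -------
    (hi, lo) : two (N, L-k+1) uint64 arrays.
    """
    if mat.ndim == 1:
        mat = mat[None, :]
    n, length = mat.shape
    if not 1 <= k <= 64:
        raise ValueError("k must be in 1..64")
    if length < k:
        raise ValueError("rows shorter than k")
    r = length - k + 1
    hi = np.zeros(n, dtype=np.uint64)
    lo = np.zeros(n, dtype=np.uint64)
    out_hi = np.empty((n, r), dtype=np.uint64)
    out_lo = np.empty((n, r), dtype=np.uint64)
    for j in range(length):
        hi, lo = _shift_in(hi, lo, mat[:, j], k)
        if j >= k - 1:
            out_hi[:, j - k + 1] = hi
            out_lo[:, j - k + 1] = lo
    return out_hi, out_lo


def keys_to_bytes(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """View packed key pairs as |S16 so byte order equals numeric order."""
    stacked = np.empty((hi.size, 2), dtype=">u8")
    stacked[:, 0] = hi.ravel()
    stacked[:, 1] = lo.ravel()
    return stacked.reshape(-1).view("|S16").reshape(hi.shape)


def pack_kmer(codes: np.ndarray) -> tuple[int, int]:
    """Pack a single k-mer code vector into Python ints (hi, lo)."""
    k = len(codes)
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    w = min(k, 32)
    return val >> (2 * w), val & ((1 << (2 * w)) - 1)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file as a list of (id, sequence) pairs."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as fh:
        return [(title.split()[0], seq.upper()) for title, seq in SimpleFastaParser(fh)]


def write_fasta(path, records, width: int = 80) -> None:
    """Write (id, sequence) pairs (or (id, desc, seq) triples) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 3:
                name, desc, seq = rec
                header = f"{name} {desc}" if desc else name
            else:
                name, seq = rec
                header = name
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
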
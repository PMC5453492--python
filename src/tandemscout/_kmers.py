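"""Vectorised 2-bit k-mer encoding shared by the assembler and the read recruiter.

Bases map A=0, C=1, G=2, T=3; anything else (N) maps to 4 and poisons every
k-mer window it touches.  k is limited to 31 so a k-mer fits a signed int64.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_BASES = np.array(list("ACGT"))

MAX_K = 31


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 array of base codes (4 = ambiguous)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of a base-code array.

    Returns (codes, valid) where valid[i] is False when the window contains
    an ambiguous base.  Empty arrays when the input is shorter than k.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    a = (arr & 3).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        np.left_shift(codes, 2, out=codes)
        np.bitwise_or(codes, a[j : j + n], out=codes)
    bad = (arr > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


# byte table for reverse-complementing 4 packed bases at once
_RC_BYTE = np.empty(256, dtype=np.uint8)
for _b in range(256):
    _v = 0
    for _j in range(4):
        _base = (_b >> (2 * _j)) & 3
        _v |= (3 - _base) << (2 * (3 - _j))
    _RC_BYTE[_b] = _v


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of each k-mer code, vectorised byte-wise."""
    if len(codes) == 0:
        return codes.copy()
    v = codes.astype(np.int64, copy=True).view(np.uint8).reshape(-1, 8)
    if not np.little_endian:  # pragma: no cover
        v = v[:, ::-1]
    out = np.ascontiguousarray(_RC_BYTE[v][:, ::-1])
    if not np.little_endian:  # pragma: no cover
        out = np.ascontiguousarray(out[:, ::-1])
    full = out.view(np.uint64).reshape(-1)
    return (full >> np.uint64(64 - 2 * k)).astype(np.int64)


def canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-min) code per k-mer plus a flag for 'rc was smaller'."""
    rc = revcomp_codes(codes, k)
    flipped = rc < codes
    return np.where(flipped, rc, codes), flipped


def decode_code(code: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append("ACGT"[(code >> (2 * j)) & 3])
    return "".join(out)


# ---------------------------------------------------------------------------
# cyclic-sequence helpers

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def least_rotation(seq: str) -> str:
    """Lexicographically least rotation (Booth via doubling; fine at n<=2000)."""
    doubled = seq + seq
    n = len(seq)
    best = min(range(n), key=lambda i: doubled[i : i + n])
    return doubled[best : best + n]


def canonical_monomer(monomer: str) -> str:
    """Rotation- and strand-normalised representative of a cyclic repeat unit.

    The least string among all rotations of the monomer and all rotations of
    its reverse complement; idempotent, so canonical monomers compare equal
    across contigs and against simulation truth.
    """
    if not monomer:
        raise ValueError("empty monomer")
    return min(least_rotation(monomer), least_rotation(reverse_complement(monomer)))
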
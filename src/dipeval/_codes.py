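"""Vectorized 2-bit DNA codes.

Every k-mer is packed into a ``uint64`` with A=0, C=1, G=2, T=3, most
significant bits first.  Because the base order matches the lexicographic
order of the letters, the numeric minimum of (forward, reverse-complement)
codes is exactly the lexicographically smaller of the two strings, so
canonicalization never needs string comparisons.  k is limited to 31 so a
code always fits in 62 bits.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[ord(chr(_b).lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MAX_K = 31


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 array; A,C,G,T -> 0..3, anything else -> 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(int(code) >> shift) & 3])
    return "".join(out)


def kmer_string_code(kmer: str) -> int:
    b = encode(kmer)
    if (b > 3).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    code = 0
    for v in b:
        code = (code << 2) | int(v)
    return code


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def canonical_codes(seq: str, k: int) -> np.ndarray:
    """Canonical codes of every valid k-mer window, in sequence order.

    Windows containing non-ACGT characters are skipped, so the result may be
    shorter than ``len(seq) - k + 1``.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    b = encode(seq)
    n = b.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = b > 3
    b64 = np.where(bad, 0, b).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        w = b64[j : j + m]
        fwd = (fwd << np.uint64(2)) | w
        rev |= (np.uint64(3) - w) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    if bad.any():
        # window is valid iff it contains no bad base
        bad_cum = np.concatenate(([0], np.cumsum(bad)))
        ok = (bad_cum[k:] - bad_cum[:-k]) == 0
        canon = canon[ok]
    return canon


def forward_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Stranded (non-canonical) codes of valid k-mer windows + their offsets."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    b = encode(seq)
    n = b.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    bad = b > 3
    b64 = np.where(bad, 0, b).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b64[j : j + m]
    pos = np.arange(m, dtype=np.int64)
    if bad.any():
        bad_cum = np.concatenate(([0], np.cumsum(bad)))
        ok = (bad_cum[k:] - bad_cum[:-k]) == 0
        fwd = fwd[ok]
        pos = pos[ok]
    return fwd, pos


def canonical_codes_with_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`canonical_codes` but also returns the window start offsets."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    b = encode(seq)
    n = b.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    bad = b > 3
    b64 = np.where(bad, 0, b).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        w = b64[j : j + m]
        fwd = (fwd << np.uint64(2)) | w
        rev |= (np.uint64(3) - w) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    pos = np.arange(m, dtype=np.int64)
    if bad.any():
        bad_cum = np.concatenate(([0], np.cumsum(bad)))
        ok = (bad_cum[k:] - bad_cum[:-k]) == 0
        canon = canon[ok]
        pos = pos[ok]
    return canon, pos
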
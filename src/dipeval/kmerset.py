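"""Canonical k-mer multisets and the k-mer consensus-quality metrics.

This module provides exact (non-sketched) canonical k-mer counting over
FASTA/FASTQ-scale inputs, parent-specific marker ("hapmer") extraction for a
mother/father/child trio, and the k-mer survey metrics used to grade a
diploid assembly: consensus QV, read-set completeness, and false-duplication
percentage.  The QV model converts the fraction of assembly k-mers that have
no support in an independent read set into a Phred-scaled per-base error
rate::

    E  = 1 - (1 - k_err / k_total)^(1/k)
    QV = -10 * log10(E)

so an assembly with a single substitution per megabase at k=21 scores QV 60
(one error contaminates k consecutive k-mers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._codes import MAX_K, canonical_codes, decode_kmer, kmer_string_code, revcomp

DEFAULT_K = 21
DEFAULT_RELIABLE_MIN = 2

#: Phred value reported when an assembly has zero unsupported k-mers.  The
#: true QV is unbounded; reports carry an ``infinite`` flag alongside.
QV_INF_SENTINEL = 999.0

_CHUNK_BASES = 32_000_000


class KmerSet:
    """Multiset of canonical k-mers, stored as sorted uint64 codes + counts."""

    __slots__ = ("k", "codes", "counts", "source")

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray, source: str = ""):
        self.k = int(k)
        self.codes = np.asarray(codes, dtype=np.uint64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.source = source

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], k: int = DEFAULT_K, source: str = "") -> "KmerSet":
        """Count canonical k-mers over sequences, chunking large inputs.

        k-mers overlapping non-ACGT characters (gaps, IUPAC codes) are
        skipped.  Counting is exact.
        """
        _check_k(k)
        pending: list[tuple[np.ndarray, np.ndarray]] = []
        buf: list[str] = []
        buf_bases = 0
        for seq in _iter_seqs(seqs):
            buf.append(seq)
            buf_bases += len(seq)
            if buf_bases >= _CHUNK_BASES:
                pending.append(_count_chunk(buf, k))
                buf, buf_bases = [], 0
        if buf:
            pending.append(_count_chunk(buf, k))
        if not pending:
            return cls(k, np.empty(0, np.uint64), np.empty(0, np.int64), source)
        codes, counts = _merge_counted(pending)
        return cls(k, codes, counts, source)

    @classmethod
    def from_counts(cls, mapping: Mapping[str, int], k: int | None = None, source: str = "") -> "KmerSet":
        """Build from an explicit {kmer: count} mapping (canonicalized here)."""
        if not mapping:
            if k is None:
                raise ValueError("k required for an empty mapping")
            return cls(k, np.empty(0, np.uint64), np.empty(0, np.int64), source)
        ks = {len(s) for s in mapping}
        if len(ks) != 1:
            raise ValueError("mixed k-mer lengths")
        kk = ks.pop()
        if k is not None and k != kk:
            raise ValueError(f"k mismatch: {k} != {kk}")
        agg: dict[int, int] = {}
        for s, c in mapping.items():
            rc = revcomp(s)
            canon = s if s <= rc else rc
            code = kmer_string_code(canon)
            agg[code] = agg.get(code, 0) + int(c)
        codes = np.array(sorted(agg), dtype=np.uint64)
        counts = np.array([agg[int(c)] for c in codes], dtype=np.int64)
        return cls(kk, codes, counts, source)

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return self.codes.size

    def __contains__(self, kmer: str) -> bool:
        rc = revcomp(kmer)
        code = kmer_string_code(kmer if kmer <= rc else rc)
        i = np.searchsorted(self.codes, np.uint64(code))
        return bool(i < self.codes.size and self.codes[i] == np.uint64(code))

    @property
    def total(self) -> int:
        """Total k-mer instances (multiset cardinality)."""
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        rc = revcomp(kmer)
        code = kmer_string_code(kmer if kmer <= rc else rc)
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and self.codes[i] == np.uint64(code):
            return int(self.counts[i])
        return 0

    def membership(self, query_codes: np.ndarray) -> np.ndarray:
        """Boolean mask: which canonical query codes are present in this set."""
        q = np.asarray(query_codes, dtype=np.uint64)
        if self.codes.size == 0:
            return np.zeros(q.size, dtype=bool)
        idx = np.searchsorted(self.codes, q)
        idx_c = np.minimum(idx, self.codes.size - 1)
        return self.codes[idx_c] == q

    def counts_of(self, query_codes: np.ndarray) -> np.ndarray:
        """Counts for each query code (0 where absent)."""
        q = np.asarray(query_codes, dtype=np.uint64)
        out = np.zeros(q.size, dtype=np.int64)
        if self.codes.size == 0:
            return out
        idx = np.searchsorted(self.codes, q)
        idx_c = np.minimum(idx, self.codes.size - 1)
        hit = self.codes[idx_c] == q
        out[hit] = self.counts[idx_c[hit]]
        return out

    # -- set algebra (over distinct k-mers) --------------------------------

    def filter_min_count(self, min_count: int) -> "KmerSet":
        keep = self.counts >= min_count
        return KmerSet(self.k, self.codes[keep], self.counts[keep], self.source)

    def minus(self, other: "KmerSet") -> "KmerSet":
        _check_same_k(self, other)
        keep = ~other.membership(self.codes)
        return KmerSet(self.k, self.codes[keep], self.counts[keep], self.source)

    def intersect(self, other: "KmerSet") -> "KmerSet":
        """Intersection keyed on this set's counts."""
        _check_same_k(self, other)
        keep = other.membership(self.codes)
        return KmerSet(self.k, self.codes[keep], self.counts[keep], self.source)

    # -- serialization -----------------------------------------------------

    def to_strings(self) -> dict[str, int]:
        return {decode_kmer(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c, n in zip(self.codes, self.counts):
                fh.write(f"{decode_kmer(int(c), self.k)}\t{int(n)}\n")

    @classmethod
    def read_tsv(cls, path, k: int | None = None, source: str = "") -> "KmerSet":
        mapping: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                s, c = line.split("\t")
                mapping[s] = int(c)
        return cls.from_counts(mapping, k=k, source=source)

    def histogram(self) -> dict[int, int]:
        """Multiplicity histogram {read count: number of distinct k-mers}."""
        vals, ns = np.unique(self.counts, return_counts=True)
        return {int(v): int(n) for v, n in zip(vals, ns)}


@dataclass(frozen=True)
class Hapmers:
    """Parent-specific inherited k-mers: disjoint maternal/paternal markers."""

    maternal: KmerSet
    paternal: KmerSet

    def __post_init__(self):
        if self.maternal.k != self.paternal.k:
            raise ValueError("maternal/paternal hapmer k mismatch")

    @property
    def k(self) -> int:
        return self.maternal.k

    def swapped(self) -> "Hapmers":
        return Hapmers(maternal=self.paternal, paternal=self.maternal)


@dataclass(frozen=True)
class QVReport:
    """k-mer consensus quality estimate for one assembly."""

    k: int
    k_total: int
    k_err: int
    err_rate: float
    qv: float
    infinite: bool = False


# ---------------------------------------------------------------------------


def count_kmers(seqs: Iterable[str] | str, k: int = DEFAULT_K, source: str = "") -> KmerSet:
    """Exact canonical k-mer multiset of the input sequences."""
    if isinstance(seqs, str):
        seqs = [seqs]
    return KmerSet.from_sequences(seqs, k=k, source=source)


def hapmer_sets(
    mat_reads: KmerSet,
    pat_reads: KmerSet,
    child_reads: KmerSet,
    reliable_min: int = DEFAULT_RELIABLE_MIN,
) -> Hapmers:
    """Extract inherited parent-specific markers from trio read k-mer sets.

    maternal = (mat − pat) ∩ child and symmetrically for paternal, with both
    the parental and the child count required to reach ``reliable_min`` so
    that singleton sequencing-error k-mers never become markers.  The two
    sets are disjoint by construction.
    """
    if not (mat_reads.k == pat_reads.k == child_reads.k):
        raise ValueError("k mismatch between trio k-mer sets")
    if reliable_min < 1:
        raise ValueError("reliable_min must be >= 1")
    child_ok = child_reads.filter_min_count(reliable_min)
    mat = mat_reads.filter_min_count(reliable_min).minus(pat_reads).intersect(child_ok)
    pat = pat_reads.filter_min_count(reliable_min).minus(mat_reads).intersect(child_ok)
    return Hapmers(
        maternal=KmerSet(mat.k, mat.codes, mat.counts, "maternal-hapmers"),
        paternal=KmerSet(pat.k, pat.codes, pat.counts, "paternal-hapmers"),
    )


def estimate_qv(asm_seqs: Iterable[str] | str, read_kmers: KmerSet, k: int | None = None) -> QVReport:
    """Phred-scaled consensus accuracy of an assembly against read k-mers.

    Every assembly k-mer instance absent from the read set is evidence of a
    consensus error; the per-base error probability follows from the k-fold
    overcounting of a single error.
    """
    if isinstance(asm_seqs, str):
        asm_seqs = [asm_seqs]
    if k is None:
        k = read_kmers.k
    if k != read_kmers.k:
        raise ValueError("k mismatch with read k-mer set")
    if len(read_kmers) == 0:
        raise ValueError("read k-mer set is empty")
    k_total = 0
    k_err = 0
    for seq in _iter_seqs(asm_seqs):
        codes = canonical_codes(seq, k)
        if codes.size == 0:
            continue
        k_total += codes.size
        k_err += int((~read_kmers.membership(codes)).sum())
    if k_total == 0:
        raise ValueError("assembly contains no k-mer of the requested size")
    if k_err == 0:
        return QVReport(k, k_total, 0, 0.0, QV_INF_SENTINEL, infinite=True)
    err = 1.0 - (1.0 - k_err / k_total) ** (1.0 / k)
    return QVReport(k, k_total, k_err, err, -10.0 * math.log10(err))


def completeness(
    asm_kmers: KmerSet,
    read_kmers: KmerSet,
    reliable_min: int = DEFAULT_RELIABLE_MIN,
) -> float:
    """Fraction of reliable (count >= reliable_min) read k-mers found in the assembly."""
    _check_same_k(asm_kmers, read_kmers)
    reliable = read_kmers.filter_min_count(reliable_min)
    if len(reliable) == 0:
        raise ValueError("no reliable read k-mers at this threshold")
    found = int(asm_kmers.membership(reliable.codes).sum())
    return found / len(reliable)


def estimate_haploid_peak(read_kmers: KmerSet, reliable_min: int = DEFAULT_RELIABLE_MIN) -> int:
    """1-copy read multiplicity estimated from the k-mer spectrum.

    Takes the lowest-multiplicity local maximum of the histogram above the
    error floor: in a diploid read set the heterozygous (1-copy) peak sits
    below the homozygous (2-copy) peak, so the global mode would be wrong by
    a factor of two whenever heterozygosity is low.
    """
    hist = read_kmers.histogram()
    xs = sorted(x for x in hist if x >= reliable_min)
    if not xs:
        raise ValueError("empty spectrum above reliable_min")
    dense = np.zeros(max(xs) + 2, dtype=np.int64)
    for x in xs:
        dense[x] = hist[x]
    for x in xs:
        if dense[x] >= dense[x - 1] and dense[x] >= dense[x + 1] and dense[x] > 0:
            return int(x)
    raise ValueError("flat k-mer spectrum: cannot estimate haploid peak")


def false_duplication(
    asm_kmers: KmerSet,
    read_kmers: KmerSet,
    haploid_peak: float,
    assembly_bp: int | None = None,
) -> float:
    """Percent of assembly bp present in more copies than the reads support.

    For each distinct assembly k-mer the expected copy number is
    ``round(read_count / haploid_peak)`` (floored at 1 so consensus-error
    k-mers are not misread as duplications); instances beyond that are
    excess, each standing proxy for one duplicated base.
    """
    _check_same_k(asm_kmers, read_kmers)
    if haploid_peak <= 0:
        raise ValueError("haploid_peak must be positive")
    read_counts = read_kmers.counts_of(asm_kmers.codes)
    expected = np.maximum(1, np.rint(read_counts / haploid_peak).astype(np.int64))
    excess = np.maximum(0, asm_kmers.counts - expected)
    if assembly_bp is None:
        assembly_bp = asm_kmers.total
    if assembly_bp <= 0:
        raise ValueError("assembly size must be positive")
    return 100.0 * float(excess.sum()) / float(assembly_bp)


# ---------------------------------------------------------------------------


def _iter_seqs(seqs: Iterable[str]) -> Iterable[str]:
    for s in seqs:
        yield str(s).upper()


def _check_k(k: int) -> None:
    if not (3 <= k <= MAX_K) or k % 2 == 0:
        raise ValueError(f"k must be odd and in [3, {MAX_K}], got {k}")


def _check_same_k(a: KmerSet, b: KmerSet) -> None:
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")


def _count_chunk(seqs: Sequence[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    parts = [canonical_codes(s, k) for s in seqs]
    parts = [p for p in parts if p.size]
    if not parts:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    allc = np.concatenate(parts)
    return np.unique(allc, return_counts=True)


def _merge_counted(pending: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    if len(pending) == 1:
        codes, counts = pending[0]
        return codes, counts.astype(np.int64)
    codes = np.concatenate([p[0] for p in pending])
    counts = np.concatenate([p[1] for p in pending]).astype(np.int64)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    counts = counts[order]
    boundary = np.concatenate(([True], codes[1:] != codes[:-1]))
    starts = np.flatnonzero(boundary)
    summed = np.add.reduceat(counts, starts)
    return codes[starts], summed
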
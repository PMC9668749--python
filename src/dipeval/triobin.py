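"""Trio binning of child reads using parent-specific markers.

Each read is scanned for maternal and paternal hapmers; it goes to the bin
with the strictly larger hit count, provided that count reaches
``min_hits``.  Ties and marker-free reads stay UNKNOWN and can be split
into two equal, seeded halves afterwards — unknowns carry no haplotype
signal, so an assembler receives them symmetrically.  Reads shorter than
``min_len`` (default 1 kb, the conventional long-read floor) are excluded
up front and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._codes import canonical_codes
from .kmerset import Hapmers, KmerSet

DEFAULT_MIN_LEN = 1000
DEFAULT_MIN_HITS = 2

MAT, PAT, UNKNOWN = "MAT", "PAT", "UNKNOWN"


@dataclass
class BinResult:
    maternal: list[str] = field(default_factory=list)
    paternal: list[str] = field(default_factory=list)
    unknown: list[str] = field(default_factory=list)
    too_short: list[str] = field(default_factory=list)
    hits: dict[str, tuple[int, int]] = field(default_factory=dict)  # id -> (n_mat, n_pat)

    def bin_of(self, read_id: str) -> str:
        if read_id in self.hits:
            n_mat, n_pat = self.hits[read_id]
        else:
            return UNKNOWN
        if read_id in set(self.maternal):
            return MAT
        if read_id in set(self.paternal):
            return PAT
        return UNKNOWN


def _read_id(name: str) -> str:
    return name.split()[0]


def bin_long_reads(
    reads: Iterable[tuple[str, str]],
    hapmers: Hapmers,
    min_len: int = DEFAULT_MIN_LEN,
    min_hits: int = DEFAULT_MIN_HITS,
    batch_bases: int = 20_000_000,
) -> BinResult:
    """Assign reads to MAT/PAT/UNKNOWN by hapmer hit counts.

    MAT requires n_mat >= min_hits and n_mat > n_pat (PAT symmetric);
    everything else — including exact ties — is UNKNOWN.
    """
    import warnings

    if len(hapmers.maternal) == 0 and len(hapmers.paternal) == 0:
        warnings.warn("both hapmer sets empty: all reads will be UNKNOWN")
    k = hapmers.k
    result = BinResult()

    batch: list[tuple[str, str]] = []
    batch_bp = 0

    def _flush():
        nonlocal batch, batch_bp
        if not batch:
            return
        code_parts = []
        idx_parts = []
        for i, (_, seq) in enumerate(batch):
            codes = canonical_codes(seq, k)
            if codes.size:
                code_parts.append(codes)
                idx_parts.append(np.full(codes.size, i, dtype=np.int32))
        n = len(batch)
        n_mat = np.zeros(n, dtype=np.int64)
        n_pat = np.zeros(n, dtype=np.int64)
        if code_parts:
            codes = np.concatenate(code_parts)
            idx = np.concatenate(idx_parts)
            np.add.at(n_mat, idx[hapmers.maternal.membership(codes)], 1)
            np.add.at(n_pat, idx[hapmers.paternal.membership(codes)], 1)
        for i, (name, _) in enumerate(batch):
            rid = _read_id(name)
            m, p = int(n_mat[i]), int(n_pat[i])
            result.hits[rid] = (m, p)
            if m >= min_hits and m > p:
                result.maternal.append(rid)
            elif p >= min_hits and p > m:
                result.paternal.append(rid)
            else:
                result.unknown.append(rid)
        batch, batch_bp = [], 0

    for name, seq in reads:
        if len(seq) < min_len:
            result.too_short.append(_read_id(name))
            continue
        batch.append((name, seq))
        batch_bp += len(seq)
        if batch_bp >= batch_bases:
            _flush()
    _flush()
    return result


def split_unknowns(unknown: Sequence[str], seed: int = 0) -> tuple[list[str], list[str]]:
    """Randomly divide unclassified reads into two equal bins (|Δ| <= 1)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unknown))
    bin1 = [unknown[int(i)] for i in order[0::2]]
    bin2 = [unknown[int(i)] for i in order[1::2]]
    return bin1, bin2


def filter_linked_pairs(
    reads: Iterable[tuple[str, str]],
    other_hap_hapmers: KmerSet,
) -> tuple[list[str], list[str]]:
    """Drop linked read pairs carrying any other-haplotype marker.

    Reads are named ``<pair_id>/1`` and ``<pair_id>/2``; a pair is dropped
    iff either mate contains at least one k-mer from the other haplotype's
    hapmer set.  Returns (kept pair ids, dropped pair ids).  Orphan mates
    raise with the offending ids.
    """
    mates: dict[str, dict[str, str]] = {}
    for name, seq in reads:
        rid = _read_id(name)
        if "/" not in rid:
            raise ValueError(f"read name {rid!r} lacks a /1 or /2 mate suffix")
        pair_id, mate = rid.rsplit("/", 1)
        mates.setdefault(pair_id, {})[mate] = seq
    orphans = sorted(p for p, m in mates.items() if set(m) != {"1", "2"})
    if orphans:
        raise ValueError(f"orphan mates for pair ids: {', '.join(orphans)}")
    kept: list[str] = []
    dropped: list[str] = []
    k = other_hap_hapmers.k
    for pair_id, m in mates.items():
        contaminated = False
        for seq in m.values():
            codes = canonical_codes(seq, k)
            if codes.size and other_hap_hapmers.membership(codes).any():
                contaminated = True
                break
        (dropped if contaminated else kept).append(pair_id)
    return kept, dropped


def write_bin_report(result: BinResult, path) -> None:
    """TSV: read_id, n_mat, n_pat, bin."""
    assign = {rid: MAT for rid in result.maternal}
    assign.update({rid: PAT for rid in result.paternal})
    assign.update({rid: UNKNOWN for rid in result.unknown})
    with open(path, "w") as fh:
        fh.write("#read_id\tn_mat\tn_pat\tbin\n")
        for rid, (m, p) in result.hits.items():
            fh.write(f"{rid}\t{m}\t{p}\t{assign.get(rid, UNKNOWN)}\n")
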
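"""Assembly-based small-variant calling and benchmarking.

The pipeline mirrors the dipcall / hap.py workflow at desk scale: align each
haplotype assembly to a reference (unique-k-mer anchor chaining with edlib
filling the inter-anchor gaps), derive phased variants from the two
haplotype alignments, and score a call set against a truth set restricted to
confident regions.  Sites covered by only one haplotype alignment receive
the GAP2 filter and their half-genotype is promoted to homozygous
(``1|.`` -> ``1|1``), matching the convention used when benchmarking
primary/alternate assemblies.

Printed summary metrics::

    SNP.Recall_ignoreGT = (SNP.TRUTH.TP + SNP.FP.gt) / SNP.TRUTH.TOTAL
    SNP.Recall          = SNP.TRUTH.TP / SNP.TRUTH.TOTAL
    QV_dip_snp_indel    = -10 * log10((SNP.QUERY.FP + INDEL.QUERY.FP)
                                      / (Subset.IS_CONF.Size * 2))

Matching is exact on left-normalized records; haplotype-graph matching of
complex overlapping representations (vcfeval) is out of scope.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from . import _intervals as iv
from ._codes import forward_codes, revcomp

ANCHOR_K = 31
QV_INF_SENTINEL = 999.0


@dataclass(frozen=True)
class VariantRecord:
    """One phased variant; ``pos`` is 0-based, alleles follow VCF anchoring."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    gt: str = "1|1"
    filter: str = "PASS"

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alts)


@dataclass
class Alignment:
    """Anchored global alignment of one contig against one reference chrom."""

    contig: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    contig_start: int
    contig_end: int
    strand: str  # '+' only for now; hetview handles inversions at edit level
    ops: list[tuple[str, int]]  # ('='|'X'|'I'|'D', run length)


@dataclass
class BenchmarkCounts:
    """hap.py-style tallies for one comparison subset."""

    snp_truth_tp: int = 0
    snp_truth_total: int = 0
    snp_query_fp: int = 0
    snp_fp_gt: int = 0
    indel_truth_tp: int = 0
    indel_truth_total: int = 0
    indel_query_fp: int = 0
    indel_fp_gt: int = 0
    conf_size: int = 0
    strata: dict = field(default_factory=dict)


# -- alignment --------------------------------------------------------------


def _unique_code_positions(seq: str, k: int) -> dict[int, int]:
    codes, pos = forward_codes(seq, k)
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    uniq_mask = np.ones(sc.size, dtype=bool)
    uniq_mask[1:] &= sc[1:] != sc[:-1]
    uniq_mask[:-1] &= sc[:-1] != sc[1:]
    upos = pos[order][uniq_mask]
    return {int(c): int(p) for c, p in zip(sc[uniq_mask], upos)}


def _chain_anchors(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of (contig_pos, ref_pos) increasing in both coordinates."""
    pairs.sort()
    tails: list[int] = []  # ref positions of chain tails
    back: list[int] = []
    tail_idx: list[int] = []
    for i, (_, r) in enumerate(pairs):
        j = bisect_left(tails, r)
        back.append(tail_idx[j - 1] if j > 0 else -1)
        if j == len(tails):
            tails.append(r)
            tail_idx.append(i)
        else:
            tails[j] = r
            tail_idx[j] = i
    if not tails:
        return []
    out = []
    i = tail_idx[len(tails) - 1]
    while i >= 0:
        out.append(pairs[i])
        i = back[i]
    return out[::-1]


def _edlib_ops(query: str, target: str) -> list[tuple[str, int]]:
    if not query and not target:
        return []
    if not query:
        return [("D", len(target))]
    if not target:
        return [("I", len(query))]
    cigar = edlib.align(query, target, mode="NW", task="path")["cigar"]
    ops = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            ops.append((ch, int(n)))
            n = ""
    return ops


def align_haplotype(
    contigs: Mapping[str, str],
    reference: Mapping[str, str],
    anchor_k: int = ANCHOR_K,
) -> tuple[list[Alignment], list[str]]:
    """Align every contig to its best reference chromosome.

    Anchors are k-mers unique in both sequences; the longest colinear chain
    is kept and the gaps between consecutive anchors (and the sequence ends)
    are aligned globally with edlib.  Returns (alignments, unaligned contig
    names).
    """
    ref_unique = {name: _unique_code_positions(seq, anchor_k) for name, seq in reference.items()}
    alignments: list[Alignment] = []
    unaligned: list[str] = []
    for cname, cseq in contigs.items():
        c_unique = _unique_code_positions(cseq, anchor_k)
        best: tuple[int, str, list[tuple[int, int]]] | None = None
        for rname, runique in ref_unique.items():
            pairs = [(cp, runique[code]) for code, cp in c_unique.items() if code in runique]
            if best is None or len(pairs) > best[0]:
                best = (len(pairs), rname, pairs)
        if best is None or best[0] == 0:
            unaligned.append(cname)
            continue
        _, rname, pairs = best
        chain = _chain_anchors(pairs)
        if not chain:
            unaligned.append(cname)
            continue
        # anchors that overlap a kept predecessor must share its diagonal,
        # otherwise the walk below would desynchronize the two coordinates
        cleaned = [chain[0]]
        for cb, rb in chain[1:]:
            ca, ra = cleaned[-1]
            if (cb < ca + anchor_k or rb < ra + anchor_k) and (cb - ca != rb - ra):
                continue
            cleaned.append((cb, rb))
        chain = cleaned
        rseq = reference[rname]
        ops: list[tuple[str, int]] = []

        def _extend(op: str, n: int) -> None:
            if n <= 0:
                return
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + n)
            else:
                ops.append((op, n))

        # leading ends are aligned globally: the synthetic contigs span their
        # chromosome, so ends correspond (documented desk-scale assumption)
        c_cursor, r_cursor = 0, 0
        first_c, first_r = chain[0]
        for op, n in _edlib_ops(cseq[c_cursor:first_c], rseq[r_cursor:first_r]):
            _extend(op, n)
        c_cursor, r_cursor = first_c, first_r
        for (ca, ra), (cb, rb) in zip(chain, chain[1:]):
            step_c, step_r = ca + anchor_k, ra + anchor_k
            if cb < step_c or rb < step_r:  # overlapping anchors: match through
                adv = min(cb - ca, rb - ra)
                _extend("=", adv)
                c_cursor, r_cursor = ca + adv, ra + adv
                continue
            _extend("=", anchor_k)
            for op, n in _edlib_ops(cseq[step_c:cb], rseq[step_r:rb]):
                _extend(op, n)
            c_cursor, r_cursor = cb, rb
        last_c, last_r = chain[-1]
        _extend("=", anchor_k)
        for op, n in _edlib_ops(cseq[last_c + anchor_k :], rseq[last_r + anchor_k :]):
            _extend(op, n)
        # edlib labels matches '=' and mismatches 'X' already
        alignments.append(
            Alignment(
                contig=cname,
                ref_chrom=rname,
                ref_start=0,
                ref_end=len(rseq),
                contig_start=0,
                contig_end=len(cseq),
                strand="+",
                ops=ops,
            )
        )
    return alignments, unaligned


# -- variant extraction -----------------------------------------------------


def left_normalize(pos: int, ref: str, alt: str, refseq: str) -> tuple[int, str, str]:
    """Left-align and make parsimonious one biallelic record (VCF convention)."""
    ref = ref.upper()
    alt = alt.upper()
    # trim identical trailing bases, shifting left when alleles empty out
    while True:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if len(ref) > 1 and len(alt) > 1:
            break
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if pos == 0:
                break
            pos -= 1
            prev = refseq[pos]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
        else:
            break
    # trim identical leading bases (keep one anchor for indels)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def alignment_edits(aln: Alignment, contig_seq: str, refseq: str) -> list[tuple[int, str, str]]:
    """Per-op edits (ref_pos, ref_allele, alt_allele), SNVs split per base."""
    edits: list[tuple[int, str, str]] = []
    c, r = aln.contig_start, aln.ref_start
    for op, n in aln.ops:
        if op == "=":
            c += n
            r += n
        elif op == "X":
            for i in range(n):
                edits.append((r + i, refseq[r + i], contig_seq[c + i]))
            c += n
            r += n
        elif op == "I":  # insertion relative to the reference
            anchor = max(r - 1, 0)
            edits.append((anchor, refseq[anchor], refseq[anchor] + contig_seq[c : c + n]))
            c += n
        elif op == "D":
            anchor = max(r - 1, 0)
            edits.append((anchor, refseq[anchor] + refseq[r : r + n], refseq[anchor]))
            r += n
        else:
            raise ValueError(f"unexpected op {op!r}")
    return [left_normalize(p, ref, alt, refseq) for p, ref, alt in edits]


def call_variants(
    alns_hap1: Sequence[Alignment],
    alns_hap2: Sequence[Alignment],
    reference: Mapping[str, str],
    hap1_contigs: Mapping[str, str] | None = None,
    hap2_contigs: Mapping[str, str] | None = None,
    hap1_edits: Mapping[str, list] | None = None,
    hap2_edits: Mapping[str, list] | None = None,
) -> tuple[list[VariantRecord], dict[str, list[tuple[int, int]]]]:
    """Phased variants + confident-coverage regions from two haplotype alignments.

    Genotype position 1 is haplotype 1 (paternal by this package's
    convention).  Edits can be supplied pre-computed; otherwise contig
    sequences are required.
    """

    def _collect(alns, contigs, pre):
        edits: dict[str, list[tuple[int, str, str]]] = {}
        cover: dict[str, list[tuple[int, int]]] = {}
        for aln in alns:
            refseq = reference[aln.ref_chrom]
            if pre is not None and aln.contig in pre:
                es = pre[aln.contig]
            else:
                es = alignment_edits(aln, contigs[aln.contig], refseq)
            edits.setdefault(aln.ref_chrom, []).extend(es)
            cover.setdefault(aln.ref_chrom, []).append((aln.ref_start, aln.ref_end))
        return edits, {c: iv.merge(v) for c, v in cover.items()}

    e1, cov1 = _collect(alns_hap1, hap1_contigs, hap1_edits)
    e2, cov2 = _collect(alns_hap2, hap2_contigs, hap2_edits)

    records: list[VariantRecord] = []
    conf: dict[str, list[tuple[int, int]]] = {}
    for chrom in reference:
        c1 = cov1.get(chrom, [])
        c2 = cov2.get(chrom, [])
        conf[chrom] = iv.intersect(c1, c2)
        sites: dict[tuple[int, str, str], list[int]] = {}
        for hap_idx, edits in ((0, e1.get(chrom, [])), (1, e2.get(chrom, []))):
            for p, ref, alt in edits:
                if ref == alt:
                    continue
                sites.setdefault((p, ref, alt), []).append(hap_idx)
        for (p, ref, alt), haps in sorted(sites.items()):
            in1 = 0 in haps
            in2 = 1 in haps
            cov_1 = iv.contains(c1, p)
            cov_2 = iv.contains(c2, p)
            if cov_1 and cov_2:
                gt = f"{int(in1)}|{int(in2)}"
                filt = "PASS"
            elif cov_1 or cov_2:
                # single-haplotype coverage: GAP2, promoted 1|. -> 1|1
                gt = "1|1"
                filt = "GAP2"
            else:
                continue
            records.append(VariantRecord(chrom, p, ref, (alt,), gt, filt))
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alts))
    return records, conf


# -- comparison -------------------------------------------------------------


def _in_regions(rec: VariantRecord, regions: Mapping[str, list[tuple[int, int]]]) -> bool:
    return rec.chrom in regions and iv.contains(regions[rec.chrom], rec.pos)


def compare_to_truth(
    query: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    conf_regions: Mapping[str, Iterable[tuple[int, int]]],
    strata: Mapping[str, Mapping[str, Iterable[tuple[int, int]]]] | None = None,
) -> BenchmarkCounts:
    """Exact-match benchmarking restricted to confident regions.

    TP requires allele and genotype identity; an allele match with a
    genotype mismatch is tallied as FP.gt (and remains a query FP); truth
    records with no allele match are FN (implicit in TOTAL − TP − FP.gt).
    """
    conf = {c: iv.merge(r) for c, r in conf_regions.items()}
    counts = _compare_subset(query, truth, conf)
    if strata:
        for name, regions in strata.items():
            sub = {
                c: iv.intersect(conf.get(c, []), iv.merge(regions.get(c, [])))
                for c in conf
            }
            counts.strata[name] = _compare_subset(query, truth, sub)
            comp = {
                c: iv.subtract(conf.get(c, []), iv.merge(regions.get(c, [])))
                for c in conf
            }
            counts.strata[f"No{name}"] = _compare_subset(query, truth, comp)
    return counts


def _compare_subset(query, truth, conf) -> BenchmarkCounts:
    def _sorted_ok(recs):
        last = {}
        for r in recs:
            if r.chrom in last and r.pos < last[r.chrom]:
                raise ValueError("records not sorted by position")
            last[r.chrom] = r.pos
        return recs

    q = [r for r in _sorted_ok(query) if _in_regions(r, conf)]
    t = [r for r in _sorted_ok(truth) if _in_regions(r, conf)]
    tmap = {r.key(): r for r in t}
    out = BenchmarkCounts(conf_size=sum(iv.total(v) for v in conf.values()))
    for r in t:
        if r.is_snp:
            out.snp_truth_total += 1
        else:
            out.indel_truth_total += 1
    seen = set()
    for r in q:
        tr = tmap.get(r.key())
        snp = r.is_snp
        if tr is not None and r.key() not in seen:
            seen.add(r.key())
            if tr.gt == r.gt:
                if snp:
                    out.snp_truth_tp += 1
                else:
                    out.indel_truth_tp += 1
            else:
                # allele match, genotype mismatch
                if snp:
                    out.snp_fp_gt += 1
                    out.snp_query_fp += 1
                else:
                    out.indel_fp_gt += 1
                    out.indel_query_fp += 1
        else:
            if snp:
                out.snp_query_fp += 1
            else:
                out.indel_query_fp += 1
    return out


def benchmark_metrics(counts: BenchmarkCounts) -> dict[str, float]:
    """The printed completeness/correctness metric table."""
    if counts.conf_size <= 0:
        raise ValueError("confident-region size must be positive")
    out: dict[str, float] = {}
    if counts.snp_truth_total > 0:
        out["SNP.Recall_ignoreGT"] = (counts.snp_truth_tp + counts.snp_fp_gt) / counts.snp_truth_total
        out["SNP.Recall"] = counts.snp_truth_tp / counts.snp_truth_total
    fp = counts.snp_query_fp + counts.indel_query_fp
    if fp == 0:
        out["QV_dip_snp_indel"] = QV_INF_SENTINEL
        out["QV_dip_infinite"] = 1.0
    else:
        out["QV_dip_snp_indel"] = -10.0 * math.log10(fp / (counts.conf_size * 2))
        out["QV_dip_infinite"] = 0.0
    for name, sub in counts.strata.items():
        for key, val in benchmark_metrics(sub).items() if sub.conf_size > 0 else []:
            out[f"{name}.{key}"] = val
    return out


def f1_score(counts: BenchmarkCounts) -> float:
    """Combined SNP+indel F1 against truth (genotype-strict)."""
    tp = counts.snp_truth_tp + counts.indel_truth_tp
    total = counts.snp_truth_total + counts.indel_truth_total
    fp = counts.snp_query_fp + counts.indel_query_fp
    if tp == 0 or total == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / total
    return 2 * prec * rec / (prec + rec)
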
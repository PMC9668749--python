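"""Haplotype-vs-haplotype diversity: variant catalogs, window densities,
coding-effect classification, heterozygosity percentage, heteroplasmy.

One haplotype assembly is aligned against the other (the second acting as
the reference), differences are cataloged with the 50-bp small/large
boundary — SNVs, small indels (<50 bp), large SVs (insertions, deletions,
inversions >=50 bp) — features that are mostly gap (more than half N) are
excluded, and the catalog is summarized as per-window densities and as a
heterozygosity percentage (affected bp over genome bp, optionally after
subtracting excluded regions such as centromeres).  Coding SNVs are
classified synonymous/non-synonymous by codon translation, and per-site
allele counts are screened for mitochondrial heteroplasmy (minor alleles
above the read-error frequency floor, default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

from . import _intervals as iv
from ._codes import revcomp
from .varbench import Alignment, align_haplotype, alignment_edits

SV_MIN_LEN = 50  # the small/large boundary used throughout


@dataclass(frozen=True)
class HetRecord:
    """One difference between haplotypes, on haplotype-2 (reference) coordinates."""

    chrom: str
    pos: int
    ref: str  # allele on h2
    alt: str  # allele on h1
    vclass: str  # SNV | INS | DEL | INV

    @property
    def affected_bp(self) -> int:
        """bp of heterozygosity the record contributes: 1 for an SNV, the
        length change plus aligned mismatch bp for indels/SVs/inversions."""
        if self.vclass == "SNV":
            return 1
        if self.vclass == "INV":
            return len(self.ref)
        return abs(len(self.alt) - len(self.ref))


@dataclass
class HetCatalog:
    snvs: list[HetRecord] = field(default_factory=list)
    small_indels: list[HetRecord] = field(default_factory=list)
    svs: list[HetRecord] = field(default_factory=list)
    unaligned: list[str] = field(default_factory=list)

    def all_records(self) -> list[HetRecord]:
        return sorted(
            self.snvs + self.small_indels + self.svs, key=lambda r: (r.chrom, r.pos)
        )

    def __len__(self) -> int:
        return len(self.snvs) + len(self.small_indels) + len(self.svs)


def _classify_edit(chrom: str, pos: int, ref: str, alt: str) -> HetRecord:
    if len(ref) == 1 and len(alt) == 1:
        return HetRecord(chrom, pos, ref, alt, "SNV")
    if min(len(ref), len(alt)) >= SV_MIN_LEN and _is_inversion(ref, alt):
        return HetRecord(chrom, pos, ref, alt, "INV")
    vclass = "INS" if len(alt) > len(ref) else "DEL"
    return HetRecord(chrom, pos, ref, alt, vclass)


_INV_BRIDGE = 20  # '=' runs this short may be chance matches inside an inversion
_INV_MAX_DIVERGENCE = 0.10


def hap_vs_hap(h1: Mapping[str, str], h2: Mapping[str, str]) -> HetCatalog:
    """Catalog all differences of haplotype 1 against haplotype 2.

    Alignment ops are grouped so a structural event is one record: an
    inverted segment aligns as a mismatch-dense block interspersed with
    chance matches, so nearby non-match ops are bridged and the grouped
    alt allele is tested against the reverse complement of the grouped
    reference allele; groups that are not inversions fall back to their
    constituent edits (per-base SNVs, anchored indels).  Features that are
    more than half gap (N) on either allele are excluded.
    """
    alns, unaligned = align_haplotype(h1, h2)
    catalog = HetCatalog(unaligned=unaligned)
    for aln in alns:
        refseq = h2[aln.ref_chrom]
        qseq = h1[aln.contig]
        for pos, ref, alt in _grouped_edits(aln, qseq, refseq):
            if ref == alt:
                continue
            n_frac_ref = ref.count("N") / len(ref) if ref else 0.0
            n_frac_alt = alt.count("N") / len(alt) if alt else 0.0
            if max(n_frac_ref, n_frac_alt) > 0.5:
                continue  # gap-majority feature
            rec = _classify_edit(aln.ref_chrom, pos, ref, alt)
            if rec.vclass == "SNV":
                catalog.snvs.append(rec)
            elif rec.vclass == "INV" or rec.affected_bp >= SV_MIN_LEN:
                catalog.svs.append(rec)
            else:
                catalog.small_indels.append(rec)
    return catalog


def _is_inversion(ref: str, alt: str) -> bool:
    if len(ref) < SV_MIN_LEN or len(alt) < SV_MIN_LEN:
        return False
    if abs(len(ref) - len(alt)) > 0.2 * max(len(ref), len(alt)):
        return False
    dist = edlib.align(revcomp(alt), ref, mode="NW", task="distance")["editDistance"]
    return dist <= _INV_MAX_DIVERGENCE * max(len(ref), len(alt))


def _grouped_edits(aln: Alignment, qseq: str, refseq: str) -> list[tuple[int, str, str]]:
    # non-match events with both coordinates
    events: list[tuple[int, int, str, int]] = []  # (rpos, qpos, op, n)
    c, r = aln.contig_start, aln.ref_start
    for op, n in aln.ops:
        if op != "=":
            events.append((r, c, op, n))
        if op in ("=", "X"):
            c += n
            r += n
        elif op == "I":
            c += n
        elif op == "D":
            r += n
    # group events separated by short '=' bridges
    groups: list[list[tuple[int, int, str, int]]] = []
    for ev in events:
        if groups:
            pr, pc, pop, pn = groups[-1][-1]
            prev_r_end = pr + (pn if pop in ("X", "D") else 0)
            if ev[0] - prev_r_end <= _INV_BRIDGE:
                groups[-1].append(ev)
                continue
        groups.append([ev])
    out: list[tuple[int, str, str]] = []
    for group in groups:
        r0, q0 = group[0][0], group[0][1]
        lr, lc, lop, ln = group[-1]
        r1 = lr + (ln if lop in ("X", "D") else 0)
        q1 = lc + (ln if lop in ("X", "I") else 0)
        g_ref = refseq[r0:r1]
        g_alt = qseq[q0:q1]
        if len(group) > 1 and _is_inversion(g_ref, g_alt):
            out.append((r0, g_ref, g_alt))
            continue
        for er, ec, op, n in group:
            if op == "X":
                run_ref = refseq[er : er + n]
                run_alt = qseq[ec : ec + n]
                if n >= SV_MIN_LEN and _is_inversion(run_ref, run_alt):
                    out.append((er, run_ref, run_alt))
                else:
                    out.extend(
                        (er + i, refseq[er + i], qseq[ec + i]) for i in range(n)
                    )
            elif op == "I":
                anchor = max(er - 1, 0)
                out.append((anchor, refseq[anchor], refseq[anchor] + qseq[ec : ec + n]))
            elif op == "D":
                anchor = max(er - 1, 0)
                out.append((anchor, refseq[anchor] + refseq[er : er + n], refseq[anchor]))
    return out


# -- window densities -------------------------------------------------------


def window_density(
    catalog: HetCatalog,
    chrom_lengths: Mapping[str, int],
    snv_window: int = 500_000,
    indel_window: int = 1_000_000,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-window counts: SNVs in 500-kb windows (plus % of window bp),
    small insertions/deletions in 1-Mb windows; last window truncated."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, L in chrom_lengths.items():
        n_snv = -(-L // snv_window)
        n_ind = -(-L // indel_window)
        tracks = {
            "snv": np.zeros(n_snv, dtype=np.int64),
            "snv_pct": np.zeros(n_snv),
            "small_ins": np.zeros(n_ind, dtype=np.int64),
            "small_del": np.zeros(n_ind, dtype=np.int64),
            "sv": np.zeros(n_ind, dtype=np.int64),
        }
        out[chrom] = tracks
    for rec in catalog.snvs:
        if rec.chrom in out:
            w = rec.pos // snv_window
            out[rec.chrom]["snv"][w] += 1
    for chrom, L in chrom_lengths.items():
        for w in range(out[chrom]["snv"].size):
            span = min(snv_window, L - w * snv_window)
            out[chrom]["snv_pct"][w] = 100.0 * out[chrom]["snv"][w] / span
    for rec in catalog.small_indels:
        if rec.chrom in out:
            key = "small_ins" if rec.vclass == "INS" else "small_del"
            out[rec.chrom][key][rec.pos // indel_window] += 1
    for rec in catalog.svs:
        if rec.chrom in out:
            out[rec.chrom]["sv"][rec.pos // indel_window] += 1
    return out


# -- coding classification --------------------------------------------------


@dataclass(frozen=True)
class CodingEffect:
    variant: HetRecord
    gene: str
    effect: str  # 'synonymous' | 'non-synonymous'


@dataclass
class CodingSummary:
    effects: list[CodingEffect]
    n_synonymous: int
    n_non_synonymous: int
    pct_synonymous: float  # one decimal
    pct_non_synonymous: float
    genes_synonymous: set[str]
    genes_non_synonymous: set[str]
    genes_exclusively_non_synonymous: set[str]
    skipped_genes: list[str]


def coding_percentages(n_synonymous: int, n_non_synonymous: int) -> tuple[float, float]:
    """Percent synonymous / non-synonymous to one decimal place."""
    total = n_synonymous + n_non_synonymous
    if total == 0:
        raise ValueError("no classified coding SNVs")
    return (
        round(100.0 * n_synonymous / total, 1),
        round(100.0 * n_non_synonymous / total, 1),
    )


def classify_coding(
    snvs: Sequence[HetRecord],
    cds_annotation: Sequence[tuple],
    reference: Mapping[str, str],
) -> CodingSummary:
    """Synonymous/non-synonymous classification of SNVs inside CDS.

    ``cds_annotation`` rows are (chrom, start, end, gene, strand[, frame]);
    multi-exon genes list one row per CDS segment, ordered 5'->3' on the
    genome.  Genes whose concatenated CDS length is not a multiple of 3
    are skipped and reported.
    """
    by_gene: dict[str, list[tuple]] = {}
    for row in cds_annotation:
        by_gene.setdefault(str(row[3]), []).append(row)
    effects: list[CodingEffect] = []
    skipped: list[str] = []
    for gene, rows in by_gene.items():
        rows = sorted(rows, key=lambda r: (r[0], int(r[1])))
        chrom = rows[0][0]
        strand = rows[0][4] if len(rows[0]) > 4 else "+"
        segs = [(int(r[1]), int(r[2])) for r in rows]
        cds_len = sum(e - s for s, e in segs)
        if cds_len % 3 != 0:
            skipped.append(gene)
            continue
        refseq = reference[chrom]
        cds_seq = "".join(refseq[s:e] for s, e in segs)
        # map genomic position -> CDS offset
        offsets: dict[int, int] = {}
        off = 0
        for s, e in segs:
            for p in range(s, e):
                offsets[p] = off
                off += 1
        for rec in snvs:
            if rec.chrom != chrom or rec.pos not in offsets:
                continue
            off = offsets[rec.pos]
            alt_seq = cds_seq[:off] + rec.alt + cds_seq[off + 1 :]
            if strand == "-":
                aa_ref = str(Seq(cds_seq).reverse_complement().translate())
                aa_alt = str(Seq(alt_seq).reverse_complement().translate())
            else:
                aa_ref = str(Seq(cds_seq).translate())
                aa_alt = str(Seq(alt_seq).translate())
            effect = "synonymous" if aa_ref == aa_alt else "non-synonymous"
            effects.append(CodingEffect(rec, gene, effect))
    n_syn = sum(1 for e in effects if e.effect == "synonymous")
    n_non = len(effects) - n_syn
    genes_syn = {e.gene for e in effects if e.effect == "synonymous"}
    genes_non = {e.gene for e in effects if e.effect == "non-synonymous"}
    if effects:
        pct_syn, pct_non = coding_percentages(n_syn, n_non)
    else:
        pct_syn = pct_non = float("nan")
    return CodingSummary(
        effects=effects,
        n_synonymous=n_syn,
        n_non_synonymous=n_non,
        pct_synonymous=pct_syn,
        pct_non_synonymous=pct_non,
        genes_synonymous=genes_syn,
        genes_non_synonymous=genes_non,
        genes_exclusively_non_synonymous=genes_non - genes_syn,
        skipped_genes=skipped,
    )


# -- heterozygosity summary -------------------------------------------------


@dataclass
class HetSummary:
    het_bp: int
    genome_bp: int
    pct: float
    per_class_bp: dict[str, int]
    per_class_n: dict[str, int]


def het_summary(
    catalog: HetCatalog,
    genome_bp: int,
    exclude: Mapping[str, Iterable[tuple[int, int]]] | None = None,
) -> HetSummary:
    """Percent of genome bp that differs between haplotypes.

    Each SNV contributes 1 bp, each indel/SV its length change (inversions
    their span).  With an exclusion map (e.g. centromeres) both the
    numerator (records inside excluded regions) and the denominator
    (excluded bp) are subtracted.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    excl = {c: iv.merge(r) for c, r in (exclude or {}).items()}
    excl_bp = sum(iv.total(v) for v in excl.values())
    if excl_bp > genome_bp:
        raise ValueError("excluded regions exceed genome size")
    het_bp = 0
    per_bp: dict[str, int] = {}
    per_n: dict[str, int] = {}
    for rec in catalog.all_records():
        if rec.chrom in excl and iv.contains(excl[rec.chrom], rec.pos):
            continue
        het_bp += rec.affected_bp
        per_bp[rec.vclass] = per_bp.get(rec.vclass, 0) + rec.affected_bp
        per_n[rec.vclass] = per_n.get(rec.vclass, 0) + 1
    denom = genome_bp - excl_bp
    return HetSummary(het_bp, denom, 100.0 * het_bp / denom, per_bp, per_n)


# -- heteroplasmy -----------------------------------------------------------


@dataclass(frozen=True)
class HeteroplasmyAllele:
    pos: int
    base: str
    count: int
    frequency: float
    pct: int  # integer-rounded percentage
    plus: int | None = None
    minus: int | None = None
    is_major: bool = False


def heteroplasmy(
    site_allele_counts: Mapping[int, Mapping[str, int | tuple[int, int]]],
    min_frac: float = 0.01,
) -> list[HeteroplasmyAllele]:
    """Minor alleles above the error-rate frequency floor (strict >).

    ``site_allele_counts`` maps position -> {base: count} or
    {base: (plus, minus)} for stranded counts.  Frequencies use the total
    of all counted bases at the site; zero-coverage sites are skipped.
    Major alleles are reported alongside for context.
    """
    out: list[HeteroplasmyAllele] = []
    for pos in sorted(site_allele_counts):
        counts = site_allele_counts[pos]
        flat: dict[str, tuple[int, int | None, int | None]] = {}
        for base, c in counts.items():
            if isinstance(c, tuple):
                flat[base] = (c[0] + c[1], c[0], c[1])
            else:
                flat[base] = (int(c), None, None)
        depth = sum(v[0] for v in flat.values())
        if depth == 0:
            continue
        major_base = max(flat, key=lambda b: flat[b][0])
        for base, (n, plus, minus) in sorted(flat.items(), key=lambda kv: -kv[1][0]):
            freq = n / depth
            if base != major_base and freq <= min_frac:
                continue
            out.append(
                HeteroplasmyAllele(
                    pos, base, n, freq, int(round(100.0 * freq)), plus, minus,
                    is_major=(base == major_base),
                )
            )
    return out
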
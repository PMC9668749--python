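"""Light-weight text I/O for the formats the toolkit exchanges.

FASTA/FASTQ go through Biopython.  BED and the molecule/map TSV dialect are
simple enough to read and write directly.  VCF support is deliberately a
4.2 subset (CHROM, POS, REF, ALT, FILTER, and a single sample's phased GT)
— the only fields the variant-benchmarking pipeline defines semantics for.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# -- FASTA / FASTQ ----------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    recs = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    SeqIO.write(recs, os.fspath(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """Returns [(full read name, sequence), ...]."""
    out = []
    for rec in SeqIO.parse(os.fspath(path), "fastq"):
        name = rec.description if rec.description else rec.id
        out.append((name, str(rec.seq).upper()))
    return out


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# -- BED --------------------------------------------------------------------


def read_bed(path) -> list[tuple]:
    """BED rows as tuples (chrom, start, end, *extra)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return rows


def write_bed(rows: Iterable[Sequence], path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# -- VCF subset -------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FILTER=<ID=PASS,Description="All filters passed">\n'
    '##FILTER=<ID=GAP2,Description="Region covered by a single haplotype alignment">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n"
)


def write_vcf(records: Iterable, path, contigs: Mapping[str, int] | None = None) -> None:
    """Write VariantRecord-like objects (chrom, pos 0-based, ref, alts, gt, filter)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(_VCF_HEADER.split("\n", 1)[1])
        for r in records:
            alts = ",".join(r.alts)
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{alts}\t.\t{r.filter}\t.\tGT\t{r.gt}\n"
            )


def read_vcf(path) -> list[tuple[str, int, str, tuple[str, ...], str, str]]:
    """Rows as (chrom, pos 0-based, ref, alts, gt, filter)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gt = f[9].split(":")[0] if len(f) > 9 else "."
            rows.append((f[0], int(f[1]) - 1, f[3], tuple(f[4].split(",")), gt, f[6]))
    return rows


# -- molecule / optical-map TSV ---------------------------------------------


def write_molecules_tsv(molecules: Iterable, path) -> None:
    """Columns: id, length, comma-separated ascending label positions (bp).

    The dialect is a flattened stand-in for BNX (molecules) / CMAP (maps):
    one row per molecule or map, label channel 1 only.
    """
    with open(path, "w") as fh:
        fh.write("#id\tlength\tlabels\n")
        for m in molecules:
            labels = ",".join(str(int(x)) for x in m.labels)
            fh.write(f"{m.id}\t{m.length}\t{labels}\n")


def read_molecules_tsv(path) -> list[tuple[str, int, list[int]]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            labels = [int(x) for x in f[2].split(",")] if len(f) > 2 and f[2] else []
            rows.append((f[0], int(f[1]), labels))
    return rows
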
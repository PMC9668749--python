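"""Synthetic diploid trios with complete ground truth.

Generates a parent–parent–child trio from a shared ancestral sequence:
each of the four parental haplotypes mutates the ancestor independently at
half the configured per-class rate, so the expected divergence between any
two haplotypes — in particular between the child's maternal and paternal
haplotypes — equals the configured rate.  The child haplotypes are
recombinants of the corresponding parent's two haplotypes (one crossover
per chromosome by default).  On top of the trio the module simulates
HiFi-like long reads, Illumina-like parental short reads, DLE1-style
optical molecules with sizing noise and label dropout, and binned coverage
tracks with implanted collapses.  Every output is a pure function of
(config, seed) and every read, molecule and variant carries its truth.

Coordinates are 0-based half-open throughout.  Truth variants are stored
per haplotype in ancestor coordinates and can be merged into a phased VCF
(child paternal allele first, matching the variant-calling convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._codes import revcomp
from .collapse import CoverageTrack
from .mapbin import Molecule, digest_to_map
from .varbench import VariantRecord, left_normalize

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

ORIGIN_TOKEN = "dipeval_truth"  # reserved read-name token carrying truth fields


@dataclass(frozen=True)
class TrioConfig:
    """Study conditions for one synthetic trio.

    Rates are per-bp probabilities of a heterozygous difference between the
    child's two haplotypes; small-indel lengths are geometric with mean
    3 bp (capped at 49 bp), SV lengths uniform in 50–5,000 bp to exercise
    the 50-bp small/large boundary.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (1_000_000,)
    snv_rate: float = 1e-3
    indel_rate: float = 1e-4
    sv_rate: float = 0.0
    recombination: int = 1
    k: int = 21  # smallest k-mer analysis the trio must support

    def __post_init__(self):
        for name in ("snv_rate", "indel_rate", "sv_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        for L in self.chrom_lengths:
            if L < 10 * self.k:
                raise ValueError(f"chromosome length {L} < 10*k={10 * self.k}: too short")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)


@dataclass(frozen=True)
class SeqVariant:
    """One implanted difference vs the ancestor, in ancestor coordinates."""

    pos: int
    ref: str
    alt: str
    vclass: str  # SNV | INS | DEL | INV

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)


HAPLOTYPE_NAMES = ("father_hap1", "father_hap2", "mother_hap1", "mother_hap2")


@dataclass
class TrioTruth:
    config: TrioConfig
    ancestor: dict[str, str]
    haplotypes: dict[str, dict[str, str]]  # member -> chrom -> sequence
    variants: dict[str, dict[str, list[SeqVariant]]]  # member -> chrom -> variants
    crossovers: dict[str, dict[str, list[int]]]  # child hap -> chrom -> positions
    read_origin: dict[str, str] = field(default_factory=dict)
    collapse_truth: list[tuple[str, int, int, int]] = field(default_factory=list)

    @property
    def father_hap1(self):
        return self.haplotypes["father_hap1"]

    @property
    def father_hap2(self):
        return self.haplotypes["father_hap2"]

    @property
    def mother_hap1(self):
        return self.haplotypes["mother_hap1"]

    @property
    def mother_hap2(self):
        return self.haplotypes["mother_hap2"]

    @property
    def child_mat(self):
        return self.haplotypes["child_mat"]

    @property
    def child_pat(self):
        return self.haplotypes["child_pat"]


# -- trio generation --------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _sample_haplotype_variants(
    rng: np.random.Generator,
    ancestor: str,
    cfg: TrioConfig,
) -> list[SeqVariant]:
    """Implant per-haplotype variants at half the configured (child-het) rates."""
    L = len(ancestor)
    events: list[tuple[int, str]] = []
    max_span = {"SNV": 1, "INDEL": 50, "SV": 5001}
    for vclass, rate in (("SNV", cfg.snv_rate / 2), ("INDEL", cfg.indel_rate / 2), ("SV", cfg.sv_rate / 2)):
        if rate <= 0:
            continue
        n = rng.binomial(L, rate)
        # keep events clear of the ends so indel anchoring and k-mer windows are safe
        lo = cfg.k
        hi = L - max_span[vclass] - cfg.k
        if hi <= lo:
            continue
        pos = rng.integers(lo, hi, size=n)
        events.extend((int(p), vclass) for p in pos)
    events.sort()
    out: list[SeqVariant] = []
    last_end = -1
    for pos, vclass in events:
        if pos <= last_end + 1:
            continue  # overlapping/adjacent events are dropped, not merged
        if vclass == "SNV":
            ref = ancestor[pos]
            alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
            out.append(SeqVariant(pos, ref, alt, "SNV"))
            last_end = pos
        elif vclass == "INDEL":
            length = min(int(rng.geometric(1 / 3.0)), 49)
            if rng.random() < 0.5:  # insertion after pos
                ins = _random_sequence(rng, length)
                out.append(SeqVariant(pos, ancestor[pos], ancestor[pos] + ins, "INS"))
                last_end = pos
            else:
                if pos + 1 + length >= L:
                    continue
                out.append(
                    SeqVariant(pos, ancestor[pos : pos + 1 + length], ancestor[pos], "DEL")
                )
                last_end = pos + length
        else:  # SV
            length = int(rng.integers(50, 5001))
            kind = rng.choice(["INS", "DEL", "INV"])
            if kind == "INS":
                ins = _random_sequence(rng, length)
                out.append(SeqVariant(pos, ancestor[pos], ancestor[pos] + ins, "INS"))
                last_end = pos
            elif kind == "DEL":
                if pos + 1 + length >= L:
                    continue
                out.append(
                    SeqVariant(pos, ancestor[pos : pos + 1 + length], ancestor[pos], "DEL")
                )
                last_end = pos + length
            else:
                if pos + length >= L:
                    continue
                seg = ancestor[pos : pos + length]
                rc = revcomp(seg)
                if rc == seg:
                    continue
                out.append(SeqVariant(pos, seg, rc, "INV"))
                last_end = pos + length - 1
    return out


def apply_variants(ancestor: str, variants: Sequence[SeqVariant]) -> str:
    """Rebuild a haplotype sequence from the ancestor and its variant list."""
    parts: list[str] = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        if v.pos < cursor:
            raise ValueError("overlapping variants")
        parts.append(ancestor[cursor : v.pos])
        parts.append(v.alt)
        cursor = v.end
    parts.append(ancestor[cursor:])
    return "".join(parts)


def gen_trio(config: TrioConfig) -> TrioTruth:
    """Generate the full trio with ground truth, deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    ancestor: dict[str, str] = {}
    haplotypes: dict[str, dict[str, str]] = {name: {} for name in HAPLOTYPE_NAMES}
    haplotypes["child_mat"] = {}
    haplotypes["child_pat"] = {}
    variants: dict[str, dict[str, list[SeqVariant]]] = {
        name: {} for name in (*HAPLOTYPE_NAMES, "child_mat", "child_pat")
    }
    crossovers = {"child_mat": {}, "child_pat": {}}
    for ci, L in enumerate(config.chrom_lengths):
        chrom = f"chr{ci + 1}"
        anc = _random_sequence(rng, L)
        ancestor[chrom] = anc
        for name in HAPLOTYPE_NAMES:
            vs = _sample_haplotype_variants(rng, anc, config)
            variants[name][chrom] = vs
            haplotypes[name][chrom] = apply_variants(anc, vs)
        for child, parent in (("child_mat", "mother"), ("child_pat", "father")):
            n_x = config.recombination
            xs = sorted(int(x) for x in rng.integers(1, L, size=n_x)) if n_x else []
            crossovers[child][chrom] = xs
            hap_order = rng.permutation([f"{parent}_hap1", f"{parent}_hap2"])
            merged: list[SeqVariant] = []
            bounds = [0, *xs, L]
            for seg_i, (s, e) in enumerate(zip(bounds, bounds[1:])):
                src = hap_order[seg_i % 2]
                merged.extend(
                    v for v in variants[src][chrom] if s <= v.pos < e and v.end <= e
                )
            merged.sort(key=lambda v: v.pos)
            # crossover may truncate a spanning variant; drop any residual overlap
            clean: list[SeqVariant] = []
            last_end = -1
            for v in merged:
                if v.pos > last_end:
                    clean.append(v)
                    last_end = v.end - 1
            variants[child][chrom] = clean
            haplotypes[child][chrom] = apply_variants(anc, clean)
    return TrioTruth(config, ancestor, haplotypes, variants, crossovers)


def child_truth_vcf(truth: TrioTruth) -> list[VariantRecord]:
    """Phased child variants vs the ancestor reference (paternal allele first).

    Records are left-normalized with the same convention the variant caller
    uses, so an error-free round trip matches exactly.
    """
    records: list[VariantRecord] = []
    for chrom, anc in truth.ancestor.items():
        sites: dict[tuple[int, str, str], list[int]] = {}
        for hap_idx, member in ((0, "child_pat"), (1, "child_mat")):
            for v in truth.variants[member].get(chrom, []):
                pos, ref, alt = left_normalize(v.pos, v.ref, v.alt, anc)
                if ref != alt:
                    sites.setdefault((pos, ref, alt), []).append(hap_idx)
        for (pos, ref, alt), haps in sorted(sites.items()):
            gt = f"{int(0 in haps)}|{int(1 in haps)}"
            records.append(VariantRecord(chrom, pos, ref, (alt,), gt, "PASS"))
    return records


# -- long reads -------------------------------------------------------------


@dataclass
class SimReads:
    """Simulated reads plus truth origins (also encoded in the read names)."""

    reads: list[tuple[str, str]]  # (name, sequence)
    origins: dict[str, str]  # read id -> origin label


def sim_long_reads(
    haps: Mapping[str, str],
    coverage: float,
    mean_len: int = 15_000,
    err_rate: float = 0.0,
    seed: int = 0,
    origins: Mapping[str, str] | None = None,
    len_sd_frac: float = 0.10,
) -> SimReads:
    """HiFi-like reads: tight length distribution, substitution+indel errors.

    ``coverage`` is the target depth over the supplied sequence set (pass
    both child haplotypes for a diploid readset).  Errors are 90%
    substitutions and 10% single-base indels at ``err_rate`` per base.
    Origin labels default to the source sequence name and are embedded in
    the read name after the reserved token, so truth needs no side file.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    names = list(haps)
    lengths = np.array([len(haps[n]) for n in names], dtype=np.float64)
    genome_bp = lengths.sum()
    max_len = int(lengths.max())
    if mean_len > max_len:
        warnings.warn(f"mean_len {mean_len} exceeds longest sequence {max_len}; reads truncated")
    n_reads = int(round(coverage * genome_bp / min(mean_len, max_len)))
    src_idx = rng.choice(len(names), size=n_reads, p=lengths / genome_bp)
    read_lens = rng.normal(mean_len, len_sd_frac * mean_len, size=n_reads)
    read_lens = np.clip(read_lens, 50, None).astype(np.int64)
    reads: list[tuple[str, str]] = []
    origin_map: dict[str, str] = {}
    for i in range(n_reads):
        src = names[int(src_idx[i])]
        seq = haps[src]
        L = min(int(read_lens[i]), len(seq))
        start = int(rng.integers(0, len(seq) - L + 1))
        frag = bytearray(seq[start : start + L], "ascii")
        if err_rate > 0:
            n_err = rng.binomial(L, err_rate)
            if n_err:
                epos = np.sort(rng.integers(0, L, size=n_err))[::-1]
                etype = rng.random(n_err)
                for p, t in zip(epos, etype):
                    p = int(p)
                    if p >= len(frag):
                        continue
                    if t < 0.9:  # substitution
                        cur = chr(frag[p])
                        frag[p] = ord("ACGT"[("ACGT".index(cur) + int(rng.integers(1, 4))) % 4])
                    elif t < 0.95:  # single-base insertion
                        frag.insert(p, ord("ACGT"[int(rng.integers(0, 4))]))
                    else:  # single-base deletion
                        del frag[p]
        strand = "+" if rng.random() < 0.5 else "-"
        out = frag.decode()
        if strand == "-":
            out = revcomp(out)
        origin = (origins or {}).get(src, src)
        rid = f"r{i:07d}"
        name = f"{rid} {ORIGIN_TOKEN}:origin={origin},src={src},start={start},end={start + L},strand={strand}"
        reads.append((name, out))
        origin_map[rid] = origin
    return SimReads(reads, origin_map)


def parse_read_origin(read_name: str) -> str | None:
    """Recover the truth origin label embedded in a simulated read name."""
    if ORIGIN_TOKEN not in read_name:
        return None
    fields = read_name.split(ORIGIN_TOKEN + ":", 1)[1]
    for part in fields.split(","):
        if part.startswith("origin="):
            return part[len("origin=") :]
    return None


def sim_short_reads(
    haps: Mapping[str, str],
    coverage: float,
    read_len: int = 150,
    err_rate: float = 0.0,
    seed: int = 0,
    origins: Mapping[str, str] | None = None,
) -> SimReads:
    """Illumina-like parental reads: fixed length, substitution errors only."""
    reads = sim_long_reads(
        haps, coverage, mean_len=read_len, err_rate=err_rate, seed=seed,
        origins=origins, len_sd_frac=0.0,
    )
    return reads


# -- optical molecules ------------------------------------------------------


@dataclass
class MoleculeSet:
    molecules: list[Molecule]
    motif: str
    flagged_zero_label: list[str] = field(default_factory=list)

    def min_length(self) -> int:
        return min(m.length for m in self.molecules) if self.molecules else 0


def sim_molecules(
    haps: Mapping[str, str],
    motif: str,
    n_molecules: int,
    min_len: int = 150_000,
    mean_len: int = 293_000,
    sizing_cv: float = 0.0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
) -> MoleculeSet:
    """DLE1-style molecules: digestion-site labels with realistic corruption.

    Lengths are min_len plus an exponential tail tuned so the default N50
    sits near 293 kb.  Label positions are the true in-silico digestion
    sites of the sampled interval, each inter-label interval perturbed by
    Gaussian sizing noise (SD = sizing_cv × interval), labels dropped
    independently at ``fn_rate`` and spurious labels added at ``fp_rate``
    per true label.  Molecules from motif-free intervals are emitted with
    zero labels and flagged.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    rng = np.random.default_rng(seed)
    names = [n for n in haps if len(haps[n]) >= min_len]
    if not names:
        raise ValueError(f"no sequence reaches min_len={min_len}")
    site_cache = {n: digest_to_map(haps[n], motif, n).labels for n in names}
    weights = np.array([len(haps[n]) for n in names], dtype=np.float64)
    weights /= weights.sum()
    molecules: list[Molecule] = []
    flagged: list[str] = []
    for i in range(n_molecules):
        src = names[int(rng.choice(len(names), p=weights))]
        seq_len = len(haps[src])
        L = min(int(min_len + rng.exponential(max(mean_len - min_len, 1))), seq_len)
        start = int(rng.integers(0, seq_len - L + 1))
        sites = site_cache[src]
        labels = sites[(sites >= start) & (sites < start + L)] - start
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            labels = np.sort(L - 1 - labels)
        if labels.size and sizing_cv > 0:
            gaps = np.diff(np.concatenate(([0], labels))).astype(np.float64)
            gaps += rng.normal(0.0, sizing_cv * gaps)
            labels = np.cumsum(np.maximum(gaps, 1.0)).astype(np.int64)
        if labels.size and fn_rate > 0:
            labels = labels[rng.random(labels.size) >= fn_rate]
        if fp_rate > 0:
            n_fp = rng.binomial(max(labels.size, 1), fp_rate)
            if n_fp:
                labels = np.concatenate([labels, rng.integers(0, L, size=n_fp)])
        labels = np.unique(labels)
        labels = labels[(labels >= 0) & (labels < L)]
        mol = Molecule(f"mol{i:06d}", L, labels, origin=(src, start, strand))
        if labels.size == 0:
            flagged.append(mol.id)
        molecules.append(mol)
    return MoleculeSet(molecules, motif, flagged)


# -- motif expansion --------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand_motif(motifs: Iterable[str] | str) -> set[str]:
    """All distinct concrete expansions of degenerate (IUPAC) motifs."""
    if isinstance(motifs, str):
        motifs = [motifs]
    out: set[str] = set()
    for motif in motifs:
        motif = motif.upper()
        for ch in motif:
            if ch not in _IUPAC:
                raise ValueError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        seqs = [""]
        for ch in motif:
            seqs = [s + b for s in seqs for b in _IUPAC[ch]]
        out.update(seqs)
    return out


# -- coverage ---------------------------------------------------------------


def sim_coverage(
    asm: Mapping[str, str] | Mapping[str, int],
    mean_depth: float,
    collapse_truth: Sequence[tuple[str, int, int, int]] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
    bin_size: int = 1000,
) -> CoverageTrack:
    """Binned depth ~ Normal(mean_depth, noise_sd), scaled by implanted copy
    number inside collapse intervals; negative samples clipped to 0."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    depths: dict[str, np.ndarray] = {}
    for chrom, seq_or_len in asm.items():
        L = seq_or_len if isinstance(seq_or_len, int) else len(seq_or_len)
        n = max(L // bin_size, 1)
        d = np.full(n, float(mean_depth))
        if noise_sd > 0:
            d += rng.normal(0.0, noise_sd, size=n)
        for c_chrom, s, e, copies in collapse_truth:
            if c_chrom != chrom:
                continue
            b0, b1 = s // bin_size, max(e // bin_size, s // bin_size + 1)
            d[b0:b1] *= copies
        depths[chrom] = np.clip(d, 0.0, None)
    return CoverageTrack(bin_size, depths)


# -- config file ------------------------------------------------------------


def read_config(path) -> TrioConfig:
    """Flat key=value text file mirroring TrioConfig."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    kwargs: dict = {}
    if "seed" in kv:
        kwargs["seed"] = int(kv["seed"])
    if "chrom_lengths" in kv:
        kwargs["chrom_lengths"] = tuple(int(x) for x in kv["chrom_lengths"].split(","))
    for fl in ("snv_rate", "indel_rate", "sv_rate"):
        if fl in kv:
            kwargs[fl] = float(kv[fl])
    for it in ("recombination", "k"):
        if it in kv:
            kwargs[it] = int(kv[it])
    return TrioConfig(**kwargs)
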
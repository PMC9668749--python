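"""Optical-map trio binning and cross-checking.

Optical maps reduce DNA to ordered label positions (nicking-enzyme motif
sites, e.g. DLE1).  A child molecule is assigned to a parental haplotype by
aligning its label pattern to each parent's maps with a dynamic program
over inter-label intervals — two consecutive intervals match when their
lengths agree within a sizing tolerance — and taking the parent with the
higher alignment confidence.  Molecules that align equally well (confidence
difference within ``tie_eps``, default 1e-2) or to neither parent are split
equally between the bins.

The cross-check exploits loci where one parent is homozygous (AA) and the
other heterozygous (AB): the child haplotype derived from the heterozygous
parent must carry allele B, so a child map carrying the shared allele A on
that haplotype is broken at the locus midpoint to stop the mis-phased
segment from propagating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._codes import revcomp


@dataclass
class OpticalMap:
    """Ordered label coordinates on one contig or consensus map."""

    contig: str
    length: int
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and not (
            (self.labels[0] >= 0)
            and (self.labels[-1] < self.length)
            and (np.diff(self.labels) > 0).all()
        ):
            raise ValueError(f"labels of {self.contig} not strictly ascending in [0, length)")

    @property
    def id(self) -> str:  # TSV dialect compatibility
        return self.contig


@dataclass
class Molecule:
    id: str
    length: int
    labels: np.ndarray
    origin: tuple | None = None  # (contig, offset, strand) truth, if simulated

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def reversed(self) -> "Molecule":
        lab = np.sort(self.length - 1 - self.labels)
        return Molecule(self.id, self.length, lab, self.origin)


@dataclass
class MapAlignment:
    molecule_id: str
    target: str
    offset: int
    orientation: str
    matched_labels: int
    score: float
    confidence: float


@dataclass
class CrossCheckLocus:
    contig: str
    start: int
    end: int
    father_genotype: str  # 'AA' or 'AB'
    mother_genotype: str
    child_haplotype: str  # which child bin was checked (MAT/PAT)
    child_assigned_allele: str  # 'A' (shared) or 'B'
    verdict: str  # 'consistent' | 'break'


# -- digestion --------------------------------------------------------------


def digest_to_map(sequence: str, motif: str, contig: str = "map") -> OpticalMap:
    """In-silico digestion: one label per motif occurrence on either strand.

    Both strands collapse to the site start on the forward strand, the CMAP
    convention for label channels.
    """
    seq = sequence.upper()
    motifs = {motif.upper()}
    motifs.add(revcomp(motif.upper()))
    sites: set[int] = set()
    for m in motifs:
        start = seq.find(m)
        while start != -1:
            sites.add(start)
            start = seq.find(m, start + 1)
    return OpticalMap(contig, len(seq), np.array(sorted(sites), dtype=np.int64))


# -- molecule alignment -----------------------------------------------------

DEFAULT_MIN_LABELS = 9
DEFAULT_SIZING_TOL = 0.10
DEFAULT_MISS_PENALTY = 0.5
DEFAULT_CONF_FLOOR = 0.5
_MAX_SKIP = 4  # max consecutive skipped labels bridged by one DP step


def _dp_align(
    mol_labels: np.ndarray,
    map_labels: np.ndarray,
    sizing_tol: float,
    miss_penalty: float,
) -> tuple[float, int, int, int] | None:
    """Best label-interval chain: (score, matched, first molecule idx, first map idx)."""
    M, N = mol_labels.size, map_labels.size
    if M == 0 or N == 0:
        return None
    p = miss_penalty
    # dp[i, j]: best score of a chain ending with molecule label i on map label j,
    # with i leading skipped molecule labels already penalized; map start is free.
    dp = np.full((M, N), -np.inf)
    matched = np.zeros((M, N), dtype=np.int32)
    first_j = np.tile(np.arange(N, dtype=np.int32), (M, 1))
    first_i = np.tile(np.arange(M, dtype=np.int32)[:, None], (1, N))
    for i in range(M):
        dp[i] = 1.0 - p * i
        matched[i] = 1
        for di in range(1, min(_MAX_SKIP, i) + 1):
            len_mol = mol_labels[i] - mol_labels[i - di]
            for dj in range(1, _MAX_SKIP + 1):
                if dj >= N:
                    break
                len_map = map_labels[dj:] - map_labels[:-dj]
                ok = np.abs(len_mol - len_map) <= sizing_tol * len_map
                cand = dp[i - di, :-dj] + 1.0 - p * ((di - 1) + (dj - 1))
                cand = np.where(ok, cand, -np.inf)
                upd = cand > dp[i, dj:]
                if upd.any():
                    dp[i, dj:][upd] = cand[upd]
                    matched[i, dj:][upd] = matched[i - di, :-dj][upd] + 1
                    first_j[i, dj:][upd] = first_j[i - di, :-dj][upd]
                    first_i[i, dj:][upd] = first_i[i - di, :-dj][upd]
    # trailing skipped molecule labels are penalized at the end
    tail = p * (M - 1 - np.arange(M))[:, None]
    final = dp - tail
    i, j = np.unravel_index(np.argmax(final), final.shape)
    if not np.isfinite(final[i, j]):
        return None
    return float(final[i, j]), int(matched[i, j]), int(first_i[i, j]), int(first_j[i, j])


def align_molecule(
    mol: Molecule,
    maps: Sequence[OpticalMap],
    sizing_tol: float = DEFAULT_SIZING_TOL,
    label_miss_penalty: float = DEFAULT_MISS_PENALTY,
    min_labels: int = DEFAULT_MIN_LABELS,
    conf_floor: float = DEFAULT_CONF_FLOOR,
) -> MapAlignment | None:
    """Best alignment of a molecule over all target maps and both orientations.

    Score = matched labels − penalties for skipped labels on either side;
    confidence = score / molecule label count, clamped to [0, 1].  Returns
    None when the molecule has fewer than ``min_labels`` labels (unalignable
    by the standard molecule filter) or no target reaches ``conf_floor``.
    """
    if mol.labels.size < min_labels:
        return None
    best: MapAlignment | None = None
    for orientation, labels in (("+", mol.labels), ("-", mol.reversed().labels)):
        for omap in maps:
            res = _dp_align(labels, omap.labels, sizing_tol, label_miss_penalty)
            if res is None:
                continue
            score, n_match, fi, fj = res
            conf = min(max(score / mol.labels.size, 0.0), 1.0)
            if best is None or score > best.score:
                offset = int(omap.labels[fj]) - int(labels[fi])
                best = MapAlignment(mol.id, omap.contig, offset, orientation, n_match, score, conf)
    if best is None or best.confidence < conf_floor:
        return None
    return best


@dataclass
class MoleculeBinResult:
    paternal: list[str]
    maternal: list[str]
    decisions: dict[str, dict]  # molecule id -> {conf_father, conf_mother, reason}


def bin_molecules(
    mols: Sequence[Molecule],
    father_maps: Sequence[OpticalMap],
    mother_maps: Sequence[OpticalMap],
    tie_eps: float = 1e-2,
    seed: int = 0,
    **align_kwargs,
) -> MoleculeBinResult:
    """Assign each molecule to the parent with higher alignment confidence.

    Ties (|Δconfidence| <= tie_eps) and unalignable molecules are split into
    two equal halves, deterministically under ``seed``.
    """
    rng = np.random.default_rng(seed)
    paternal: list[str] = []
    maternal: list[str] = []
    undecided: list[str] = []
    decisions: dict[str, dict] = {}
    for mol in mols:
        af = align_molecule(mol, father_maps, **align_kwargs)
        am = align_molecule(mol, mother_maps, **align_kwargs)
        cf = af.confidence if af else 0.0
        cm = am.confidence if am else 0.0
        entry = {"conf_father": cf, "conf_mother": cm}
        if af is None and am is None:
            entry["reason"] = "unaligned"
            undecided.append(mol.id)
        elif abs(cf - cm) <= tie_eps:
            entry["reason"] = "tie"
            undecided.append(mol.id)
        elif cf > cm:
            entry["reason"] = "confidence"
            paternal.append(mol.id)
        else:
            entry["reason"] = "confidence"
            maternal.append(mol.id)
        decisions[mol.id] = entry
    order = rng.permutation(len(undecided))
    for rank, idx in enumerate(order):
        (paternal if rank % 2 == 0 else maternal).append(undecided[idx])
        decisions[undecided[idx]]["split_to"] = "paternal" if rank % 2 == 0 else "maternal"
    return MoleculeBinResult(paternal, maternal, decisions)


# -- cross-check ------------------------------------------------------------


def _window_signature(omap: OpticalMap, start: int, end: int) -> np.ndarray:
    lab = omap.labels
    sel = lab[(lab >= start) & (lab < end)]
    return sel - start


def _same_allele(a: np.ndarray, b: np.ndarray, tol_bp: float) -> bool:
    """Two label patterns are the same allele if counts match and every
    label sits within the sizing tolerance of its counterpart."""
    if a.size != b.size:
        return False
    if a.size == 0:
        return True
    return bool(np.abs(a - b).max() <= tol_bp)


def _maps_by_contig(maps: Sequence[OpticalMap]) -> dict[str, OpticalMap]:
    return {m.contig: m for m in maps}


def cross_check(
    child_binned_maps: Mapping[str, Sequence[OpticalMap]],
    father_maps: tuple[Sequence[OpticalMap], Sequence[OpticalMap]],
    mother_maps: tuple[Sequence[OpticalMap], Sequence[OpticalMap]],
    window: int = 50_000,
    sizing_tol: float = DEFAULT_SIZING_TOL,
) -> tuple[list[CrossCheckLocus], dict[str, list[OpticalMap]]]:
    """Identify hom/het loci and break mis-phased child maps.

    ``child_binned_maps`` holds the binned child haplotype maps keyed 'MAT'
    and 'PAT'; each parent is a pair of haplotype map sets.  All maps must
    come from the same digestion motif and share contig naming.  At every
    window where exactly one parent is heterozygous (alleles A/B, with A the
    allele shared with the homozygous parent), the child haplotype from the
    heterozygous parent must carry B; carrying A instead yields a ``break``
    verdict and the child map is split at the window midpoint.
    """
    tol_bp = sizing_tol * window
    loci: list[CrossCheckLocus] = []
    breaks: dict[str, list[int]] = {}

    f1, f2 = (_maps_by_contig(m) for m in father_maps)
    m1, m2 = (_maps_by_contig(m) for m in mother_maps)
    child = {hap: _maps_by_contig(maps) for hap, maps in child_binned_maps.items()}

    contigs = set(f1) & set(f2) & set(m1) & set(m2)
    for contig in sorted(contigs):
        length = min(f1[contig].length, f2[contig].length, m1[contig].length, m2[contig].length)
        for start in range(0, length - window + 1, window):
            end = start + window
            fa = _window_signature(f1[contig], start, end)
            fb = _window_signature(f2[contig], start, end)
            ma = _window_signature(m1[contig], start, end)
            mb = _window_signature(m2[contig], start, end)
            f_het = not _same_allele(fa, fb, tol_bp)
            m_het = not _same_allele(ma, mb, tol_bp)
            if f_het == m_het:  # need exactly one heterozygous parent
                continue
            if m_het:
                hom_allele, het_alleles = fa, (ma, mb)
                het_hap, het_parent_gt, hom_parent_gt = "MAT", "AB", "AA"
            else:
                hom_allele, het_alleles = ma, (fa, fb)
                het_hap, het_parent_gt, hom_parent_gt = "PAT", "AB", "AA"
            shared = [h for h in het_alleles if _same_allele(h, hom_allele, tol_bp)]
            other = [h for h in het_alleles if not _same_allele(h, hom_allele, tol_bp)]
            if not shared or not other:
                continue  # parents do not share an allele here
            allele_a, allele_b = hom_allele, other[0]
            cmap = child.get(het_hap, {}).get(contig)
            if cmap is None or cmap.length < end:
                continue
            sig = _window_signature(cmap, start, end)
            if _same_allele(sig, allele_b, tol_bp):
                verdict, assigned = "consistent", "B"
            elif _same_allele(sig, allele_a, tol_bp):
                verdict, assigned = "break", "A"
                breaks.setdefault(f"{het_hap}:{contig}", []).append((start + end) // 2)
            else:
                continue  # child allele matches neither parent pattern; no call
            loci.append(
                CrossCheckLocus(
                    contig,
                    start,
                    end,
                    father_genotype=het_parent_gt if het_hap == "PAT" else hom_parent_gt,
                    mother_genotype=het_parent_gt if het_hap == "MAT" else hom_parent_gt,
                    child_haplotype=het_hap,
                    child_assigned_allele=assigned,
                    verdict=verdict,
                )
            )

    broken: dict[str, list[OpticalMap]] = {}
    for hap, cmaps in child_binned_maps.items():
        out: list[OpticalMap] = []
        for cmap in cmaps:
            cuts = sorted(breaks.get(f"{hap}:{cmap.contig}", []))
            if not cuts:
                out.append(cmap)
                continue
            bounds = [0] + cuts + [cmap.length]
            for i, (s, e) in enumerate(zip(bounds, bounds[1:]), 1):
                lab = cmap.labels[(cmap.labels >= s) & (cmap.labels < e)] - s
                out.append(OpticalMap(f"{cmap.contig}.{i}", e - s, lab))
        broken[hap] = out
    return loci, broken
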
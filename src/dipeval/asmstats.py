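"""Continuity statistics, telomere scanning and conservative gap patching.

Contigs are the maximal N-free runs of each scaffold — every run of one or
more N counts as a gap — and NG50 values are computed against a supplied
genome size (3 Gb for human) so assemblies of different completeness are
comparable.  Gap patching replaces an N-run only when a single donor
contig anchors to both flanks consistently; conflicting donor support
leaves the gap untouched and logged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib

from ._codes import revcomp

HUMAN_G = 3_000_000_000
TELOMERE_MOTIF = "TTAGGG"

_N_RUN = re.compile(r"N+", re.IGNORECASE)


@dataclass
class ContinuityReport:
    n_scaffolds: int
    n_contigs: int
    total_bp: int
    total_N: int
    max_scaffold: int
    scaffold_NG50: int
    contig_NG50: int
    gaps_per_scaffold: float


def _ng50(lengths: Sequence[int], G: float) -> int:
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= G / 2:
            return L
    return 0


def continuity_stats(asm: Mapping[str, str], G: float = HUMAN_G) -> ContinuityReport:
    """Scaffold/contig continuity against genome size G (N runs split contigs)."""
    if not asm:
        raise ValueError("empty assembly")
    scaffold_lens = []
    contig_lens = []
    total_N = 0
    n_gaps = 0
    for seq in asm.values():
        scaffold_lens.append(len(seq))
        gaps = _N_RUN.findall(seq)
        n_gaps += len(gaps)
        total_N += sum(len(g) for g in gaps)
        contig_lens.extend(len(c) for c in _N_RUN.split(seq) if c)
    return ContinuityReport(
        n_scaffolds=len(scaffold_lens),
        n_contigs=len(contig_lens),
        total_bp=sum(scaffold_lens),
        total_N=total_N,
        max_scaffold=max(scaffold_lens),
        scaffold_NG50=_ng50(scaffold_lens, G),
        contig_NG50=_ng50(contig_lens, G),
        gaps_per_scaffold=n_gaps / len(scaffold_lens),
    )


# -- telomeres --------------------------------------------------------------


@dataclass
class TelomereCall:
    contig: str
    p_arm: bool  # motif reverse complement at the sequence start
    q_arm: bool  # motif forward at the sequence end
    p_frac: float
    q_frac: float


def _motif_coverage(window: str, motif: str) -> float:
    """Fraction of the window covered by (possibly overlapping) motif copies."""
    if not window:
        return 0.0
    covered = bytearray(len(window))
    start = window.find(motif)
    while start != -1:
        for i in range(start, start + len(motif)):
            covered[i] = 1
        start = window.find(motif, start + 1)
    return sum(covered) / len(window)


def telomere_scan(
    asm: Mapping[str, str],
    motif: str = TELOMERE_MOTIF,
    window: int = 1000,
    min_frac: float = 0.4,
) -> list[TelomereCall]:
    """Call telomeric ends: q-arm = forward motif at the 3' end, p-arm =
    reverse-complement motif at the 5' end; threshold is closed (>=)."""
    motif = motif.upper()
    rc = revcomp(motif)
    calls = []
    for name, seq in asm.items():
        seq = seq.upper()
        w = min(window, len(seq))
        if w == 0:
            continue
        p_frac = _motif_coverage(seq[:w], rc)
        q_frac = _motif_coverage(seq[-w:], motif)
        calls.append(TelomereCall(name, p_frac >= min_frac, q_frac >= min_frac, p_frac, q_frac))
    return calls


# -- gap patching -----------------------------------------------------------


@dataclass
class PatchEvent:
    scaffold: str
    gap_start: int
    gap_end: int
    donor: str
    donor_start: int
    donor_end: int
    orientation: str
    status: str  # 'patched' | 'no_donor' | 'one_flank' | 'conflict'


def _locate(flank: str, donor: str, max_mismatch: int) -> tuple[int, int] | None:
    """Best infix location of flank in donor within the edit budget."""
    res = edlib.align(flank, donor, mode="HW", task="locations", k=max_mismatch)
    if res["editDistance"] == -1 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    return int(s), int(e) + 1  # half-open


def patch_gaps(
    scaffolds: Mapping[str, str],
    donor_contigs: Mapping[str, str],
    anchor: int = 10_000,
    max_mismatch_frac: float = 0.01,
) -> tuple[dict[str, str], list[PatchEvent]]:
    """Fill N-runs with donor sequence when exactly one donor spans the gap.

    Both flanks (up to ``anchor`` bp each) must locate in the same donor,
    in consistent orientation and order, each within ``max_mismatch_frac``
    edits; the donor sequence between the flank anchors then substitutes
    the N-run.  Donors are searched in both orientations.  Multi-donor
    support is a conflict and the gap is left unpatched.
    """
    for dname, dseq in donor_contigs.items():
        if "N" in dseq.upper():
            raise ValueError(f"donor contig {dname} contains gaps")
    patched: dict[str, str] = {}
    events: list[PatchEvent] = []
    for sname, seq in scaffolds.items():
        sequ = seq.upper()
        out_parts: list[str] = []
        cursor = 0
        for m in _N_RUN.finditer(sequ):
            gs, ge = m.start(), m.end()
            left = sequ[max(gs - anchor, 0) : gs]
            right = sequ[ge : ge + anchor]
            budget_l = int(max_mismatch_frac * len(left))
            budget_r = int(max_mismatch_frac * len(right))
            candidates: list[tuple[str, str, int, int]] = []
            one_flank_only = False
            for dname, dseq in donor_contigs.items():
                for orient, dor in (("+", dseq.upper()), ("-", revcomp(dseq.upper()))):
                    locL = _locate(left, dor, budget_l) if left else None
                    locR = _locate(right, dor, budget_r) if right else None
                    if locL and locR:
                        if locL[1] <= locR[0]:  # ordering consistent with the gap
                            candidates.append((dname, orient, locL[1], locR[0]))
                    elif locL or locR:
                        one_flank_only = True
            out_parts.append(sequ[cursor:gs])
            if len(candidates) == 1:
                dname, orient, fill_s, fill_e = candidates[0]
                dor = donor_contigs[dname].upper()
                if orient == "-":
                    dor = revcomp(dor)
                out_parts.append(dor[fill_s:fill_e])
                events.append(PatchEvent(sname, gs, ge, dname, fill_s, fill_e, orient, "patched"))
            else:
                out_parts.append(sequ[gs:ge])
                status = (
                    "conflict" if len(candidates) > 1
                    else ("one_flank" if one_flank_only else "no_donor")
                )
                events.append(PatchEvent(sname, gs, ge, "", -1, -1, ".", status))
            cursor = ge
        out_parts.append(sequ[cursor:])
        patched[sname] = "".join(out_parts)
    return patched, events
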
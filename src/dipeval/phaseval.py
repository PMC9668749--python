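"""Phase-block and switch-error evaluation from hapmer marker tracks.

Every hapmer occurrence on a contig is a parental marker; a phase block is
a maximal run of markers from one parent, tolerating short-range switches
(an opposite-label stretch of at most ``max_switches`` markers spanning at
most ``within`` bp — the convention of the upstream k-mer evaluator, since
no tolerance is printed anywhere authoritative).  The switch-error rate is
the fraction of adjacent marker pairs with different labels.  Block sizes
are summarized as NG50 against an assumed genome size (3 Gb for human).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._codes import canonical_codes_with_positions
from .kmerset import Hapmers

MAT, PAT = "MAT", "PAT"

DEFAULT_MAX_SWITCHES = 100
DEFAULT_WITHIN_BP = 20_000
HUMAN_G = 3_000_000_000


@dataclass
class MarkerTrack:
    contig: str
    positions: np.ndarray  # strictly increasing bp
    labels: np.ndarray  # array of 'MAT'/'PAT' (unicode)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("marker positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return self.positions.size


@dataclass
class PhaseBlock:
    contig: str
    start: int
    end: int  # half-open, over marker extents
    label: str
    n_markers: int
    n_switches_internal: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SwitchStats:
    n_adjacent_pairs: int
    n_switches: int
    defined: bool = True

    @property
    def rate(self) -> float:
        return self.n_switches / self.n_adjacent_pairs if self.n_adjacent_pairs else 0.0


def marker_track(contig_seq: str, hapmers: Hapmers, contig: str = "contig") -> MarkerTrack:
    """One marker per hapmer occurrence (canonical match), labeled by parent."""
    k = hapmers.k
    codes, pos = canonical_codes_with_positions(contig_seq, k)
    if codes.size == 0:
        return MarkerTrack(contig, np.empty(0, np.int64), np.empty(0, dtype="U3"))
    is_mat = hapmers.maternal.membership(codes)
    is_pat = hapmers.paternal.membership(codes)
    # hapmer sets are disjoint, so a position can only carry one label
    any_hit = is_mat | is_pat
    pos = pos[any_hit]
    labels = np.where(is_mat[any_hit], MAT, PAT)
    return MarkerTrack(contig, pos, labels)


def phase_blocks(
    track: MarkerTrack,
    max_switches: int = DEFAULT_MAX_SWITCHES,
    within: int = DEFAULT_WITHIN_BP,
) -> tuple[list[PhaseBlock], SwitchStats]:
    """Partition a marker track into phase blocks and tally switch errors.

    Markers are grouped into runs of equal label; an opposite-label run is
    a short-range switch (kept inside the block) when it has at most
    ``max_switches`` markers and spans at most ``within`` bp, otherwise it
    terminates the block and starts a new one.  Block extents cover their
    markers (k-mer start positions); unmarked terminal sequence does not
    count toward block length.
    """
    n = track.n_markers
    if n == 0:
        return [], SwitchStats(0, 0, defined=False)
    labels = track.labels
    pos = track.positions
    if n == 1:
        blocks = [PhaseBlock(track.contig, int(pos[0]), int(pos[0]) + 1, str(labels[0]), 1, 0)]
        return blocks, SwitchStats(0, 0, defined=False)

    switches = int((labels[1:] != labels[:-1]).sum())
    stats = SwitchStats(n - 1, switches)

    # runs of identical label
    boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))  # half-open marker index ranges

    blocks: list[PhaseBlock] = []
    cur_label: str | None = None
    cur_start_idx = 0
    cur_markers = 0
    cur_switch = 0

    def _close(end_idx: int):
        nonlocal cur_label, cur_markers, cur_switch
        if cur_label is None:
            return
        s = int(pos[cur_start_idx])
        e = int(pos[end_idx - 1]) + 1
        blocks.append(PhaseBlock(track.contig, s, e, cur_label, cur_markers, cur_switch))
        cur_label = None
        cur_markers = 0
        cur_switch = 0

    for s, e in zip(starts, ends):
        run_label = str(labels[s])
        run_n = int(e - s)
        run_span = int(pos[e - 1] - pos[s]) + 1
        if cur_label is None:
            cur_label, cur_start_idx, cur_markers = run_label, int(s), run_n
        elif run_label == cur_label:
            cur_markers += run_n
        elif run_n <= max_switches and run_span <= within:
            # tolerated short-range switch: stays inside the block
            cur_switch += 1
            cur_markers += run_n
        else:
            _close(int(s))
            cur_label, cur_start_idx, cur_markers = run_label, int(s), run_n
    _close(n)

    # a tolerated opposite run at the very end should not relabel the block tail;
    # majority label per block is re-derived from its markers
    for b in blocks:
        i0 = np.searchsorted(pos, b.start)
        i1 = np.searchsorted(pos, b.end)
        lab = labels[i0:i1]
        n_mat = int((lab == MAT).sum())
        b.label = MAT if n_mat * 2 >= lab.size else PAT
    return blocks, stats


def block_ng(blocks: Sequence[PhaseBlock] | Sequence[int], G: float = HUMAN_G) -> tuple[int, list[tuple[int, float]]]:
    """NG50 and the NG curve of block lengths against genome size G.

    NG50 is the largest L such that blocks of length >= L together cover at
    least G/2.  Returns (NG50, [(length, cumulative fraction of G), ...]);
    NG50 is 0 when the blocks cover less than G/2.
    """
    if G <= 0:
        raise ValueError("G must be positive")
    lengths = sorted(
        (b.length if isinstance(b, PhaseBlock) else int(b)) for b in blocks
    )[::-1]
    curve: list[tuple[int, float]] = []
    acc = 0
    ng50 = 0
    for L in lengths:
        acc += L
        curve.append((L, acc / G))
        if ng50 == 0 and acc >= G / 2:
            ng50 = L
    return ng50, curve
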
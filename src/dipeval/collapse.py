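"""Collapsed-repeat detection from read-depth tracks.

A collapse is an assembly interval represented once where the genome has
several copies, so mapped read depth rises in proportion to the missing
copies.  Regions are called where binned depth exceeds the genome-wide mean
by at least ``z`` robust standard deviations for at least ``min_len`` bp
(defaults: z=3, 15 kb), optionally filtered by common-repeat content
(dropped when more than 75% of the region is annotated repeat), and
converted to "expandable" sequence: the bp the region would occupy if
assembled at full copy number, length × depth / average coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _intervals as iv

DEFAULT_BIN = 1000


@dataclass
class CoverageTrack:
    """Binned read depth per assembly sequence (BED-graph dialect)."""

    bin_size: int
    depths: dict[str, np.ndarray]

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, d in self.depths.items():
                for i, v in enumerate(d):
                    fh.write(f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{v:.3f}\n")

    @classmethod
    def read_bedgraph(cls, path) -> "CoverageTrack":
        per: dict[str, list[tuple[int, float]]] = {}
        bin_size = None
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split()[:4]
                s, e = int(s), int(e)
                if bin_size is None:
                    bin_size = e - s
                per.setdefault(chrom, []).append((s, float(v)))
        depths = {}
        for chrom, rows in per.items():
            rows.sort()
            n = rows[-1][0] // bin_size + 1
            d = np.zeros(n)
            for s, v in rows:
                d[s // bin_size] = v
            depths[chrom] = d
        return cls(bin_size or DEFAULT_BIN, depths)


@dataclass
class CollapseRegion:
    chrom: str
    start: int
    end: int
    mean_depth: float
    repeat_frac: float = float("nan")
    expandable_bp: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


def _robust_stats(track: CoverageTrack, trim: float = 0.01) -> tuple[float, float]:
    """Genome-wide mean/SD excluding zero-depth gap bins, 1% tails trimmed."""
    pooled = np.concatenate([d[d > 0] for d in track.depths.values()])
    if pooled.size == 0:
        raise ValueError("coverage track is all zero")
    lo, hi = np.quantile(pooled, [trim, 1.0 - trim])
    core = pooled[(pooled >= lo) & (pooled <= hi)]
    if core.size == 0:
        core = pooled
    return float(core.mean()), float(core.std())


def detect_collapses(
    track: CoverageTrack,
    z: float = 3.0,
    min_len: int = 15_000,
) -> list[CollapseRegion]:
    """Maximal super-threshold runs, tolerating single-bin dips, >= min_len."""
    mean, sd = _robust_stats(track)
    threshold = mean + z * sd
    regions: list[CollapseRegion] = []
    b = track.bin_size
    for chrom, depth in track.depths.items():
        mask = depth > threshold
        if not mask.any():
            continue
        # bridge isolated single-bin dips between super-threshold neighbours
        interior = np.flatnonzero(~mask[1:-1] & mask[:-2] & mask[2:]) + 1
        mask = mask.copy()
        mask[interior] = True
        idx = np.flatnonzero(mask)
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            start, end = int(run[0]) * b, (int(run[-1]) + 1) * b
            if end - start < min_len:
                continue
            regions.append(CollapseRegion(chrom, start, end, float(depth[run].mean())))
    return regions


def filter_repeat_collapses(
    regions: Sequence[CollapseRegion],
    repeat_annotation: Iterable[tuple],
    max_repeat_frac: float = 0.75,
) -> list[CollapseRegion]:
    """Drop regions whose annotated-repeat overlap fraction exceeds the cap.

    ``repeat_annotation`` is BED-like rows (chrom, start, end, ...); overlap
    fractions are computed by exact interval intersection and recorded on
    the surviving regions.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in repeat_annotation:
        per_chrom.setdefault(row[0], []).append((int(row[1]), int(row[2])))
    merged = {c: iv.merge(v) for c, v in per_chrom.items()}
    kept = []
    for r in regions:
        cov = iv.overlap_bp(merged.get(r.chrom, []), r.start, r.end)
        frac = cov / r.length if r.length else 0.0
        r.repeat_frac = frac
        if frac <= max_repeat_frac:
            kept.append(r)
    return kept


def expandable_bp(regions: Sequence[CollapseRegion], avg_cov: float) -> float:
    """Total sequence the collapses would occupy at full copy number."""
    if avg_cov <= 0:
        raise ValueError("avg_cov must be positive")
    total = 0.0
    for r in regions:
        r.expandable_bp = r.length * r.mean_depth / avg_cov
        total += r.expandable_bp
    return total


def write_regions_bed(regions: Sequence[CollapseRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.mean_depth:.2f}\t"
                f"{r.repeat_frac:.4f}\t{r.expandable_bp:.1f}\n"
            )
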
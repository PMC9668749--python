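"""Half-open genomic interval arithmetic on plain (start, end) lists."""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable


def merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    a = merge(a)
    b = merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    a = merge(a)
    b = merge(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        jj = j
        while jj < len(b) and b[jj][0] < e:
            if b[jj][0] > cur:
                out.append((cur, b[jj][0]))
            cur = max(cur, b[jj][1])
            jj += 1
        if cur < e:
            out.append((cur, e))
    return out


def total(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge(intervals))


def contains(merged: list[tuple[int, int]], pos: int) -> bool:
    """Membership test against an already merged, sorted interval list."""
    i = bisect_right(merged, (pos, float("inf"))) - 1
    return i >= 0 and merged[i][0] <= pos < merged[i][1]


def overlap_bp(merged: list[tuple[int, int]], start: int, end: int) -> int:
    """Total bp of [start, end) covered by a merged interval list."""
    out = 0
    for s, e in merged:
        if e <= start:
            continue
        if s >= end:
            break
        out += min(e, end) - max(s, start)
    return out
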
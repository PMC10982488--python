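"""Interval arithmetic on 0-based half-open (start, end) pairs.

Shared by the QC blacklist filter, the CNV-region clustering and the
common-variant removal step.  All functions are pure and operate on plain
tuples so they stay independent of the call/region dataclasses.
"""

from __future__ import annotations


def merge_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse possibly-overlapping intervals into their sorted union."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def covered_length(target: tuple[int, int], intervals: list[tuple[int, int]]) -> int:
    """Base pairs of ``target`` covered by the union of ``intervals``."""
    s, e = target
    total = 0
    for us, ue in merge_union(intervals):
        lo, hi = max(s, us), min(e, ue)
        if lo < hi:
            total += hi - lo
    return total


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap as a fraction of the LONGER interval's length.

    This is the binding fraction of the two per-interval fractions: the
    criterion ``reciprocal_overlap(a, b) >= x`` holds iff the overlap is at
    least ``x`` of BOTH intervals' lengths.
    """
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return ov / max(a[1] - a[0], b[1] - b[0])


class UnionFind:
    """Disjoint sets over ``range(n)``; used for single-linkage clustering."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)

    def groups(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return out
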
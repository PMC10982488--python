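"""Two-pass merging of adjacent same-sample CNV fragments.

Hidden-Markov-model CNV callers occasionally split one variant into several
adjacent fragments.  Two fragments are rejoined when the gap between them is
small relative to the span of the would-be merged call: gap fraction =
gap length / merged-call length.  The merge runs in two passes with
decreasing thresholds (default <0.50, then <0.40 for best precision); the
second pass can act on gaps created by first-pass merges.

Within a pass the algorithm is deterministic: the adjacent pair with the
smallest gap fraction merges first, ties broken by leftmost start.  Calls of
the same type that outright overlap are union-merged unconditionally before
gap merging, since the gap fraction is undefined for overlapping calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import CnvCall


@dataclass
class MergePolicy:
    pass_thresholds: list[float] = field(default_factory=lambda: [0.50, 0.40])
    same_type_only: bool = True

    def __post_init__(self) -> None:
        for t in self.pass_thresholds:
            if not 0 < t < 1:
                raise ValueError(f"pass threshold {t} outside (0, 1)")


def gap_fraction(a: CnvCall, b: CnvCall) -> float:
    """Gap between two same-sample, same-chromosome calls as a fraction of
    the span of the call that would result from merging them.

    Returns 0 for abutting calls; always < 1.  ``a`` must precede ``b``.
    """
    if a.sample_id != b.sample_id or a.chrom != b.chrom:
        raise ValueError("gap_fraction requires same sample and chromosome")
    if b.start < a.end:
        raise ValueError("calls overlap; union-merge them first")
    # 0-based half-open: gap = b.start - a.end equals the 1-based inclusive
    # (b.start1 - a.end1 - 1); merged span likewise matches end - start + 1.
    return (b.start - a.end) / (b.end - a.start)


def _combine(a: CnvCall, b: CnvCall) -> CnvCall:
    # copy number from the longer constituent; probe counts summed
    cn = a.copy_number if a.length >= b.length else b.copy_number
    return CnvCall(
        sample_id=a.sample_id,
        chrom=a.chrom,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        cnv_type=a.cnv_type,
        copy_number=cn,
        num_probes=a.num_probes + b.num_probes,
        confidence=None,
    )


def _union_merge_overlapping(group: list[CnvCall]) -> list[CnvCall]:
    group = sorted(group, key=lambda c: (c.start, c.end))
    out = [group[0]]
    for c in group[1:]:
        if c.start < out[-1].end:
            out[-1] = _combine(out[-1], c)
        else:
            out.append(c)
    return out


def _merge_pass(group: list[CnvCall], threshold: float) -> list[CnvCall]:
    """Greedily merge the adjacent pair with the smallest gap fraction while
    it stays under the pass threshold."""
    group = list(group)
    while len(group) > 1:
        best_i, best_f = None, None
        for i in range(len(group) - 1):
            f = gap_fraction(group[i], group[i + 1])
            if best_f is None or f < best_f:  # strict < keeps leftmost on ties
                best_i, best_f = i, f
        if best_f is None or not best_f < threshold:
            break
        group[best_i: best_i + 2] = [_combine(group[best_i], group[best_i + 1])]
    return group


def merge_adjacent(calls: list[CnvCall], policy: MergePolicy | None = None) -> list[CnvCall]:
    """Merge adjacent fragments per (sample, chromosome, type) group.

    Deletions are never merged with duplications.  Output is sorted by
    (sample, chrom, start) and pairwise non-overlapping within each group.
    """
    policy = policy or MergePolicy()
    groups: dict[tuple, list[CnvCall]] = {}
    for c in calls:
        key = (c.sample_id, c.chrom, c.cnv_type if policy.same_type_only else None)
        groups.setdefault(key, []).append(c)
    merged: list[CnvCall] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1], str(k[2]))):
        g = _union_merge_overlapping(groups[key])
        for thr in policy.pass_thresholds:
            g = _merge_pass(g, thr)
        merged.extend(g)
    merged.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return merged
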
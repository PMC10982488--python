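"""Common-CNV reference panel and rare-variant filtering.

A stratified random subset of controls (default 200: equal parts Norwegian
males, Norwegian females, Swedish males, Swedish females) serves as an
array-specific reference for population carrier frequencies.  Panel calls
are clustered into CNV regions (CNVRs) by 50% reciprocal-overlap single
linkage, per type; a region with carrier frequency >= 2% is "common", and
any analysed call with at least half its length inside common regions of
its own type is removed.  Panel members are excluded from all further
analyses, so no analysed sample contributes to the frequency estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import UnionFind, covered_length, reciprocal_overlap
from .io_formats import CnvCall, SampleRecord


@dataclass
class CnvRegion:
    """A population-level CNV locus with its distinct-carrier frequency."""

    chrom: int
    start: int
    end: int
    cnv_type: str
    carrier_ids: frozenset[str]
    carrier_frequency: float

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ReferencePanel:
    sample_ids: frozenset[str]
    strata: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.sample_ids)


def select_reference_panel(
    controls: list[SampleRecord], size: int = 200, seed: int = 0
) -> ReferencePanel:
    """Draw ``size/4`` controls uniformly without replacement from each
    country x sex stratum.  Deterministic given the seed."""
    strata_keys = [("NO", "M"), ("NO", "F"), ("SE", "M"), ("SE", "F")]
    per_stratum = size // len(strata_keys)
    if per_stratum * len(strata_keys) != size:
        raise ValueError(f"panel size {size} not divisible by {len(strata_keys)} strata")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    strata: dict[tuple[str, str], int] = {}
    for key in strata_keys:
        pool = sorted(
            s.sample_id for s in controls
            if s.phenotype == "control" and (s.country, s.sex) == key
        )
        if len(pool) < per_stratum:
            raise ValueError(
                f"stratum {key} has only {len(pool)} controls, need {per_stratum}"
            )
        picked = rng.choice(len(pool), size=per_stratum, replace=False)
        chosen.extend(pool[i] for i in picked)
        strata[key] = per_stratum
    return ReferencePanel(sample_ids=frozenset(chosen), strata=strata)


def build_cnv_regions(
    panel_calls: list[CnvCall],
    panel: ReferencePanel,
    cluster_overlap: float = 0.5,
) -> list[CnvRegion]:
    """Single-linkage clustering of panel calls into CNVRs, per type.

    Linkage: reciprocal overlap >= ``cluster_overlap`` on both calls.  Each
    cluster spans min start .. max end of its members; carriers are counted
    as distinct sample IDs, so a sample with two member calls counts once.
    """
    stray = [c for c in panel_calls if c.sample_id not in panel.sample_ids]
    if stray:
        raise ValueError(f"panel_calls contain non-panel sample {stray[0].sample_id!r}")
    regions: list[CnvRegion] = []
    for cnv_type in ("DEL", "DUP"):
        for chrom in sorted({c.chrom for c in panel_calls}):
            group = sorted(
                (c for c in panel_calls if c.cnv_type == cnv_type and c.chrom == chrom),
                key=lambda c: (c.start, c.end),
            )
            if not group:
                continue
            uf = UnionFind(len(group))
            max_end = 0
            for i, a in enumerate(group):
                for j in range(i + 1, len(group)):
                    b = group[j]
                    if b.start >= a.end:
                        break
                    if reciprocal_overlap(a.interval(), b.interval()) >= cluster_overlap:
                        uf.union(i, j)
            for members in uf.groups().values():
                calls = [group[i] for i in members]
                carriers = frozenset(c.sample_id for c in calls)
                regions.append(
                    CnvRegion(
                        chrom=chrom,
                        start=min(c.start for c in calls),
                        end=max(c.end for c in calls),
                        cnv_type=cnv_type,
                        carrier_ids=carriers,
                        carrier_frequency=len(carriers) / panel.size,
                    )
                )
    regions.sort(key=lambda r: (r.cnv_type, r.chrom, r.start))
    return regions


def remove_common(
    calls: list[CnvCall],
    regions: list[CnvRegion],
    min_freq: float = 0.02,
    overlap: float = 0.5,
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Split calls into (rare, removed-as-common).

    A call is removed iff >= ``overlap`` of its own length is covered by the
    union of common regions (carrier frequency >= ``min_freq``) of the same
    CNV type on its chromosome.
    """
    common: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for r in regions:
        if r.carrier_frequency >= min_freq:
            common.setdefault((r.cnv_type, r.chrom), []).append(r.interval())
    rare, removed = [], []
    for c in calls:
        track = common.get((c.cnv_type, c.chrom), [])
        if track and covered_length(c.interval(), track) / c.length >= overlap:
            removed.append(c)
        else:
            rare.append(c)
    return rare, removed


def drop_panel_samples(
    samples: list[SampleRecord],
    calls: list[CnvCall],
    panel: ReferencePanel,
) -> tuple[list[SampleRecord], list[CnvCall]]:
    """Exclude panel members and all their calls from further analysis."""
    kept_samples = [s for s in samples if s.sample_id not in panel.sample_ids]
    kept_calls = [c for c in calls if c.sample_id not in panel.sample_ids]
    return kept_samples, kept_calls
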
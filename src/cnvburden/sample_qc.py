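"""Sample-level and call-level quality control.

A sample passes QC iff its array metrics satisfy LRR_SD < 0.3,
BAF_drift < 0.01 and |WF| < 0.05, and it carries at most 50 raw CNV calls
(an excessive NumCNVs indicates a low-quality array).  Calls then pass a
size/support filter (length > 50 kb, >5 probes) and a blacklist filter:
calls with at least half their length inside immunoglobulin, telomeric or
centromeric regions are spurious-call-prone and removed, unless they touch
a retained region (the HLA locus, kept for its autoimmunity relevance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import covered_length
from .io_formats import CnvCall, GenomicInterval, SampleRecord


@dataclass
class QcThresholds:
    max_lrr_sd: float = 0.3
    max_baf_drift: float = 0.01
    max_abs_wf: float = 0.05
    max_num_cnvs: int = 50
    min_length_bp: int = 50_000
    min_probes: int = 6
    max_blacklist_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("max_lrr_sd", "max_baf_drift", "max_abs_wf", "max_num_cnvs",
                     "min_length_bp", "min_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.max_blacklist_fraction <= 1:
            raise ValueError("max_blacklist_fraction must be in (0, 1]")


@dataclass
class QcReport:
    """Audit trail of exclusions; tallies sum consistently by construction."""

    samples_in: int = 0
    samples_out: int = 0
    calls_in: int = 0
    calls_out: int = 0
    exclusions_by_filter: dict[str, int] = field(default_factory=dict)
    excluded_samples: dict[str, str] = field(default_factory=dict)  # id -> reason


def filter_samples(
    samples: list[SampleRecord],
    calls: list[CnvCall],
    thresholds: QcThresholds | None = None,
) -> tuple[list[SampleRecord], list[CnvCall], QcReport]:
    """Drop metric-outlier and call-excess samples along with their calls.

    NumCNVs is computed from the raw (pre-filter) call list, matching the
    calling-stage statistic, and stored on each kept record.
    """
    thr = thresholds or QcThresholds()
    known = {s.sample_id for s in samples}
    counts: dict[str, int] = {}
    for c in calls:
        if c.sample_id not in known:
            raise ValueError(f"call references unknown sample {c.sample_id!r}")
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1

    report = QcReport(samples_in=len(samples), calls_in=len(calls))
    kept_samples = []
    for s in samples:
        s.num_cnvs = counts.get(s.sample_id, 0)
        reason = None
        if not s.lrr_sd < thr.max_lrr_sd:
            reason = "lrr_sd"
        elif not s.baf_drift < thr.max_baf_drift:
            reason = "baf_drift"
        elif not abs(s.wf) < thr.max_abs_wf:
            reason = "wf"
        elif s.num_cnvs > thr.max_num_cnvs:
            reason = "num_cnvs"
        if reason is None:
            kept_samples.append(s)
        else:
            report.excluded_samples[s.sample_id] = reason
            report.exclusions_by_filter[reason] = (
                report.exclusions_by_filter.get(reason, 0) + 1
            )
    kept_ids = {s.sample_id for s in kept_samples}
    kept_calls = [c for c in calls if c.sample_id in kept_ids]
    report.samples_out = len(kept_samples)
    report.calls_out = len(kept_calls)
    return kept_samples, kept_calls, report


def filter_calls_basic(
    calls: list[CnvCall], thresholds: QcThresholds | None = None
) -> list[CnvCall]:
    """Keep only large, well-supported calls: length > 50 kb AND >5 probes."""
    thr = thresholds or QcThresholds()
    return [
        c for c in calls
        if c.length > thr.min_length_bp and c.num_probes >= thr.min_probes
    ]


def overlap_fraction(call: CnvCall, regions: list[GenomicInterval]) -> float:
    """Fraction of the call's length covered by the union of same-chromosome
    regions.  Regions may overlap each other; double-cover counts once."""
    same = [(r.start, r.end) for r in regions if r.chrom == call.chrom]
    if not same:
        return 0.0
    return covered_length(call.interval(), same) / call.length


def exclude_blacklisted(
    calls: list[CnvCall],
    blacklist: list[GenomicInterval],
    retain: list[GenomicInterval] | None = None,
    thresholds: QcThresholds | None = None,
) -> list[CnvCall]:
    """Remove calls mostly inside blacklist regions, unless touching a
    retained region.

    A call is removed iff >= ``max_blacklist_fraction`` (default 0.5) of its
    length lies in the blacklist union AND it has zero overlap with any
    retain interval.
    """
    thr = thresholds or QcThresholds()
    retain = retain or []
    kept = []
    for c in calls:
        if overlap_fraction(c, blacklist) >= thr.max_blacklist_fraction and (
            overlap_fraction(c, retain) == 0.0
        ):
            continue
        kept.append(c)
    return kept
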
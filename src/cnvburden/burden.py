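"""Size-binned case/control CNV burden statistics.

For each CNV type (deletion/duplication) and length interval (50-100,
100-200, 200-500, 500-1000, >1000 kb) the burden is the number of rare
calls divided by the number of individuals in the group — note calls, not
carriers, so a "frequency" can exceed 1.  Group differences are tested with
a pooled two-proportion z-test (chi-square(1)-equivalent, two-sided, no
continuity correction by default) and summarised as an odds ratio with a
Wald 95% CI, treating (count, n - count) as a 2x2 table.  Ten binned tests
give a Bonferroni threshold of 0.005; overall (unbinned) per-type rows are
reported unadjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import norm

from .intervals import reciprocal_overlap
from .io_formats import CnvCall, SampleRecord


@dataclass
class SizeBins:
    """Length-bin edges in bp; membership is lo < length <= hi, last bin
    open-ended."""

    edges: list[int] = field(
        default_factory=lambda: [50_000, 100_000, 200_000, 500_000, 1_000_000]
    )

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        kb = [e // 1000 for e in self.edges]
        labels = [f"{a}-{b}kb" for a, b in zip(kb, kb[1:])]
        labels.append(f">{kb[-1]}kb")
        return labels

    def assign(self, length: int) -> str:
        if length <= self.edges[0]:
            raise ValueError(
                f"call of length {length} <= {self.edges[0]} bp reached binning "
                "(QC violation)"
            )
        for lo, hi, label in zip(self.edges, self.edges[1:], self.labels):
            if lo < length <= hi:
                return label
        return self.labels[-1]


@dataclass
class BurdenRow:
    cnv_type: str
    bin_label: str  # "all" for the overall per-type row
    case_count: int
    control_count: int
    n_cases: int
    n_controls: int
    case_freq: float
    control_freq: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    bonferroni_significant: bool | None = None  # None for unadjusted rows


def bin_by_size(
    calls: list[CnvCall], bins: SizeBins | None = None
) -> dict[tuple[str, str], list[CnvCall]]:
    """Partition calls into (cnv_type, bin label) groups by length."""
    bins = bins or SizeBins()
    out: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        out.setdefault((c.cnv_type, bins.assign(c.length)), []).append(c)
    return out


def odds_ratio(a: int, n1: int, b: int, n2: int) -> float:
    """OR of the 2x2 table ((a, n1-a), (b, n2-b)).

    Zero cells yield inf or 0.0 rather than raising; the CI is suppressed
    for those by :func:`or_confidence_interval`.
    """
    if n1 - a < 0 or n2 - b < 0:
        # call counts exceed group size: the 2x2 arithmetic is undefined
        return math.nan
    num, den = a * (n2 - b), (n1 - a) * b
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def or_confidence_interval(
    a: int, n1: int, b: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """Wald interval exp(ln OR +/- z * SE), SE from the reciprocal cell sums.

    Returns (nan, nan) when any cell is zero (SE undefined)."""
    cells = (a, n1 - a, b, n2 - b)
    if any(x <= 0 for x in cells):
        return (math.nan, math.nan)
    se = math.sqrt(sum(1 / x for x in cells))
    z = norm.ppf(1 - (1 - level) / 2)
    lor = math.log(odds_ratio(a, n1, b, n2))
    return (math.exp(lor - z * se), math.exp(lor + z * se))


def two_proportion_test(
    a: int, n1: int, b: int, n2: int, continuity: bool = False
) -> float:
    """Two-sided pooled two-sample z-test of proportions.

    Without the Yates continuity correction this is identical to the
    Pearson chi-square test on the 2x2 table; with ``continuity=True`` the
    Yates-corrected variant is used.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = a / n1, b / n2
    if p1 > 1 or p2 > 1:
        return math.nan  # call counts exceed group size; no binomial model
    pooled = (a + b) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    diff = abs(p1 - p2)
    if continuity:
        diff = max(0.0, diff - 0.5 * (1 / n1 + 1 / n2))
    z = diff / math.sqrt(var)
    return float(2 * norm.sf(z))


def _make_row(
    cnv_type: str,
    label: str,
    a: int,
    b: int,
    n1: int,
    n2: int,
    continuity: bool,
    alpha: float | None,
) -> BurdenRow:
    ci = or_confidence_interval(a, n1, b, n2)
    p = two_proportion_test(a, n1, b, n2, continuity=continuity)
    return BurdenRow(
        cnv_type=cnv_type,
        bin_label=label,
        case_count=a,
        control_count=b,
        n_cases=n1,
        n_controls=n2,
        case_freq=a / n1,
        control_freq=b / n2,
        odds_ratio=odds_ratio(a, n1, b, n2),
        ci_low=ci[0],
        ci_high=ci[1],
        p_value=p,
        bonferroni_significant=None if alpha is None else bool(p < alpha),
    )


def burden_table(
    cases: list[SampleRecord],
    controls: list[SampleRecord],
    calls: list[CnvCall],
    bins: SizeBins | None = None,
    continuity: bool = False,
    alpha: float = 0.05,
) -> list[BurdenRow]:
    """One row per (type, bin) plus an overall row per type.

    Binned rows carry a Bonferroni flag at ``alpha / m`` with m = number of
    binned tests (10 by default); overall rows are unadjusted.
    """
    bins = bins or SizeBins()
    case_ids = {s.sample_id for s in cases}
    control_ids = {s.sample_id for s in controls}
    n1, n2 = len(case_ids), len(control_ids)
    binned = bin_by_size(calls, bins)
    m = 2 * len(bins.labels)
    threshold = alpha / m
    rows: list[BurdenRow] = []
    for cnv_type in ("DEL", "DUP"):
        type_a = type_b = 0
        for label in bins.labels:
            group = binned.get((cnv_type, label), [])
            a = sum(1 for c in group if c.sample_id in case_ids)
            b = sum(1 for c in group if c.sample_id in control_ids)
            type_a, type_b = type_a + a, type_b + b
            rows.append(_make_row(cnv_type, label, a, b, n1, n2, continuity, threshold))
        rows.append(_make_row(cnv_type, "all", type_a, type_b, n1, n2, continuity, None))
    return rows


def burden_frame(rows: list[BurdenRow]) -> pd.DataFrame:
    """Tabular view of burden rows, mirroring the published table columns."""
    return pd.DataFrame(
        [
            {
                "cnv_type": r.cnv_type,
                "bin": r.bin_label,
                "case_count": r.case_count,
                "control_count": r.control_count,
                "case_freq": r.case_freq,
                "control_freq": r.control_freq,
                "OR": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "bonferroni_significant": r.bonferroni_significant,
            }
            for r in rows
        ]
    )


def find_singletons(calls: list[CnvCall], overlap: float = 0.5) -> list[CnvCall]:
    """Calls seen in exactly one individual.

    A call is a singleton iff no same-type call in any OTHER sample has
    reciprocal overlap >= ``overlap`` with it.
    """
    singletons = []
    by_group: dict[tuple[str, int], list[CnvCall]] = {}
    for c in calls:
        by_group.setdefault((c.cnv_type, c.chrom), []).append(c)
    for group in by_group.values():
        group.sort(key=lambda c: (c.start, c.end))
        for i, a in enumerate(group):
            shared = False
            for j, b in enumerate(group):
                if j == i or b.sample_id == a.sample_id:
                    continue
                if b.start >= a.end:
                    break
                if reciprocal_overlap(a.interval(), b.interval()) >= overlap:
                    shared = True
                    break
            if not shared:
                singletons.append(a)
    singletons.sort(key=lambda c: (c.sample_id, c.chrom, c.start))
    return singletons


def stratified_burden(
    cases: list[SampleRecord],
    controls: list[SampleRecord],
    calls: list[CnvCall],
    bins: SizeBins | None = None,
    group_by: str = "country",
    **kwargs,
) -> dict[str, list[BurdenRow]]:
    """Burden tables computed within each stratum (default: country).

    Strata with zero cases or zero controls are suppressed with a warning.
    """
    import warnings

    strata = sorted({getattr(s, group_by) for s in cases + controls})
    by_sample = {s.sample_id: s for s in cases + controls}
    out: dict[str, list[BurdenRow]] = {}
    for value in strata:
        sub_cases = [s for s in cases if getattr(s, group_by) == value]
        sub_controls = [s for s in controls if getattr(s, group_by) == value]
        if not sub_cases or not sub_controls:
            warnings.warn(f"stratum {value!r} lacks cases or controls; suppressed")
            continue
        sub_calls = [
            c for c in calls
            if c.sample_id in by_sample and getattr(by_sample[c.sample_id], group_by) == value
        ]
        out[value] = burden_table(sub_cases, sub_controls, sub_calls, bins, **kwargs)
    return out
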
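"""Polygenic-risk-score comparison across CNV-carrier groups.

Samples are partitioned into four groups by case/control status crossed
with carriage of at least one rare deletion larger than the size cutoff
(default >1,000 kb).  Group PRS distributions (Z-scores standardised to the
healthy-control distribution) are compared pairwise with the Wilcoxon rank
sum test, and carrier scores are placed within the control percentile
distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_formats import CnvCall, SampleRecord

CARRIER_CASE = "carrier_case"
NONCARRIER_CASE = "noncarrier_case"
CARRIER_CONTROL = "carrier_control"
NONCARRIER_CONTROL = "noncarrier_control"
GROUPS = (CARRIER_CASE, NONCARRIER_CASE, CARRIER_CONTROL, NONCARRIER_CONTROL)


@dataclass
class PrsGroupSpec:
    """Carrier rule: >=1 rare deletion strictly longer than ``min_del_size``."""

    min_del_size: int = 1_000_000
    cnv_type: str = "DEL"


def assign_groups(
    samples: list[SampleRecord],
    calls: list[CnvCall],
    spec: PrsGroupSpec | None = None,
    prs: dict[str, float] | None = None,
) -> dict[str, list[str]]:
    """Partition samples into the four carrier x phenotype groups.

    Samples missing a PRS value (when ``prs`` is given) are excluded with a
    warning.  Group lists are sorted for determinism.
    """
    spec = spec or PrsGroupSpec()
    carriers = {
        c.sample_id
        for c in calls
        if c.cnv_type == spec.cnv_type and c.length > spec.min_del_size
    }
    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    n_missing = 0
    for s in samples:
        if prs is not None and s.sample_id not in prs:
            n_missing += 1
            continue
        is_carrier = s.sample_id in carriers
        if s.phenotype == "case":
            groups[CARRIER_CASE if is_carrier else NONCARRIER_CASE].append(s.sample_id)
        else:
            groups[CARRIER_CONTROL if is_carrier else NONCARRIER_CONTROL].append(s.sample_id)
    if n_missing:
        warnings.warn(f"{n_missing} sample(s) without a PRS value excluded")
    for g in groups.values():
        g.sort()
    return groups


def wilcoxon_rank_sum(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups are small (<= 25) and
    tie-free, otherwise the normal approximation with tie correction and,
    when flagged, continuity correction.  Returns (U statistic of ``x``,
    two-sided p).  Identical constant samples give p = 1.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return (len(x) * len(y) / 2.0, 1.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(len(x), len(y)) <= 25:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=continuity,
        )
    return (float(res.statistic), float(res.pvalue))


def compare_prs_groups(
    groups: dict[str, list[str]],
    prs: dict[str, float],
    continuity: bool = True,
) -> dict[str, pd.DataFrame]:
    """Groupwise PRS summary and all pairwise Wilcoxon tests.

    Returns ``{"summary": ..., "pairwise": ..., "carrier_placement": ...}``:
    per-group n/median, pairwise two-sided p-values (empty groups
    suppressed), and the placement of carrier-case scores within the
    control distribution (fraction above the control 75th percentile).
    """
    scores = {g: np.array([prs[i] for i in ids if i in prs]) for g, ids in groups.items()}
    summary = pd.DataFrame(
        [
            {
                "group": g,
                "n": len(v),
                "median": float(np.median(v)) if len(v) else float("nan"),
                "mean": float(np.mean(v)) if len(v) else float("nan"),
            }
            for g, v in scores.items()
        ]
    )
    pairs = []
    for g1, g2 in itertools.combinations([g for g in GROUPS if len(scores.get(g, [])) > 0], 2):
        stat, p = wilcoxon_rank_sum(scores[g1], scores[g2], continuity=continuity)
        pairs.append({"group1": g1, "group2": g2, "statistic": stat, "p": p})
    pairwise = pd.DataFrame(pairs, columns=["group1", "group2", "statistic", "p"])

    controls = np.concatenate(
        [scores.get(CARRIER_CONTROL, np.array([])), scores.get(NONCARRIER_CONTROL, np.array([]))]
    )
    carrier_cases = scores.get(CARRIER_CASE, np.array([]))
    if len(controls) and len(carrier_cases):
        q75 = float(np.percentile(controls, 75))
        placement = pd.DataFrame(
            [
                {
                    "control_q75": q75,
                    "n_carrier_cases": len(carrier_cases),
                    "n_above_control_q75": int(np.sum(carrier_cases > q75)),
                    "fraction_above_control_q75": float(np.mean(carrier_cases > q75)),
                }
            ]
        )
    else:
        placement = pd.DataFrame(
            columns=["control_q75", "n_carrier_cases", "n_above_control_q75",
                     "fraction_above_control_q75"]
        )
    return {"summary": summary, "pairwise": pairwise, "carrier_placement": placement}
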
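"""Gene-overlap counting and covariate-adjusted CNV gene-set enrichment.

The enrichment test regresses case/control status on the number of distinct
genes a sample's rare CNVs intersect, adjusting for total CNV length (kb)
and segment count — the adjustment makes it robust to case-control
differences in CNV size and CNV rate.  In subset mode the predictor is the
count of genes from a candidate list, with the all-gene count added as a
covariate, testing enrichment of pathway genes relative to all genes.  The
reported p is one-sided for a positive coefficient; with two candidate
lists plus all genes, each tested for deletions and duplications, the
Bonferroni threshold is 0.008 (6 tests).

Also provides annotation of large (>1 Mb) deletions against a local locus
catalog (trait, position, mapped gene) and merging of majority-overlapping
deletions from different samples into single report rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .intervals import UnionFind, reciprocal_overlap
from .io_formats import CnvCall, GenomicInterval

ENRICHMENT_ALPHA = 0.008  # Bonferroni for 6 tests


@dataclass
class GeneCountProfile:
    sample_id: str
    genes_total: int
    genes_subset: int
    total_kb: float
    n_segments: int


@dataclass
class EnrichmentResult:
    coefficient: float
    standard_error: float
    one_sided_p: float
    model: str
    converged: bool = True
    diagnostics: str | None = None


def count_genes(
    calls: list[CnvCall],
    genes: list[GenomicInterval],
    subset: set[str] | None = None,
) -> GeneCountProfile:
    """Count the distinct genes intersected by one sample's calls.

    A gene is hit if its transcript interval overlaps any call by >= 1 bp
    (no flanking border).  Overlapping calls hitting the same gene count it
    once.  ``total_kb`` and ``n_segments`` summarise the same calls.
    """
    if calls:
        ids = {c.sample_id for c in calls}
        if len(ids) > 1:
            raise ValueError(f"count_genes expects one sample's calls, got {sorted(ids)}")
        sample_id = calls[0].sample_id
    else:
        sample_id = ""
    hit: set[str] = set()
    by_chrom: dict[int, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for g in genes:
        for c in by_chrom.get(g.chrom, []):
            if c.start < g.end and g.start < c.end:
                hit.add(g.label)
                break
    n_subset = len(hit & subset) if subset is not None else 0
    return GeneCountProfile(
        sample_id=sample_id,
        genes_total=len(hit),
        genes_subset=n_subset,
        total_kb=sum(c.length for c in calls) / 1000.0,
        n_segments=len(calls),
    )


def enrichment_test(
    profiles: list[GeneCountProfile],
    phenotypes: dict[str, str],
    subset_mode: bool = False,
) -> EnrichmentResult:
    """Logistic enrichment test of gene counts on case status.

    All-genes mode: case ~ genes_total + total_kb + n_segments.
    Subset mode:    case ~ genes_subset + genes_total + total_kb + n_segments.
    One-sided p for a positive coefficient on the predictor of interest.
    Separation or non-convergence yields a flagged result, not a crash.
    """
    y = np.array([1.0 if phenotypes[p.sample_id] == "case" else 0.0 for p in profiles])
    if len(set(y)) < 2 or len(y) < 4:
        raise ValueError("need >=2 samples per phenotype")
    predictor = "genes_subset" if subset_mode else "genes_total"
    cols = {predictor: [getattr(p, predictor) for p in profiles]}
    if subset_mode:
        cols["genes_total"] = [p.genes_total for p in profiles]
    cols["total_kb"] = [p.total_kb for p in profiles]
    cols["n_segments"] = [p.n_segments for p in profiles]
    X = pd.DataFrame(cols, dtype=float)
    # drop degenerate covariates (constant columns make the design singular)
    keep = [c for c in X.columns if X[c].nunique() > 1 or c == predictor]
    X = X[keep]
    model_desc = "case ~ " + " + ".join(X.columns)
    X = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef = float(fit.params[predictor])
        se = float(fit.bse[predictor])
        converged = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(se)
        diag = None if converged else "non-convergence or unstable SE"
    except Exception as exc:  # separation etc.
        return EnrichmentResult(
            coefficient=float("nan"),
            standard_error=float("nan"),
            one_sided_p=float("nan"),
            model=model_desc,
            converged=False,
            diagnostics=f"{type(exc).__name__}: {exc}",
        )
    z = coef / se if se > 0 else float("nan")
    return EnrichmentResult(
        coefficient=coef,
        standard_error=se,
        one_sided_p=float(norm.sf(z)),
        model=model_desc,
        converged=converged,
        diagnostics=diag,
    )


def annotate_catalog(
    deletions: list[CnvCall],
    catalog: pd.DataFrame,
    min_size: int = 1_000_000,
) -> pd.DataFrame:
    """Survey large deletions against a locus catalog.

    ``catalog`` needs columns trait, chrom, pos (1-based bp), mapped_genes.
    For each deletion >= ``min_size`` every catalog record whose position
    falls within it is listed, grouped by trait; no hits -> "None".
    """
    rows = []
    for d in sorted(deletions, key=lambda c: (c.chrom, c.start)):
        if d.length < min_size:
            continue
        hits = []
        for rec in catalog.itertuples(index=False):
            try:
                chrom = int(str(rec.chrom).removeprefix("chr"))
            except ValueError:
                continue
            pos0 = int(rec.pos) - 1
            if chrom == d.chrom and d.start <= pos0 < d.end:
                hits.append((rec.trait, rec.mapped_genes))
        rows.append(
            {
                "sample_id": d.sample_id,
                "region": f"{d.chrom}:{d.start + 1}-{d.end}",
                "length_mb": round(d.length / 1e6, 2),
                "traits": "; ".join(t for t, _ in hits) if hits else "None",
                "mapped_genes": "; ".join(str(g) for _, g in hits) if hits else "",
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "region", "length_mb", "traits", "mapped_genes"])


def merge_overlapping_deletions_for_report(
    deletions: list[CnvCall],
    phenotypes: dict[str, str],
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Collapse majority-overlapping deletions from different samples into
    one report row each, spanning their cumulative greatest extent, with
    affected (A=) / unaffected (U=) carrier tallies."""
    rows = []
    by_chrom: dict[int, list[CnvCall]] = {}
    for d in deletions:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        uf = UnionFind(len(group))
        for i, a in enumerate(group):
            for j in range(i + 1, len(group)):
                b = group[j]
                if b.start >= a.end:
                    break
                if reciprocal_overlap(a.interval(), b.interval()) > overlap:
                    uf.union(i, j)
        for members in sorted(uf.groups().values(), key=lambda m: group[m[0]].start):
            calls = [group[i] for i in members]
            n_aff = sum(1 for c in calls if phenotypes[c.sample_id] == "case")
            n_unaff = len(calls) - n_aff
            cat = (f"A={n_aff}" if n_aff else "") + (f"U={n_unaff}" if n_unaff else "")
            start = min(c.start for c in calls)
            end = max(c.end for c in calls)
            rows.append(
                {
                    "region": f"{chrom}:{start + 1}-{end}",
                    "length_mb": round((end - start) / 1e6, 2),
                    "category": cat,
                    "n_carriers": len(calls),
                }
            )
    return pd.DataFrame(rows, columns=["region", "length_mb", "category", "n_carriers"])
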
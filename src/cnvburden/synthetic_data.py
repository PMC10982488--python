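"""Synthetic case/control CNV cohorts with the structure the analysis assumes.

The generator emulates a two-country (Norwegian/Swedish) SNP-array cohort:
per-sample array QC metrics with a configurable outlier rate, a background
of rare CNVs drawn per size bin from per-individual Poisson rates (defaults
matched to the observed control frequencies, e.g. 0.34 deletions per person
at 50-100 kb and 0.003 at >1 Mb), planted common polymorphic CNV regions
(carrier frequency 2-20%), a planted case excess of >1 Mb deletions
(default rate ratio 4), caller-style fragmentation of a fraction of calls
into adjacent pieces with small gaps (so merging can reassemble them),
blacklist regions (telomeres, centromeres, immunoglobulin loci) plus the
retained HLA interval, a gene annotation with candidate gene sets, a locus
catalog for deletion annotation, and PRS Z-scores (controls ~ N(0,1),
cases shifted).

Everything is a deterministic function of the seed; per-sample sub-streams
are derived from the master seed so cohorts are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    DEL,
    DUP,
    CnvCall,
    GenomicInterval,
    SampleRecord,
    write_rawcnv,
    write_sample_table,
)

# GRCh37 autosome lengths (bp)
GRCH37_AUTOSOMES: dict[int, int] = {
    1: 249_250_621, 2: 243_199_373, 3: 198_022_430, 4: 191_154_276,
    5: 180_915_260, 6: 171_115_067, 7: 159_138_663, 8: 146_364_022,
    9: 141_213_431, 10: 135_534_747, 11: 135_006_516, 12: 133_851_895,
    13: 115_169_878, 14: 107_349_540, 15: 102_531_392, 16: 90_354_753,
    17: 81_195_210, 18: 78_077_248, 19: 59_128_983, 20: 63_025_520,
    21: 48_129_895, 22: 51_304_566,
}

BIN_LABELS = ["50-100kb", "100-200kb", "200-500kb", "500-1000kb", ">1000kb"]
_BIN_RANGES = {
    "50-100kb": (50_001, 100_000),
    "100-200kb": (100_001, 200_000),
    "200-500kb": (200_001, 500_000),
    "500-1000kb": (500_001, 1_000_000),
    ">1000kb": (1_000_001, 3_000_000),
}

# Per-individual expected rare-call counts in controls, per (type, bin);
# matched to the observed control frequencies in a cohort of this design.
DEFAULT_RARE_RATES: dict[tuple[str, str], float] = {
    (DEL, "50-100kb"): 0.34, (DEL, "100-200kb"): 0.24, (DEL, "200-500kb"): 0.085,
    (DEL, "500-1000kb"): 0.017, (DEL, ">1000kb"): 0.003,
    (DUP, "50-100kb"): 0.28, (DUP, "100-200kb"): 0.16, (DUP, "200-500kb"): 0.13,
    (DUP, "500-1000kb"): 0.039, (DUP, ">1000kb"): 0.017,
}


@dataclass
class SyntheticCohortSpec:
    n_cases: int = 1_200
    n_controls: int = 3_800
    country_proportion_no: float = 0.5
    sex_proportion_m: float = 0.5
    chrom_lengths: dict[int, int] = field(default_factory=lambda: dict(GRCH37_AUTOSOMES))
    qc_outlier_rates: dict[str, float] = field(
        default_factory=lambda: {"lrr_sd": 0.01, "baf_drift": 0.005, "wf": 0.005}
    )
    common_region_count: int = 30
    common_freq_range: tuple[float, float] = (0.02, 0.20)
    rare_rates: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RARE_RATES)
    )
    case_rate_ratio: dict[tuple[str, str], float] = field(
        default_factory=lambda: {(DEL, ">1000kb"): 4.0}
    )
    fragmentation_rate: float = 0.2
    blacklist_contamination: float = 0.02
    gene_count: int = 1_000
    subset_fraction: float = 0.1
    prs_case_shift: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rare_rates.values()):
            raise ValueError("rare rates must be >= 0")
        lo, hi = self.common_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("common_freq_range must lie in [0, 1]")
        if any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class CohortBundle:
    """All pipeline inputs, in memory."""

    spec: SyntheticCohortSpec
    samples: list[SampleRecord]
    calls: list[CnvCall]
    blacklist: list[GenomicInterval]
    retain: list[GenomicInterval]
    genes: list[GenomicInterval]
    gene_sets: dict[str, set[str]]
    catalog: pd.DataFrame
    prs: dict[str, float]


# --- building blocks --------------------------------------------------------

def default_blacklist(chrom_lengths: dict[int, int]) -> list[GenomicInterval]:
    """Telomeric (outer 500 kb), centromeric (3 Mb at 40% of each arm) and
    immunoglobulin-locus regions."""
    regions = []
    for chrom, L in chrom_lengths.items():
        telo = min(500_000, L // 10)
        regions.append(GenomicInterval(chrom, 0, telo, "telomere_p"))
        regions.append(GenomicInterval(chrom, L - telo, L, "telomere_q"))
        cen = int(L * 0.4)
        half = min(1_500_000, L // 20)
        regions.append(GenomicInterval(chrom, cen - half, cen + half, "centromere"))
    for chrom, start, end, label in (
        (2, 89_100_000, 90_300_000, "IGK"),
        (14, 106_000_000, 107_300_000, "IGH"),
        (22, 22_300_000, 23_300_000, "IGL"),
    ):
        if chrom in chrom_lengths:
            regions.append(GenomicInterval(chrom, start, end, label))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def default_retain(chrom_lengths: dict[int, int]) -> list[GenomicInterval]:
    """The HLA region (chr6:29.6-33.1 Mb, GRCh37)."""
    if 6 not in chrom_lengths:
        return []
    return [GenomicInterval(6, 29_600_000, 33_100_000, "HLA")]


def _blacklist_arrays(blacklist: list[GenomicInterval]) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for r in blacklist:
        out.setdefault(r.chrom, [])
    for r in blacklist:
        out[r.chrom].append((r.start, r.end))
    return {c: np.array(sorted(v)) for c, v in out.items()}


def _place_interval(
    rng: np.random.Generator,
    length: int,
    chrom_lengths: dict[int, int],
    bl: dict[int, np.ndarray],
    inside_blacklist: bool = False,
) -> tuple[int, int, int]:
    """Uniformly place an interval of ``length``; by default rejection-sample
    away from the blacklist, or (for contamination) drop it inside one."""
    chroms = np.array(sorted(chrom_lengths))
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    if inside_blacklist:
        regions = [(c, s, e) for c, arr in bl.items() for s, e in arr if e - s > 0]
        c, s, e = regions[rng.integers(len(regions))]
        start = int(s + rng.integers(max(1, (e - s))))
        return c, start, start + length
    for _ in range(200):
        c = int(rng.choice(chroms, p=weights))
        hi = chrom_lengths[c] - length
        if hi <= 0:
            continue
        start = int(rng.integers(hi))
        end = start + length
        arr = bl.get(c)
        if arr is None or not np.any((arr[:, 0] < end) & (start < arr[:, 1])):
            return c, start, end
    raise RuntimeError("could not place interval outside the blacklist")


def draw_bin_counts(
    rng: np.random.Generator,
    n_samples: int,
    is_case: bool,
    rare_rates: dict[tuple[str, str], float],
    case_rate_ratio: dict[tuple[str, str], float],
) -> dict[tuple[str, str], np.ndarray]:
    """Per-sample Poisson call counts per (type, bin) — the generator's core
    rate model, also usable standalone for count-level simulation."""
    out = {}
    for key, rate in rare_rates.items():
        lam = rate * (case_rate_ratio.get(key, 1.0) if is_case else 1.0)
        out[key] = rng.poisson(lam, size=n_samples)
    return out


def _fragment(
    rng: np.random.Generator, call: CnvCall, n_pieces: int
) -> list[CnvCall]:
    """Split one call into adjacent fragments whose pairwise gap fractions
    stay below ~0.40, so the two-pass merge reassembles the original span."""
    span = call.length
    pieces = []
    n_gaps = n_pieces - 1
    # fragment lengths proportional to Dirichlet-ish draws; gaps carved so
    # each adjacent pair's gap/(pair span) lies in (0.05, 0.35)
    weights = rng.uniform(0.5, 1.5, size=n_pieces)
    weights /= weights.sum()
    frac_gaps = rng.uniform(0.05, 0.35, size=n_gaps)
    # total gap budget <= 40% of span; shrink if needed
    budget = 0.40 * span
    gap_lens = []
    cursor = call.start
    frag_lens = np.maximum((weights * span * 0.6).astype(int), 50_001)
    for i, f in enumerate(frac_gaps):
        pair = frag_lens[i] + frag_lens[i + 1]
        g = int(f * pair / (1 - f))
        gap_lens.append(g)
    total = int(frag_lens.sum() + sum(gap_lens))
    scale = min(1.0, span / total)
    probes_each = max(6, call.num_probes // n_pieces)
    for i in range(n_pieces):
        flen = max(50_001, int(frag_lens[i] * scale))
        pieces.append(
            CnvCall(
                sample_id=call.sample_id, chrom=call.chrom,
                start=cursor, end=cursor + flen,
                cnv_type=call.cnv_type, copy_number=call.copy_number,
                num_probes=probes_each,
            )
        )
        if i < n_gaps:
            cursor += flen + max(1, int(gap_lens[i] * scale))
        else:
            cursor += flen
    return pieces


def _probes_for(length: int) -> int:
    return max(6, length // 3000)


# --- cohort simulation ------------------------------------------------------

def simulate_cohort(spec: SyntheticCohortSpec) -> CohortBundle:
    """Generate a complete in-memory fixture bundle for the pipeline."""
    master = np.random.default_rng(spec.seed)
    # independent sub-streams per concern, all derived from the master seed
    seeds = master.integers(0, 2**31 - 1, size=8)
    rng_samples = np.random.default_rng(seeds[0])
    rng_common = np.random.default_rng(seeds[1])
    rng_rare = np.random.default_rng(seeds[2])
    rng_frag = np.random.default_rng(seeds[3])
    rng_genes = np.random.default_rng(seeds[4])
    rng_prs = np.random.default_rng(seeds[5])
    rng_qc = np.random.default_rng(seeds[6])
    rng_catalog = np.random.default_rng(seeds[7])

    n = spec.n_cases + spec.n_controls
    blacklist = default_blacklist(spec.chrom_lengths)
    retain = default_retain(spec.chrom_lengths)
    bl = _blacklist_arrays(blacklist)

    # samples -----------------------------------------------------------
    samples: list[SampleRecord] = []
    for i in range(n):
        phenotype = "case" if i < spec.n_cases else "control"
        sid = f"{'C' if phenotype == 'case' else 'K'}{i:05d}"
        country = "NO" if rng_samples.random() < spec.country_proportion_no else "SE"
        sex = "M" if rng_samples.random() < spec.sex_proportion_m else "F"
        lrr_sd = rng_qc.uniform(0.05, 0.25)
        baf = rng_qc.uniform(0.0, 0.008)
        wf = rng_qc.uniform(-0.04, 0.04)
        if rng_qc.random() < spec.qc_outlier_rates.get("lrr_sd", 0):
            lrr_sd = rng_qc.uniform(0.31, 0.5)
        if rng_qc.random() < spec.qc_outlier_rates.get("baf_drift", 0):
            baf = rng_qc.uniform(0.011, 0.05)
        if rng_qc.random() < spec.qc_outlier_rates.get("wf", 0):
            wf = rng_qc.choice([-1, 1]) * rng_qc.uniform(0.051, 0.2)
        samples.append(
            SampleRecord(sid, phenotype, country, sex,
                         lrr_sd=float(lrr_sd), baf_drift=float(baf), wf=float(wf))
        )

    calls: list[CnvCall] = []

    # planted common polymorphic regions --------------------------------
    lo_f, hi_f = spec.common_freq_range
    for _ in range(spec.common_region_count):
        length = int(math.exp(rng_common.uniform(math.log(60_000), math.log(400_000))))
        chrom, start, end = _place_interval(rng_common, length, spec.chrom_lengths, bl)
        cnv_type = DEL if rng_common.random() < 0.5 else DUP
        cn = 1 if cnv_type == DEL else 3
        freq = rng_common.uniform(lo_f, hi_f)
        carriers = rng_common.random(n) < freq
        for idx in np.nonzero(carriers)[0]:
            # light jitter keeps reciprocal overlap among carriers >= 0.9
            js = int(rng_common.integers(0, max(1, length // 20)))
            calls.append(
                CnvCall(samples[idx].sample_id, chrom, start + js, end + js,
                        cnv_type, cn, _probes_for(length))
            )

    # rare background + planted case excess -----------------------------
    for i, s in enumerate(samples):
        sub = np.random.default_rng(seeds[2] + 10_000 + i)  # per-sample stream
        for (cnv_type, label), rate in spec.rare_rates.items():
            lam = rate
            if s.phenotype == "case":
                lam *= spec.case_rate_ratio.get((cnv_type, label), 1.0)
            k = sub.poisson(lam)
            lo, hi = _BIN_RANGES[label]
            for _ in range(k):
                length = int(math.exp(sub.uniform(math.log(lo), math.log(hi))))
                contaminate = sub.random() < spec.blacklist_contamination
                chrom, start, end = _place_interval(
                    sub, length, spec.chrom_lengths, bl, inside_blacklist=contaminate
                )
                cn = sub.choice([0, 1], p=[0.1, 0.9]) if cnv_type == DEL else (
                    sub.choice([3, 4], p=[0.9, 0.1])
                )
                call = CnvCall(s.sample_id, chrom, start, end, cnv_type,
                               int(cn), _probes_for(length))
                if rng_frag.random() < spec.fragmentation_rate and length > 150_000:
                    calls.extend(_fragment(rng_frag, call, int(rng_frag.integers(2, 4))))
                else:
                    calls.append(call)

    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start))

    # gene annotation and candidate sets --------------------------------
    genes: list[GenomicInterval] = []
    for g in range(spec.gene_count):
        length = int(np.clip(rng_genes.lognormal(math.log(30_000), 0.8), 5_000, 200_000))
        chrom, start, end = _place_interval(rng_genes, length, spec.chrom_lengths, {})
        genes.append(GenomicInterval(chrom, start, end, f"G{g:05d}"))
    symbols = [g.label for g in genes]
    n_subset = max(1, int(spec.subset_fraction * len(symbols)))
    subset = set(rng_genes.choice(symbols, size=n_subset, replace=False))
    curated = set(rng_genes.choice(symbols, size=min(2 * n_subset, len(symbols)),
                                   replace=False))
    gene_sets = {"immune_panel": subset, "curated": curated}

    # locus catalog: positions inside a few planted large case deletions
    # plus random background loci
    big_dels = [c for c in calls if c.cnv_type == DEL and c.length > 1_000_000][:5]
    cat_rows = []
    traits = ["type 1 diabetes", "vitiligo", "multiple sclerosis",
              "lymphocyte count", "serum immune biomarker"]
    for j, d in enumerate(big_dels):
        pos = int(rng_catalog.integers(d.start + 1, d.end)) + 1  # 1-based
        cat_rows.append({"trait": traits[j % len(traits)], "chrom": d.chrom,
                         "pos": pos, "mapped_genes": f"G{j:05d}"})
    for j in range(15):
        chrom = int(rng_catalog.integers(1, 23))
        pos = int(rng_catalog.integers(1, spec.chrom_lengths[chrom]))
        cat_rows.append({"trait": traits[j % len(traits)], "chrom": chrom,
                         "pos": pos, "mapped_genes": f"B{j:05d}"})
    catalog = pd.DataFrame(cat_rows, columns=["trait", "chrom", "pos", "mapped_genes"])

    # PRS Z-scores -------------------------------------------------------
    prs = {}
    for s in samples:
        shift = spec.prs_case_shift if s.phenotype == "case" else 0.0
        prs[s.sample_id] = float(rng_prs.normal(shift, 1.0))

    return CohortBundle(spec, samples, calls, blacklist, retain, genes,
                        gene_sets, catalog, prs)


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the plain-text files the CLI pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": out / "calls.rawcnv",
        "samples": out / "samples.tsv",
        "blacklist": out / "blacklist.bed",
        "retain": out / "retain.bed",
        "genes": out / "genes.tsv",
        "catalog": out / "catalog.tsv",
        "prs": out / "prs.tsv",
    }
    write_rawcnv(bundle.calls, paths["calls"])
    write_sample_table(bundle.samples, paths["samples"])
    for key, regions in (("blacklist", bundle.blacklist), ("retain", bundle.retain)):
        with open(paths[key], "w") as fh:
            for r in regions:
                fh.write(f"chr{r.chrom}\t{r.start}\t{r.end}\t{r.label or '.'}\n")
    pd.DataFrame(
        [{"symbol": g.label, "chrom": g.chrom, "tx_start": g.start, "tx_end": g.end}
         for g in bundle.genes]
    ).to_csv(paths["genes"], sep="\t", index=False)
    bundle.catalog.to_csv(paths["catalog"], sep="\t", index=False)
    pd.DataFrame(
        [{"sample_id": k, "prs_z": v} for k, v in bundle.prs.items()]
    ).to_csv(paths["prs"], sep="\t", index=False)
    for name, symbols in bundle.gene_sets.items():
        p = out / f"geneset_{name}.txt"
        p.write_text("\n".join(sorted(symbols)) + "\n")
        paths[f"geneset_{name}"] = p
    return paths


# --- exact-table fixture ----------------------------------------------------

_REPRESENTATIVE_LENGTH = {
    "50-100kb": 75_000, "100-200kb": 150_000, "200-500kb": 300_000,
    "500-1000kb": 750_000, ">1000kb": 1_500_000,
}


def make_table_fixture(
    counts: dict[tuple[str, str], tuple[int, int]],
    n_cases: int,
    n_controls: int,
) -> CohortBundle:
    """Build a minimal cohort whose burden table reproduces a printed
    (case_count, control_count) grid exactly.

    Calls are placed at distinct, non-overlapping loci (so every call is
    rare and a singleton), with bin-representative lengths, >= 6 probes and
    all-passing QC metrics; they survive every upstream filter by
    construction.  Round-robin assignment keeps any one sample's calls far
    apart so merging cannot join them.
    """
    for (cnv_type, label), (a, b) in counts.items():
        if a < 0 or b < 0:
            raise ValueError(f"negative count for ({cnv_type}, {label})")
        if label not in _REPRESENTATIVE_LENGTH:
            raise ValueError(f"unknown bin label {label!r}")
    countries = ["NO", "SE"]
    sexes = ["M", "F"]
    samples = []
    for i in range(n_cases):
        samples.append(SampleRecord(f"C{i:05d}", "case", countries[i % 2],
                                    sexes[(i // 2) % 2], 0.1, 0.001, 0.0))
    for i in range(n_controls):
        samples.append(SampleRecord(f"K{i:05d}", "control", countries[i % 2],
                                    sexes[(i // 2) % 2], 0.1, 0.001, 0.0))

    chroms = sorted(GRCH37_AUTOSOMES)
    cursor = {c: 1_000_000 for c in chroms}
    chrom_iter = 0
    calls: list[CnvCall] = []

    def _place(length: int) -> tuple[int, int, int]:
        nonlocal chrom_iter
        for _ in range(len(chroms)):
            c = chroms[chrom_iter % len(chroms)]
            chrom_iter += 1
            if cursor[c] + length + 10_000 < GRCH37_AUTOSOMES[c] - 1_000_000:
                start = cursor[c]
                cursor[c] = start + length + 10_000
                return c, start, start + length
        raise ValueError("count grid too large to place on the genome")

    case_idx = control_idx = 0
    for (cnv_type, label), (a, b) in sorted(counts.items()):
        length = _REPRESENTATIVE_LENGTH[label]
        cn = 1 if cnv_type == DEL else 3
        for _ in range(a):
            chrom, s, e = _place(length)
            calls.append(CnvCall(f"C{case_idx % n_cases:05d}", chrom, s, e,
                                 cnv_type, cn, _probes_for(length)))
            case_idx += 1
        for _ in range(b):
            chrom, s, e = _place(length)
            calls.append(CnvCall(f"K{control_idx % n_controls:05d}", chrom, s, e,
                                 cnv_type, cn, _probes_for(length)))
            control_idx += 1

    spec = SyntheticCohortSpec(n_cases=n_cases, n_controls=n_controls,
                               common_region_count=0, fragmentation_rate=0.0)
    prs = {s.sample_id: 0.0 for s in samples}
    return CohortBundle(spec, samples, calls, [], [], [], {},
                        pd.DataFrame(columns=["trait", "chrom", "pos", "mapped_genes"]),
                        prs)


# Printed count grids for the published cohort (cases n=1182, controls n=3810)
TABLE2_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    (DEL, "50-100kb"): (435, 1298), (DEL, "100-200kb"): (260, 919),
    (DEL, "200-500kb"): (102, 323), (DEL, "500-1000kb"): (17, 65),
    (DEL, ">1000kb"): (13, 10),
    (DUP, "50-100kb"): (297, 1050), (DUP, "100-200kb"): (204, 614),
    (DUP, "200-500kb"): (157, 488), (DUP, "500-1000kb"): (48, 150),
    (DUP, ">1000kb"): (15, 65),
}
TABLE_N_CASES = 1182
TABLE_N_CONTROLS = 3810


def simulate_gene_profiles(
    rng: np.random.Generator,
    n: int,
    effect_log_odds: float = 0.0,
    subset_effect: bool = False,
) -> tuple[list, dict[str, str]]:
    """Per-sample gene-count profiles with case status drawn from a logistic
    model — the reference generative process for enrichment-test checks.

    Covariates: total_kb ~ LogNormal, n_segments ~ 1 + Poisson(2),
    genes_total ~ Poisson(0.02 * total_kb), genes_subset ~ Binomial(genes_total,
    0.3).  ``effect_log_odds`` acts on genes_subset when ``subset_effect``
    else on genes_total; baseline intercept keeps prevalence near 0.5.
    """
    from .enrichment import GeneCountProfile

    total_kb = rng.lognormal(math.log(300), 0.6, size=n)
    n_segments = 1 + rng.poisson(2.0, size=n)
    genes_total = rng.poisson(0.02 * total_kb * (n_segments / 3.0))
    genes_subset = rng.binomial(genes_total, 0.3)
    x = genes_subset if subset_effect else genes_total
    logit = effect_log_odds * (x - x.mean())
    p = 1 / (1 + np.exp(-logit))
    y = rng.random(n) < p
    profiles = [
        GeneCountProfile(f"S{i:05d}", int(genes_total[i]), int(genes_subset[i]),
                         float(total_kb[i]), int(n_segments[i]))
        for i in range(n)
    ]
    phenotypes = {f"S{i:05d}": ("case" if y[i] else "control") for i in range(n)}
    return profiles, phenotypes
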
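"""End-to-end orchestration of the rare-CNV case/control analysis.

Stages, in order: sample QC -> adjacent-call merging -> call size/probe
filter -> blacklist-region exclusion -> reference-panel selection and
common-CNV removal -> burden tables (pooled, stratified, singletons) ->
gene-set enrichment -> large-deletion catalog annotation -> PRS group
comparison.  A flow report records sample and call counts at every stage so
each exclusion is attributable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import burden as burden_mod
from . import enrichment as enrich_mod
from . import prs_compare as prs_mod
from .cnv_merge import MergePolicy, merge_adjacent
from .io_formats import (
    CnvCall,
    GenomicInterval,
    SampleRecord,
    read_gene_set,
    read_gene_table,
    read_prs_table,
    read_rawcnv,
    read_regions_bed,
    read_sample_table,
)
from .rare_filter import (
    build_cnv_regions,
    drop_panel_samples,
    remove_common,
    select_reference_panel,
)
from .sample_qc import QcThresholds, exclude_blacklisted, filter_calls_basic, filter_samples

logger = logging.getLogger("cnvburden")


@dataclass
class PipelineConfig:
    calls: str = ""
    samples: str = ""
    blacklist: str | None = None
    retain: str | None = None
    genes: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)
    catalog: str | None = None
    prs: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    merge: MergePolicy = field(default_factory=MergePolicy)
    panel_size: int = 200  # 0 disables the rare-CNV filter entirely
    min_freq: float = 0.02
    overlap: float = 0.5
    continuity: bool = False
    min_del_size: int = 1_000_000
    basic_filter_before_merge: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QcThresholds(**raw["qc"])
        if "merge" in raw:
            raw["merge"] = MergePolicy(**raw["merge"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    flow: pd.DataFrame
    burden: pd.DataFrame
    burden_by_country: dict[str, pd.DataFrame]
    singleton_burden: pd.DataFrame
    enrichment: pd.DataFrame
    annotation: pd.DataFrame
    deletion_report: pd.DataFrame
    prs: dict[str, pd.DataFrame]
    rare_calls: list[CnvCall]
    analysed_samples: list[SampleRecord]


def run_stages(
    samples: list[SampleRecord],
    calls: list[CnvCall],
    config: PipelineConfig,
    blacklist: list[GenomicInterval] | None = None,
    retain: list[GenomicInterval] | None = None,
    genes: list[GenomicInterval] | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    catalog: pd.DataFrame | None = None,
    prs: dict[str, float] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    flow_rows = [("input", len(samples), len(calls))]

    samples, calls, qc_report = filter_samples(samples, calls, config.qc)
    flow_rows.append(("sample_qc", len(samples), len(calls)))
    logger.info("sample QC: %d samples, %d calls", len(samples), len(calls))

    if config.basic_filter_before_merge:
        calls = filter_calls_basic(calls, config.qc)
        flow_rows.append(("call_size_probe_filter", len(samples), len(calls)))

    calls = merge_adjacent(calls, config.merge)
    flow_rows.append(("merge_adjacent", len(samples), len(calls)))

    if not config.basic_filter_before_merge:
        calls = filter_calls_basic(calls, config.qc)
        flow_rows.append(("call_size_probe_filter", len(samples), len(calls)))

    if blacklist:
        calls = exclude_blacklisted(calls, blacklist, retain, config.qc)
        flow_rows.append(("blacklist_exclusion", len(samples), len(calls)))

    if config.panel_size > 0:
        controls = [s for s in samples if s.phenotype == "control"]
        panel = select_reference_panel(controls, config.panel_size, config.seed)
        panel_calls = [c for c in calls if c.sample_id in panel.sample_ids]
        regions = build_cnv_regions(panel_calls, panel, config.overlap)
        samples, calls = drop_panel_samples(samples, calls, panel)
        calls, removed = remove_common(calls, regions, config.min_freq, config.overlap)
        flow_rows.append(("rare_filter", len(samples), len(calls)))
        logger.info("rare filter: removed %d common calls", len(removed))

    cases = [s for s in samples if s.phenotype == "case"]
    controls = [s for s in samples if s.phenotype == "control"]
    rows = burden_mod.burden_table(cases, controls, calls, continuity=config.continuity)
    burden_df = burden_mod.burden_frame(rows)
    by_country = {
        k: burden_mod.burden_frame(v)
        for k, v in burden_mod.stratified_burden(
            cases, controls, calls, continuity=config.continuity
        ).items()
    }
    singles = burden_mod.find_singletons(calls, config.overlap)
    singleton_df = burden_mod.burden_frame(
        burden_mod.burden_table(cases, controls, singles, continuity=config.continuity)
    )

    phenotypes = {s.sample_id: s.phenotype for s in samples}
    enrich_rows = []
    if genes:
        by_sample: dict[str, dict[str, list[CnvCall]]] = {}
        for c in calls:
            by_sample.setdefault(c.sample_id, {"DEL": [], "DUP": []})[c.cnv_type].append(c)
        for cnv_type in ("DEL", "DUP"):
            for set_name, subset in [("all_genes", None)] + sorted(
                (gene_sets or {}).items()
            ):
                profiles = [
                    enrich_mod.count_genes(
                        by_sample.get(s.sample_id, {}).get(cnv_type, []), genes, subset
                    )
                    for s in samples
                ]
                for p, s in zip(profiles, samples):
                    p.sample_id = s.sample_id
                res = enrich_mod.enrichment_test(
                    profiles, phenotypes, subset_mode=subset is not None
                )
                enrich_rows.append(
                    {
                        "cnv_type": cnv_type, "gene_set": set_name,
                        "coefficient": res.coefficient, "se": res.standard_error,
                        "one_sided_p": res.one_sided_p,
                        "significant": (res.one_sided_p < enrich_mod.ENRICHMENT_ALPHA)
                        if res.converged else None,
                        "converged": res.converged,
                    }
                )
    enrichment_df = pd.DataFrame(
        enrich_rows,
        columns=["cnv_type", "gene_set", "coefficient", "se", "one_sided_p",
                 "significant", "converged"],
    )

    large_dels = [
        c for c in calls
        if c.cnv_type == "DEL" and c.length >= config.min_del_size
    ]
    annotation = enrich_mod.annotate_catalog(
        large_dels, catalog if catalog is not None else
        pd.DataFrame(columns=["trait", "chrom", "pos", "mapped_genes"]),
        config.min_del_size,
    )
    deletion_report = enrich_mod.merge_overlapping_deletions_for_report(
        large_dels, phenotypes
    )

    prs_result: dict[str, pd.DataFrame] = {}
    if prs:
        groups = prs_mod.assign_groups(
            samples, calls, prs_mod.PrsGroupSpec(min_del_size=config.min_del_size),
            prs=prs,
        )
        prs_result = prs_mod.compare_prs_groups(groups, prs)

    flow = pd.DataFrame(flow_rows, columns=["stage", "n_samples", "n_calls"])
    return PipelineResult(
        flow=flow, burden=burden_df, burden_by_country=by_country,
        singleton_burden=singleton_df, enrichment=enrichment_df,
        annotation=annotation, deletion_report=deletion_report,
        prs=prs_result, rare_calls=calls, analysed_samples=samples,
    )


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Load every configured input from disk, run the stages, and optionally
    write the result tables as TSVs."""
    samples = read_sample_table(config.samples)
    calls = read_rawcnv(config.calls)
    blacklist = read_regions_bed(config.blacklist) if config.blacklist else []
    retain = read_regions_bed(config.retain) if config.retain else []
    genes = read_gene_table(config.genes) if config.genes else []
    known = {g.label for g in genes}
    gene_sets = {
        name: read_gene_set(path, known or None)
        for name, path in config.gene_sets.items()
    }
    catalog = pd.read_csv(config.catalog, sep="\t") if config.catalog else None
    prs = read_prs_table(config.prs) if config.prs else None

    result = run_stages(samples, calls, config, blacklist, retain, genes,
                        gene_sets, catalog, prs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.flow.to_csv(out / "flow_report.tsv", sep="\t", index=False)
        result.burden.to_csv(out / "burden.tsv", sep="\t", index=False)
        result.singleton_burden.to_csv(out / "burden_singletons.tsv", sep="\t", index=False)
        for country, df in result.burden_by_country.items():
            df.to_csv(out / f"burden_{country}.tsv", sep="\t", index=False)
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        result.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        result.deletion_report.to_csv(out / "large_deletions.tsv", sep="\t", index=False)
        for name, df in result.prs.items():
            df.to_csv(out / f"prs_{name}.tsv", sep="\t", index=False)
    return result
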
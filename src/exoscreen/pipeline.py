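"""End-to-end orchestration: restrict -> filter -> annotate -> overlap -> screens.

``run_pipeline`` consumes a :class:`PipelineConfig` (paths to the VCF,
capture targets, gene models, reference, and catalogs) and writes a report
bundle: a per-sample summary TSV, a gene-level count/density TSV, the
population-overlap JSON, and the screen report (burden + compound-het
matrix with artifact flags).  Per-stage in/out counts go to the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pyfaidx
import yaml

from . import annotate as _annotate
from . import overlap as _overlap
from . import qc as _qc
from . import screens as _screens
from .formats import (
    PopulationCatalog,
    VariantSite,
    read_catalog,
    read_gene_models,
    read_targets,
    read_vcf,
)

log = logging.getLogger("exoscreen.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and switches of one pipeline run."""

    vcf: str
    targets: str
    models: str
    reference: str
    dbsnp: str
    catalogs: dict[str, str]            # control-catalog name -> path
    out_dir: str
    samples: list[str] | None = None    # default: all samples in the VCF
    groups: dict[str, str] | None = None
    filters: _qc.FilterConfig = field(default_factory=_qc.FilterConfig)
    rare_requires_control_absence: bool = False
    non_common_mode: str = "shared_all"
    correlated_span_bp: int = 100

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filters = _qc.FilterConfig(**raw.pop("filters", {}))
        return cls(filters=filters, **raw)

    def validate_paths(self) -> None:
        paths = [self.vcf, self.targets, self.models, self.reference,
                 self.dbsnp, *self.catalogs.values()]
        missing = [p for p in paths if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")


@dataclass
class PipelineResult:
    samples: list[str]
    summaries: list[_qc.SampleSummary]
    group_means: "object"
    overlap: _overlap.OverlapReport
    gene_summaries: list[_screens.GeneSummary]
    burden_hits: list[_screens.ScreenHit]
    compound_het_hits: list[_screens.ScreenHit]
    paths: dict[str, str]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every analysis stage and write the report bundle."""
    config.validate_paths()
    os.makedirs(config.out_dir, exist_ok=True)

    scan = read_vcf(config.vcf, config.samples)
    samples = scan.samples
    log.info("stage=read_vcf snvs=%d indels_skipped=%d samples=%d",
             len(scan), scan.indel_count, len(samples))

    targets = read_targets(config.targets)
    on_target = _qc.restrict_to_targets(scan, targets)
    log.info("stage=restrict_to_targets in=%d out=%d dropped=%d",
             len(scan), len(on_target), len(scan) - len(on_target))

    dbsnp = read_catalog(config.dbsnp, "DBSNP")
    controls = [read_catalog(path, name) for name, path in sorted(config.catalogs.items())]
    log.info("stage=read_catalogs dbsnp=%d controls=%s", len(dbsnp),
             {c.name: len(c) for c in controls})

    summaries = _qc.summarize_cohort(on_target, samples, dbsnp, config.filters,
                                     scan.indels_by_sample)
    paths = {"sample_summary": os.path.join(config.out_dir, "sample_summary.tsv")}
    _qc.write_summary_table(paths["sample_summary"], summaries)
    group_means = None
    if config.groups:
        group_means = _qc.cohort_group_means(summaries, config.groups)
        paths["group_means"] = os.path.join(config.out_dir, "group_means.tsv")
        group_means.to_csv(paths["group_means"], sep="\t")
    log.info("stage=qc_summaries pass_totals=%s",
             {s.sample_id: s.n_pass_filters for s in summaries})

    pass_by_sample: dict[str, list[VariantSite]] = {
        s: _qc.sample_pass_sites(on_target, s, config.filters) for s in samples}
    passing_sites = {v.key: v for sites in pass_by_sample.values() for v in sites}
    log.info("stage=filter distinct_passing_sites=%d", len(passing_sites))

    pool = _overlap.case_pool(pass_by_sample)
    report = _overlap.overlap_report(pool, controls)
    paths["overlap"] = os.path.join(config.out_dir, "overlap.json")
    report.to_json(paths["overlap"])
    paths["overlap_row"] = os.path.join(config.out_dir, "overlap_counts.tsv")
    report.to_row_tsv(paths["overlap_row"])
    log.info("stage=overlap pool=%d shared_all=%d case_only=%d",
             len(pool), report.shared_all, report.case_only)

    reference = pyfaidx.Fasta(config.reference)
    isoforms = read_gene_models(config.models)
    annotations = _annotate.annotate_all(passing_sites.values(), isoforms, reference)
    paths["annotations"] = os.path.join(config.out_dir, "annotations.tsv")
    _annotate.write_annotations(paths["annotations"], annotations)
    log.info("stage=annotate records=%d isoforms=%d", len(annotations), len(isoforms))

    gene_symbols = sorted({iso.gene_symbol for iso in isoforms})
    gene_summaries = [
        _screens.gene_summary(g, isoforms, pass_by_sample, dbsnp, controls,
                              config.non_common_mode)
        for g in gene_symbols]
    paths["gene_summary"] = os.path.join(config.out_dir, "gene_summary.tsv")
    _screens.write_gene_table(paths["gene_summary"], gene_summaries)

    extra = tuple(controls) if config.rare_requires_control_absence else ()
    burden = _screens.burden_screen(annotations, pass_by_sample, dbsnp, extra)
    compound = _screens.compound_het_screen(annotations, pass_by_sample, dbsnp, extra)
    for hit in compound:
        hit.artifact_flags = _screens.artifact_flags(
            hit, pass_by_sample, dbsnp, config.correlated_span_bp)
    log.info("stage=screens burden_isoforms=%d compound_het_isoforms=%d",
             len(burden), len(compound))

    paths["screen_matrix"] = os.path.join(config.out_dir, "screen_matrix.tsv")
    _screens.write_screen_matrix(paths["screen_matrix"], compound, samples)
    paths["screens"] = os.path.join(config.out_dir, "screens.json")
    with open(paths["screens"], "w") as fh:
        json.dump({
            "burden": [{"isoform": h.isoform_id, "gene": h.gene_symbol,
                        "counts": h.counts} for h in burden],
            "compound_het": [{"isoform": h.isoform_id, "gene": h.gene_symbol,
                              "counts": h.counts,
                              "artifact_flags": sorted(h.artifact_flags)}
                             for h in compound],
        }, fh, indent=2, sort_keys=True)

    return PipelineResult(samples=samples, summaries=summaries,
                          group_means=group_means, overlap=report,
                          gene_summaries=gene_summaries, burden_hits=burden,
                          compound_het_hits=compound, paths=paths)
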
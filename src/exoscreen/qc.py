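"""SNV quality filtering and per-sample call summaries.

The filter chain reproduces a conservative short-read SNP-calling recipe:
a site-level Phred quality floor (QUAL strictly greater than 50), an
allele-balance ceiling at heterozygous calls (reference-read fraction
strictly below 0.75), and a local clustering rule that discards every SNV
falling in any 10 bp window containing more than two of one sample's SNVs
(dense clusters are the classic signature of misalignment).

Filters are applied per sample, to the sites at which that sample carries
an alternate allele, in the fixed order: target restriction -> quality ->
allele balance -> window density.  The order matters only for the window
rule, which sees the post-quality site list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import PopulationCatalog, TargetRegion, VariantSite

__all__ = [
    "FilterConfig",
    "SampleSummary",
    "filter_qual",
    "allele_balance",
    "filter_window_density",
    "restrict_to_targets",
    "sample_pass_sites",
    "summarize_sample",
    "summarize_cohort",
    "cohort_group_means",
    "write_summary_table",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the SNV quality-filter chain.

    min_qual
        Site QUAL must be strictly greater than this (Phred scale).
    max_allele_balance
        At heterozygous calls the allele-balance fraction must be strictly
        below this; homozygous calls and calls without depths are exempt.
    ab_mode
        Which fraction is the balance: ``"ref"`` (reference reads / total,
        the common caller convention and the default), ``"alt"``, or
        ``"max"`` (larger of the two).
    window_bp / max_snps_per_window
        A sample's SNV fails if it lies in any window of ``window_bp``
        consecutive bases holding more than ``max_snps_per_window`` of that
        sample's SNVs; every SNV inside a violating window fails.
    """

    min_qual: float = 50.0
    max_allele_balance: float = 0.75
    window_bp: int = 10
    max_snps_per_window: int = 2
    ab_mode: str = "ref"

    def __post_init__(self) -> None:
        if self.min_qual < 0 or not (0 < self.max_allele_balance <= 1):
            raise ValueError("thresholds must be positive")
        if self.window_bp < 1 or self.max_snps_per_window < 1:
            raise ValueError("window parameters must be positive")
        if self.ab_mode not in ("ref", "alt", "max"):
            raise ValueError(f"unknown ab_mode {self.ab_mode!r}")


@dataclass
class SampleSummary:
    """Per-sample SNV counts over the capture targets."""

    sample_id: str
    n_snps: int = 0
    n_in_dbsnp: int = 0
    n_pass_filters: int = 0
    n_pass_and_dbsnp: int = 0
    n_pass_and_novel: int = 0
    n_indels: int = 0

    def validate(self) -> None:
        counts = (self.n_snps, self.n_in_dbsnp, self.n_pass_filters,
                  self.n_pass_and_dbsnp, self.n_pass_and_novel, self.n_indels)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.sample_id}: negative count")
        if self.n_pass_filters != self.n_pass_and_dbsnp + self.n_pass_and_novel:
            raise ValueError(f"{self.sample_id}: pass counts not additive")
        if self.n_pass_filters > self.n_snps:
            raise ValueError(f"{self.sample_id}: more passing than total SNVs")


def filter_qual(sites: Iterable[VariantSite], min_qual: float = 50.0,
                ) -> tuple[list[VariantSite], list[VariantSite]]:
    """Partition sites into (pass, fail) on QUAL > min_qual (strict)."""
    passed, failed = [], []
    for v in sites:
        (passed if v.qual > min_qual else failed).append(v)
    return passed, failed


def allele_balance(v: VariantSite, sample: str, mode: str = "ref") -> float | None:
    """Allele-balance fraction at a heterozygous call, else ``None``.

    Defined only for heterozygous calls with positive total depth; for
    homozygous calls, missing genotypes, missing depths, or zero depth the
    balance is undefined and the AB filter passes by convention.
    """
    if not v.is_het(sample):
        return None
    ad = v.allele_depths.get(sample)
    if ad is None:
        return None
    ref_reads, alt_reads = ad
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError(f"negative allele depth for {sample} at {v.chrom}:{v.pos}")
    total = ref_reads + alt_reads
    if total == 0:
        return None
    ref_frac = ref_reads / total
    if mode == "ref":
        return ref_frac
    if mode == "alt":
        return 1.0 - ref_frac
    return max(ref_frac, 1.0 - ref_frac)


def _passes_ab(v: VariantSite, sample: str, config: FilterConfig) -> bool:
    ab = allele_balance(v, sample, config.ab_mode)
    return ab is None or ab < config.max_allele_balance


def filter_window_density(sites: Sequence[VariantSite], window_bp: int = 10,
                          max_snps: int = 2,
                          ) -> tuple[list[VariantSite], list[VariantSite]]:
    """Partition one sample's sites on the local-clustering rule.

    A site fails iff it lies in ANY ``window_bp``-long window (windows start
    at every base) containing more than ``max_snps`` of the given sites.
    Equivalently: whenever ``max_snps + 1`` consecutive sites on a
    chromosome span at most ``window_bp - 1`` bases, all of them fail.
    Input need not be sorted.
    """
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    bad = [False] * len(sites)
    k = max_snps  # a run of k+1 sites inside one window is a violation
    for start in range(len(order)):
        i = order[start]
        end = start + k
        if end >= len(order):
            break
        j = order[end]
        if sites[i].chrom == sites[j].chrom and sites[j].pos - sites[i].pos <= window_bp - 1:
            for idx in order[start:end + 1]:
                bad[idx] = True
    passed = [v for v, b in zip(sites, bad) if not b]
    failed = [v for v, b in zip(sites, bad) if b]
    return passed, failed


def restrict_to_targets(sites: Iterable[VariantSite],
                        targets: Iterable[TargetRegion]) -> list[VariantSite]:
    """Keep sites whose 1-based position falls inside a capture target."""
    by_chrom: dict[str, list[TargetRegion]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    for ivs in by_chrom.values():
        ivs.sort()
    import bisect
    out = []
    for v in sites:
        ivs = by_chrom.get(v.chrom)
        if not ivs:
            continue
        p0 = v.pos - 1
        i = bisect.bisect_right(ivs, (v.chrom, p0, float("inf"))) - 1
        if i >= 0 and ivs[i].start <= p0 < ivs[i].end:
            out.append(v)
    return out


def sample_pass_sites(sites: Iterable[VariantSite], sample: str,
                      config: FilterConfig = FilterConfig(),
                      ) -> list[VariantSite]:
    """Run the quality -> allele-balance -> window chain for one sample.

    Operates on the sites at which *sample* carries an alternate allele;
    target restriction is assumed to have happened upstream.
    """
    carried = [v for v in sites if v.carries_alt(sample)]
    passed, _ = filter_qual(carried, config.min_qual)
    passed = [v for v in passed if _passes_ab(v, sample, config)]
    passed, _ = filter_window_density(passed, config.window_bp, config.max_snps_per_window)
    return passed


def summarize_sample(sites: Iterable[VariantSite], sample: str,
                     dbsnp: PopulationCatalog,
                     config: FilterConfig = FilterConfig(),
                     n_indels: int = 0) -> SampleSummary:
    """Count one sample's SNVs: totals, dbSNP membership, filter survivors.

    "Novel" means a pass-filter site whose (chrom, pos, alt) key is absent
    from the dbSNP stand-in.  *sites* must already be target-restricted.
    """
    carried = [v for v in sites if v.carries_alt(sample)]
    passed = sample_pass_sites(carried, sample, config)
    summary = SampleSummary(
        sample_id=sample,
        n_snps=len(carried),
        n_in_dbsnp=sum(1 for v in carried if v.key in dbsnp),
        n_pass_filters=len(passed),
        n_pass_and_dbsnp=sum(1 for v in passed if v.key in dbsnp),
        n_pass_and_novel=sum(1 for v in passed if v.key not in dbsnp),
        n_indels=n_indels,
    )
    summary.validate()
    return summary


def summarize_cohort(sites: Iterable[VariantSite], samples: Sequence[str],
                     dbsnp: PopulationCatalog,
                     config: FilterConfig = FilterConfig(),
                     indels_by_sample: Mapping[str, int] | None = None,
                     ) -> list[SampleSummary]:
    sites = list(sites)
    indels = indels_by_sample or {}
    return [summarize_sample(sites, s, dbsnp, config, indels.get(s, 0)) for s in samples]


_SUMMARY_FIELDS = ["n_snps", "n_in_dbsnp", "n_pass_filters",
                   "n_pass_and_dbsnp", "n_pass_and_novel", "n_indels"]


def cohort_group_means(summaries: Iterable[SampleSummary],
                       grouping: Mapping[str, str]) -> pd.DataFrame:
    """Arithmetic mean of each summary field per sample group.

    *grouping* maps sample_id -> group label; every summary must be
    assigned.  Full-precision means are returned (round only at report
    time).
    """
    rows = []
    for s in summaries:
        if s.sample_id not in grouping:
            raise KeyError(f"sample {s.sample_id} has no group assignment")
        rows.append({"group": grouping[s.sample_id],
                     **{f: getattr(s, f) for f in _SUMMARY_FIELDS}})
    df = pd.DataFrame(rows)
    return df.groupby("group")[_SUMMARY_FIELDS].mean()


def write_summary_table(path: str, summaries: Sequence[SampleSummary]) -> None:
    """Write the per-sample summary as a TSV with samples as columns."""
    df = pd.DataFrame(
        {s.sample_id: [getattr(s, f) for f in _SUMMARY_FIELDS] for s in summaries},
        index=["snps", "snps_in_dbsnp", "pass_q_filters",
               "pass_qf_and_in_dbsnp", "pass_qf_and_novel", "indels"],
    )
    df.to_csv(path, sep="\t", index_label="category")
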
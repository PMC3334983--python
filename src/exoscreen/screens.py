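"""Gene-level statistics and the rare-variant screens.

Three screens operate on QC-passed, annotated case variants:

* the **gene summary** — per-gene variant counts, sharing against each
  control catalog, and the non-common SNP density (variants per kb of
  exonic footprint after removing sites shared by cases and every control
  population simultaneously);
* the **burden screen** — transcript isoforms in which every case sample
  carries at least one rare (dbSNP-novel) variant;
* the **compound-heterozygote ("double-hit") screen** — isoforms in which
  every case carries at least two distinct novel variant sites (phase is
  not required; homozygous sites count once by default).

Burden/double-hit candidates are then probed for the genotype signatures
of a segmental-duplication artifact: a member site heterozygous in every
sample, nearby member sites with perfectly correlated genotype vectors,
and "novel" sites that re-match the dbSNP stand-in when the allele is
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import Annotation
from .formats import Isoform, PopulationCatalog, SiteKey, VariantSite, merge_intervals
from .overlap import non_common_set, venn_partition

__all__ = [
    "GeneSummary",
    "ScreenHit",
    "AssocRecord",
    "gene_exon_bases",
    "non_common_density",
    "round_density",
    "allele_count_pct",
    "gene_summary",
    "burden_screen",
    "compound_het_screen",
    "artifact_flags",
    "select_candidate_genes",
    "read_assoc_records",
    "write_gene_table",
    "write_screen_matrix",
]


@dataclass
class GeneSummary:
    """Per-gene case/control variant counts and the non-common density."""

    gene_symbol: str
    exon_bases: int
    n_total: int
    n_known: int
    n_novel: int
    pct_known: float
    catalog_counts: dict[str, int] = field(default_factory=dict)
    sharing: dict[str, int] = field(default_factory=dict)  # "cases&ASW" style keys
    n_shared_all: int = 0
    non_common_density: float | None = None

    def validate(self) -> None:
        if self.n_total != self.n_known + self.n_novel:
            raise ValueError(f"{self.gene_symbol}: known+novel != total")
        if self.non_common_density is not None and self.non_common_density < 0:
            raise ValueError(f"{self.gene_symbol}: negative density")


@dataclass
class ScreenHit:
    """One isoform passing a screen, with its per-sample novel-site counts."""

    isoform_id: str
    gene_symbol: str
    screen: str  # "burden" | "compound_het"
    counts: dict[str, int]  # sample -> distinct qualifying sites
    member_sites: set[SiteKey] = field(default_factory=set)
    artifact_flags: set[str] = field(default_factory=set)

    def validate(self) -> None:
        floor = 2 if self.screen == "compound_het" else 1
        if any(c < floor for c in self.counts.values()):
            raise ValueError(f"{self.isoform_id}: {self.screen} hit below count floor")


@dataclass(frozen=True)
class AssocRecord:
    """One association-scan result row used to seed candidate-gene selection."""

    snp_id: str
    gene_symbol: str
    p_value: float
    nonsynonymous: bool
    deleterious: bool | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.snp_id}: p-value out of (0, 1]")


def gene_exon_bases(isoforms: Iterable[Isoform]) -> int:
    """Exonic footprint of a gene: size of the union of all isoforms' exons."""
    isoforms = list(isoforms)
    if not isoforms:
        raise ValueError("at least one isoform required")
    merged = merge_intervals(iv for iso in isoforms for iv in iso.exons)
    return sum(e - s for s, e in merged)


def non_common_density(n_total: int, n_shared_all: int, exon_bases: int) -> float | None:
    """Non-common variants per kb: (total - shared_all) / (exon_bases/1000).

    Returns ``None`` (reported as missing) when the exonic footprint is
    empty.  Full precision is kept; round only in reports.
    """
    if not (0 <= n_shared_all <= n_total):
        raise ValueError("need 0 <= n_shared_all <= n_total")
    if exon_bases <= 0:
        return None
    return (n_total - n_shared_all) / (exon_bases / 1000.0)


def round_density(density: float | None, ndigits: int = 1) -> float | None:
    """Half-up decimal rounding for report columns (5.35 -> 5.4, not 5.3)."""
    if density is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(density)).quantize(q, rounding=ROUND_HALF_UP))


def allele_count_pct(n_alt_alleles: int, n_diploid_samples: int) -> float:
    """Alternate-allele count as a percent of 2N chromosomes."""
    if not (0 <= n_alt_alleles <= 2 * n_diploid_samples):
        raise ValueError("allele count outside [0, 2N]")
    return 100.0 * n_alt_alleles / (2 * n_diploid_samples)


def gene_summary(gene_symbol: str, isoforms: Sequence[Isoform],
                 case_sites_by_sample: Mapping[str, Iterable[VariantSite]],
                 dbsnp: PopulationCatalog,
                 catalogs: Sequence[PopulationCatalog],
                 non_common_mode: str = "shared_all") -> GeneSummary:
    """All per-gene count columns plus the non-common density.

    Case sites are restricted to the gene's exonic footprint; catalog sites
    likewise, so "ASW snps" counts that catalog's variants in this gene.
    Sharing counts cover every subset of {cases} ∪ catalogs.
    """
    gene_isos = [iso for iso in isoforms if iso.gene_symbol == gene_symbol]
    if not gene_isos:
        raise ValueError(f"no isoforms for gene {gene_symbol}")
    chrom = gene_isos[0].chrom
    footprint = merge_intervals(iv for iso in gene_isos for iv in iso.exons)

    def in_gene(key: SiteKey) -> bool:
        p0 = key.pos - 1
        return key.chrom == chrom and any(s <= p0 < e for s, e in footprint)

    pool: set[SiteKey] = set()
    for sites in case_sites_by_sample.values():
        for v in sites:
            k = v if isinstance(v, SiteKey) else v.key
            if in_gene(k):
                pool.add(k)
    known = {k for k in pool if k in dbsnp}
    cat_sets = {cat.name: {k for k in cat.sites if in_gene(k)} for cat in catalogs}
    sets = {"cases": pool, **cat_sets}
    partition = venn_partition(sets)

    def isect(group: tuple[str, ...]) -> int:
        req = set(group)
        return sum(n for cell, n in partition.items() if req <= cell)

    import itertools
    sharing = {}
    names = list(sets)
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            sharing["&".join(combo)] = isect(combo)
    shared_all = isect(tuple(names))
    exon_bases = gene_exon_bases(gene_isos)
    gene_cats = [PopulationCatalog(name=n, sites=s) for n, s in cat_sets.items()]
    n_non_common = len(non_common_set(pool, gene_cats, mode=non_common_mode))
    if non_common_mode == "shared_all":
        density = non_common_density(len(pool), shared_all, exon_bases)
    else:
        density = n_non_common / (exon_bases / 1000.0) if exon_bases else None
    gs = GeneSummary(
        gene_symbol=gene_symbol,
        exon_bases=exon_bases,
        n_total=len(pool),
        n_known=len(known),
        n_novel=len(pool) - len(known),
        pct_known=100.0 * len(known) / len(pool) if pool else 0.0,
        catalog_counts={n: len(s) for n, s in cat_sets.items()},
        sharing=sharing,
        n_shared_all=shared_all,
        non_common_density=density,
    )
    gs.validate()
    return gs


def _novel_site_counts(annotations: Sequence[Annotation],
                       sites_by_sample: Mapping[str, Iterable[VariantSite]],
                       dbsnp: PopulationCatalog,
                       extra_catalogs: Sequence[PopulationCatalog] = (),
                       count_hom_as_two: bool = False,
                       ) -> dict[str, dict]:
    """Per-isoform bookkeeping: which novel sites each sample carries.

    A site qualifies as rare when its key is absent from the dbSNP
    stand-in (and, if ``extra_catalogs`` are given, absent from those
    too).  Returns isoform_id -> {"gene": symbol, "counts": {sample: n},
    "sites": set of member keys}.
    """
    iso_sites: dict[str, set[SiteKey]] = {}
    iso_gene: dict[str, str] = {}
    for a in annotations:
        if a.isoform_id is None:
            continue
        iso_sites.setdefault(a.isoform_id, set()).add(a.site_key)
        iso_gene[a.isoform_id] = a.gene_symbol or a.isoform_id

    def is_rare(key: SiteKey) -> bool:
        if key in dbsnp:
            return False
        return all(key not in cat for cat in extra_catalogs)

    book: dict[str, dict] = {}
    for iso_id, keys in iso_sites.items():
        rare_keys = {k for k in keys if is_rare(k)}
        counts: dict[str, int] = {}
        carried: dict[str, set[SiteKey]] = {}
        for sample, sites in sites_by_sample.items():
            n = 0
            mem: set[SiteKey] = set()
            for v in sites:
                if v.key in rare_keys and v.carries_alt(sample):
                    mem.add(v.key)
                    n += 1 if (v.is_het(sample) or not count_hom_as_two) else 2
            counts[sample] = n if count_hom_as_two else len(mem)
            carried[sample] = mem
        book[iso_id] = {"gene": iso_gene[iso_id], "counts": counts,
                        "sites": set().union(*carried.values()) if carried else set()}
    return book


def burden_screen(annotations: Sequence[Annotation],
                  sites_by_sample: Mapping[str, Iterable[VariantSite]],
                  dbsnp: PopulationCatalog,
                  extra_catalogs: Sequence[PopulationCatalog] = (),
                  min_per_sample: int = 1,
                  count_hom_as_two: bool = False) -> list[ScreenHit]:
    """Isoforms in which EVERY case sample carries >= min_per_sample rare variants."""
    book = _novel_site_counts(annotations, sites_by_sample, dbsnp,
                              extra_catalogs, count_hom_as_two)
    hits = []
    screen = "burden" if min_per_sample < 2 else "compound_het"
    for iso_id in sorted(book):
        entry = book[iso_id]
        if entry["counts"] and all(c >= min_per_sample for c in entry["counts"].values()):
            hit = ScreenHit(isoform_id=iso_id, gene_symbol=entry["gene"],
                            screen=screen, counts=dict(entry["counts"]),
                            member_sites=set(entry["sites"]))
            hit.validate()
            hits.append(hit)
    return hits


def compound_het_screen(annotations: Sequence[Annotation],
                        sites_by_sample: Mapping[str, Iterable[VariantSite]],
                        dbsnp: PopulationCatalog,
                        extra_catalogs: Sequence[PopulationCatalog] = (),
                        count_hom_as_two: bool = False) -> list[ScreenHit]:
    """Double-hit screen: every case carries >= 2 distinct novel sites per isoform.

    Phase is not required.  By default a homozygous novel genotype counts
    as one site; set ``count_hom_as_two`` to count its two alleles.
    """
    return burden_screen(annotations, sites_by_sample, dbsnp, extra_catalogs,
                         min_per_sample=2, count_hom_as_two=count_hom_as_two)


def artifact_flags(hit: ScreenHit,
                   sites_by_sample: Mapping[str, Iterable[VariantSite]],
                   dbsnp: PopulationCatalog,
                   correlated_span_bp: int = 100) -> set[str]:
    """Duplication-artifact diagnostics for one screen hit.

    ``universal_heterozygosity``
        some member site is called heterozygous in every sample — the
        hallmark of reads from an unannotated paralog co-aligning;
    ``correlated_haplotype``
        two member sites within ``correlated_span_bp`` of each other have
        identical genotype vectors across all samples;
    ``catalog_recheck_hit``
        a "novel" member site matches the dbSNP stand-in when the alternate
        allele is ignored (position-only recheck).
    """
    samples = list(sites_by_sample)
    site_objs: dict[SiteKey, VariantSite] = {}
    for sites in sites_by_sample.values():
        for v in sites:
            if v.key in hit.member_sites:
                site_objs.setdefault(v.key, v)
    flags: set[str] = set()
    vectors: dict[SiteKey, tuple] = {}
    for key, v in site_objs.items():
        gts = tuple(tuple(sorted(v.genotypes.get(s) or (-1, -1))) for s in samples)
        vectors[key] = gts
        if samples and all(v.is_het(s) for s in samples):
            flags.add("universal_heterozygosity")
    keys = sorted(vectors)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1:]:
            if k1.chrom != k2.chrom or abs(k2.pos - k1.pos) > correlated_span_bp:
                continue
            if vectors[k1] == vectors[k2]:
                flags.add("correlated_haplotype")
    positions = dbsnp.positions()
    for key in hit.member_sites:
        if key not in dbsnp and (key.chrom, key.pos) in positions:
            flags.add("catalog_recheck_hit")
    return flags


def select_candidate_genes(records: Iterable[AssocRecord], k: int,
                           deleterious_only: bool = False) -> list[str]:
    """Genes carrying nonsynonymous SNPs among the k smallest p-values.

    Records are ordered by (p_value, snp_id) for determinism, the k
    best kept, nonsynonymous ones retained, and their distinct gene
    symbols returned in selection order.  ``deleterious_only`` further
    restricts to records flagged deleterious (requires the flag column).
    """
    ranked = sorted(records, key=lambda r: (r.p_value, r.snp_id))[:k]
    genes: list[str] = []
    for r in ranked:
        if not r.nonsynonymous:
            continue
        if deleterious_only and not r.deleterious:
            continue
        if r.gene_symbol not in genes:
            genes.append(r.gene_symbol)
    return genes


def read_assoc_records(path: str) -> list[AssocRecord]:
    """Read association results: snp_id, gene, p, nonsyn flag [, deleterious]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        vals = list(row)
        out.append(AssocRecord(
            snp_id=str(vals[0]), gene_symbol=str(vals[1]), p_value=float(vals[2]),
            nonsynonymous=bool(int(vals[3])),
            deleterious=bool(int(vals[4])) if len(vals) > 4 and pd.notna(vals[4]) else None,
        ))
    return out


def write_gene_table(path: str, summaries: Sequence[GeneSummary]) -> None:
    """Write per-gene summaries (counts + one-decimal density) as a TSV."""
    rows = []
    for g in summaries:
        rows.append({
            "gene": g.gene_symbol,
            "exon_bases": g.exon_bases,
            "case_snps": g.n_total,
            "case_known": g.n_known,
            "pct_known": round(g.pct_known, 1),
            "case_novel": g.n_novel,
            **{f"{name}_snps": n for name, n in g.catalog_counts.items()},
            "shared_all": g.n_shared_all,
            "non_common_density": round_density(g.non_common_density),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_screen_matrix(path: str, hits: Sequence[ScreenHit],
                        samples: Sequence[str]) -> None:
    """Write the isoform x sample matrix of qualifying-variant counts."""
    rows = []
    for h in hits:
        rows.append({"gene_isoform": f"{h.gene_symbol}/{h.isoform_id}",
                     **{s: h.counts.get(s, 0) for s in samples},
                     "flags": ",".join(sorted(h.artifact_flags)) or "."})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
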
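"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
VCF positions and all user-facing reports are 1-based; every internal
interval (exons, CDS bounds, capture targets) is 0-based half-open.
Conversion happens only here, at the I/O boundary.  Chromosome names are
normalised by stripping a leading ``chr`` so that ``chr10`` and ``10``
compare equal across files from different providers.

Variant identity
----------------
Population-level identity of a variant is its :class:`SiteKey` —
``(chrom, pos, alt)``.  Catalog membership (dbSNP novelty, control-
population sharing) is decided on SiteKeys, never on rsIDs, because the
control catalogs are consumed as plain site lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

BASES = frozenset("ACGT")

__all__ = [
    "VariantSite",
    "SiteKey",
    "Isoform",
    "TargetRegion",
    "PopulationCatalog",
    "VcfScan",
    "VcfParseError",
    "ConfigurationError",
    "GeneModelError",
    "BedFormatError",
    "read_vcf",
    "write_vcf",
    "read_targets",
    "write_targets",
    "merge_intervals",
    "read_gene_models",
    "write_gene_models",
    "read_catalog",
    "write_catalog",
    "site_key",
    "normalize_chrom",
]


class VcfParseError(ValueError):
    """A VCF record could not be parsed."""


class ConfigurationError(ValueError):
    """Requested samples do not match the VCF header."""


class GeneModelError(ValueError):
    """A transcript model violates its structural invariants."""


class BedFormatError(ValueError):
    """A BED interval is malformed (end <= start)."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix from a chromosome name."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class SiteKey(NamedTuple):
    """Canonical population-level variant identity: (chrom, 1-based pos, alt)."""

    chrom: str
    pos: int
    alt: str


@dataclass
class VariantSite:
    """One biallelic SNV site with per-sample genotypes and allelic depths.

    ``genotypes`` maps sample -> diploid allele pair over {0 (ref), 1 (alt)},
    or ``None`` when the genotype is missing.  ``allele_depths`` maps
    sample -> (ref_reads, alt_reads) or ``None`` when AD was absent.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    rsid: str | None = None
    genotypes: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    allele_depths: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(
                f"non-SNV alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.qual is not None and self.qual < 0:
            raise ValueError(f"negative QUAL at {self.chrom}:{self.pos}")

    @property
    def key(self) -> SiteKey:
        return SiteKey(self.chrom, self.pos, self.alt)

    def carries_alt(self, sample: str) -> bool:
        """True if *sample* has at least one alternate allele called."""
        gt = self.genotypes.get(sample)
        return gt is not None and any(a == 1 for a in gt)

    def is_het(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        return gt is not None and len(set(gt)) == 2

    def n_alt_alleles(self, sample: str) -> int:
        gt = self.genotypes.get(sample)
        return 0 if gt is None else sum(1 for a in gt if a == 1)


def site_key(v: VariantSite) -> SiteKey:
    """Canonical (chrom, pos, alt) identity of a variant site."""
    return v.key


class TargetRegion(NamedTuple):
    """A capture-target interval, 0-based half-open."""

    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Isoform:
    """A transcript model (refFlat/GenePred semantics, 0-based half-open).

    ``cds_start == cds_end`` marks a noncoding transcript.  Exons are kept
    sorted in genomic order regardless of strand; transcript orientation is
    applied when splicing the CDS.
    """

    isoform_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.isoform_id}: bad strand {self.strand!r}")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise GeneModelError(f"{self.isoform_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise GeneModelError(f"{self.isoform_id}: overlapping exons")
            prev_end = e
        if self.is_coding:
            if not (exons[0][0] <= self.cds_start < self.cds_end <= exons[-1][1]):
                raise GeneModelError(f"{self.isoform_id}: CDS outside transcript span")
            # CDS boundaries must land inside exons
            if not self._in_exon(self.cds_start) or not self._in_exon(self.cds_end - 1):
                raise GeneModelError(f"{self.isoform_id}: CDS bounds outside exon union")

    def _in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exon ∩ CDS pieces in genomic order (0-based half-open)."""
        out = []
        for s, e in self.exons:
            a, b = max(s, self.cds_start), min(e, self.cds_end)
            if a < b:
                out.append((a, b))
        return out

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())


@dataclass
class PopulationCatalog:
    """A named set of variant site keys (a dbSNP or control-population stand-in)."""

    name: str
    sites: set[SiteKey] = field(default_factory=set)
    frequencies: dict[SiteKey, float] = field(default_factory=dict)
    rsids: dict[SiteKey, str] = field(default_factory=dict)

    def __contains__(self, key: SiteKey) -> bool:
        return key in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> set[tuple[str, int]]:
        """Allele-agnostic (chrom, pos) index, for position-only rechecks."""
        return {(k.chrom, k.pos) for k in self.sites}

    def contains(self, key: SiteKey, match_on: str = "site") -> bool:
        """Membership under either matching convention.

        ``match_on="site"`` (default) requires position and alternate
        allele to agree; ``"position"`` ignores the allele.
        """
        if match_on == "site":
            return key in self.sites
        if match_on == "position":
            return (key.chrom, key.pos) in self.positions()
        raise ValueError(f"unknown match_on {match_on!r}")


class VcfScan(list):
    """The SNVs read from a VCF, plus counts of records skipped as non-SNV.

    Behaves as a plain list of :class:`VariantSite`.  ``indel_count`` counts
    skipped non-SNV records (indels and symbolic/multi-base alleles);
    ``indels_by_sample`` counts, per sample, skipped records in which that
    sample carries a non-reference allele.
    """

    def __init__(self, sites: Iterable[VariantSite] = (), samples: Sequence[str] = ()):
        super().__init__(sites)
        self.samples: list[str] = list(samples)
        self.indel_count: int = 0
        self.indels_by_sample: dict[str, int] = {s: 0 for s in samples}


def _decompose_gt(raw_gt, alt_index: int) -> tuple[int, int] | None:
    """Map a raw VCF genotype onto {0,1} for one decomposed alt allele.

    Alleles equal to the chosen alt become 1; the reference and any *other*
    alternate allele become 0 (the standard left-decomposition convention).
    """
    if raw_gt is None or any(a is None for a in raw_gt):
        return None
    mapped = tuple(1 if a == alt_index else 0 for a in raw_gt)
    if len(mapped) == 1:  # haploid call; represent as homozygous
        mapped = (mapped[0], mapped[0])
    return mapped  # type: ignore[return-value]


def read_vcf(path: str, sample_names: Sequence[str] | None = None) -> VcfScan:
    """Read a multi-sample VCF into :class:`VariantSite` records.

    Multi-allelic records are decomposed into one site per alternate allele.
    Non-SNV alleles (indels, symbolic alleles) are skipped and tallied on the
    returned :class:`VcfScan`.  Positions stay 1-based.

    Raises
    ------
    ConfigurationError
        if *sample_names* are not all present in the VCF header.
    VcfParseError
        if a record cannot be parsed.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: {exc}") from exc
    header_samples = list(vf.header.samples)
    if sample_names is None:
        samples = header_samples
    else:
        missing = [s for s in sample_names if s not in header_samples]
        if missing:
            raise ConfigurationError(
                f"{path}: samples {missing} not in VCF header {header_samples}"
            )
        samples = list(sample_names)

    scan = VcfScan(samples=samples)
    lineno = 0
    try:
        for rec in vf:
            lineno += 1
            chrom = normalize_chrom(rec.chrom)
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                is_snv = (
                    rec.ref is not None
                    and len(rec.ref) == 1
                    and rec.ref in BASES
                    and alt is not None
                    and len(alt) == 1
                    and alt in BASES
                )
                if not is_snv:
                    scan.indel_count += 1
                    for s in samples:
                        raw = rec.samples[s].get("GT")
                        if raw is not None and (ai + 1) in [a for a in raw if a is not None]:
                            scan.indels_by_sample[s] += 1
                    continue
                genotypes: dict[str, tuple[int, int] | None] = {}
                depths: dict[str, tuple[int, int] | None] = {}
                for s in samples:
                    fmt = rec.samples[s]
                    genotypes[s] = _decompose_gt(fmt.get("GT"), ai + 1)
                    ad = fmt.get("AD")
                    if ad is None or ad[0] is None:
                        depths[s] = None
                    else:
                        depths[s] = (int(ad[0]), int(ad[ai + 1]))
                scan.append(
                    VariantSite(
                        chrom=chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        rsid=rec.id,
                        genotypes=genotypes,
                        allele_depths=depths,
                    )
                )
    except VcfParseError:
        raise
    except Exception as exc:  # pysam raises assorted errors on malformed rows
        raise VcfParseError(f"{path}: malformed record near data line {lineno + 1}: {exc}") from exc
    return scan


def write_vcf(path: str, sites: Sequence[VariantSite], samples: Sequence[str],
              contig_lengths: dict[str, int] | None = None,
              indel_records: Sequence[tuple] | None = None) -> None:
    """Write biallelic SNV records as a VCF 4.2 file with GT and AD.

    ``indel_records`` optionally interleaves raw non-SNV records given as
    ``(chrom, pos, ref, alt, qual, genotypes)`` tuples (pos 1-based,
    genotypes a sample -> allele-pair dict), so simulated cohorts can carry
    indel calls through the same file.
    """
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for v in sites:
        contigs.setdefault(v.chrom, 0)
        contigs[v.chrom] = max(contigs[v.chrom], v.pos + 1)
    for rec in indel_records or ():
        contigs.setdefault(rec[0], 0)
        contigs[rec[0]] = max(contigs[rec[0]], rec[1] + len(rec[2]))
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in samples:
        header.add_sample(s)

    rows: list[tuple] = []
    for v in sites:
        rows.append((v.chrom, v.pos, v.alt, v.ref, float(v.qual), v.rsid,
                     v.genotypes, v.allele_depths))
    for chrom, pos, ref, alt, qual, genotypes in indel_records or ():
        rows.append((chrom, pos, alt, ref, float(qual), None, genotypes, {}))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos, alt, ref, qual, rsid, genotypes, depths in rows:
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt), qual=qual, id=rsid,
            )
            for s in samples:
                gt = genotypes.get(s)
                rec.samples[s]["GT"] = gt if gt is not None else (None, None)
                ad = depths.get(s)
                if ad is not None:
                    rec.samples[s]["AD"] = ad
            out.write(rec)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals, sorted and non-overlapping."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_targets(path: str) -> set[TargetRegion]:
    """Read a BED3+ file of capture targets; overlapping intervals are merged."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return set()
    out: set[TargetRegion] = set()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in df.itertuples(index=False):
        start, end = int(start), int(end)
        if end <= start:
            raise BedFormatError(f"{path}: interval end <= start ({chrom}:{start}-{end})")
        by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
    for chrom, ivs in by_chrom.items():
        for s, e in merge_intervals(ivs):
            out.add(TargetRegion(chrom, s, e))
    return out


def write_targets(path: str, targets: Iterable[TargetRegion]) -> None:
    with open(path, "w") as fh:
        for t in sorted(targets):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")


_REFFLAT_COLS = [
    "gene_symbol", "isoform_id", "chrom", "strand", "tx_start", "tx_end",
    "cds_start", "cds_end", "exon_count", "exon_starts", "exon_ends",
]


def read_gene_models(path: str) -> list[Isoform]:
    """Read a refFlat/GenePred-style tab-separated transcript table.

    Transcripts with ``cdsStart == cdsEnd`` are loaded as noncoding models.
    A CDS falling outside the exon union raises :class:`GeneModelError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=_REFFLAT_COLS, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    isoforms: list[Isoform] = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        if len(starts) != len(ends) or len(starts) != int(row.exon_count):
            raise GeneModelError(f"{row.isoform_id}: exon list length mismatch")
        isoforms.append(
            Isoform(
                isoform_id=str(row.isoform_id),
                gene_symbol=str(row.gene_symbol),
                chrom=normalize_chrom(str(row.chrom)),
                strand=str(row.strand),
                exons=tuple(zip(starts, ends)),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )
    return isoforms


def write_gene_models(path: str, isoforms: Iterable[Isoform]) -> None:
    with open(path, "w") as fh:
        for iso in isoforms:
            starts = ",".join(str(s) for s, _ in iso.exons) + ","
            ends = ",".join(str(e) for _, e in iso.exons) + ","
            fh.write(
                "\t".join([
                    iso.gene_symbol, iso.isoform_id, iso.chrom, iso.strand,
                    str(iso.tx_start), str(iso.tx_end),
                    str(iso.cds_start), str(iso.cds_end),
                    str(len(iso.exons)), starts, ends,
                ]) + "\n"
            )


def read_catalog(path: str, name: str) -> PopulationCatalog:
    """Read a catalog TSV (chrom, pos, alt [, rsid, af]) into a site-key set.

    Duplicate keys are deduplicated; rows that conflict on optional columns
    log a warning and keep the first occurrence.
    """
    cat = PopulationCatalog(name=name)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return cat
    for row in df.itertuples(index=False):
        vals = list(row)
        key = SiteKey(normalize_chrom(str(vals[0])), int(vals[1]), str(vals[2]))
        if key in cat.sites:
            log.warning("%s: duplicate catalog row for %s; keeping first", name, key)
            continue
        cat.sites.add(key)
        if len(vals) > 3 and isinstance(vals[3], str) and vals[3] not in (".", ""):
            cat.rsids[key] = vals[3]
        if len(vals) > 4 and vals[4] is not None and str(vals[4]) not in (".", "", "nan"):
            cat.frequencies[key] = float(vals[4])
    return cat


def write_catalog(path: str, catalog: PopulationCatalog) -> None:
    with open(path, "w") as fh:
        for key in sorted(catalog.sites):
            rsid = catalog.rsids.get(key, ".")
            af = f"{catalog.frequencies[key]:g}" if key in catalog.frequencies else "."
            fh.write(f"{key.chrom}\t{key.pos}\t{key.alt}\t{rsid}\t{af}\n")
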
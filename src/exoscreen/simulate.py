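"""Synthetic exome cohort generator with a ground-truth ledger.

Emulates the study conditions of a small case-only exome screen: a
two-ancestry cohort of diploid cases (8 + 2 by default), a contig of
multi-exon genes on both strands with valid coding sequences, a dbSNP
stand-in plus three control-population site catalogs (ASW/YRI/CEU-like)
with configurable sharing structure, and per-sample SNV calls whose
known/novel split matches each group's target fraction (~88.5 % / ~95 %
known).  Four signals are planted with exact bookkeeping:

* a *density-enriched* gene: a fixed set of case sites of which only a
  known subset is shared by all four populations, giving a predictable
  non-common SNP density;
* a *universal-burden* gene: every case carries at least one novel site;
* a *compound-heterozygote* gene: every case carries at least two
  distinct novel sites;
* a *duplication-artifact* locus on a minus-strand gene: a genomic T→A
  call creating a Lys→stop codon, heterozygous in every sample, with a
  perfectly correlated flanking variant three bases away, and dbSNP
  entries at both positions under a different alternate allele (so an
  allele-agnostic recheck re-identifies the "novel" calls).

Everything is drawn from one seeded NumPy generator; the same seed yields
byte-identical output files.  The ledger (:class:`GroundTruthLedger`)
records exactly what was planted and drawn, so end-to-end tests can
demand zero false negatives.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .formats import (
    Isoform,
    PopulationCatalog,
    SiteKey,
    TargetRegion,
    VariantSite,
    merge_intervals,
    write_catalog,
    write_gene_models,
    write_targets,
    write_vcf,
)

__all__ = ["CohortConfig", "GroundTruthLedger", "SimulatedCohort",
           "CohortSimulator", "simulate_cohort", "genomic_position_of_cds_index"]

STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in STOP_CODONS]
_BASES = np.array(list("ACGT"))


@dataclass
class CohortConfig:
    """Study-condition knobs of the simulated cohort (all seeded)."""

    seed: int = 0
    # cohort design: two ancestry groups, as in the pilot (8 + 2 males)
    n_cases_group_a: int = 8
    n_cases_group_b: int = 2
    group_a_label: str = "African-American"
    group_b_label: str = "Caucasian"
    # gene / contig geometry
    chrom: str = "1"
    n_genes: int = 60
    codons_min: int = 200
    codons_max: int = 500
    utr_len: int = 30
    exons_min: int = 2
    exons_max: int = 4
    intron_min: int = 60
    intron_max: int = 200
    intergenic_gap: int = 300
    target_pad: int = 20
    # per-sample call scale and known/novel split
    sites_per_sample: int = 2000
    known_fraction_a: float = 0.885
    known_fraction_b: float = 0.95
    # catalog pools and sharing structure
    known_pool_size: int = 4000
    novel_pool_size: int = 1500
    control_only_pool_size: int = 2000
    p_control_known: float = 0.7      # P(control catalog holds a dbSNP case site)
    p_control_novel: float = 0.05     # P(control catalog holds a non-dbSNP case site)
    p_control_only: float = 0.7       # membership prob for control-only sites
    p_dbsnp_control_only: float = 0.9
    recheck_decoy_rate: float = 0.02  # dbSNP entry at a novel site's position, other allele
    # call quality
    qual_fail_rate: float = 0.05
    ab_fail_rate: float = 0.03
    het_fraction: float = 0.8
    depth_mean: int = 40
    # off-target / indel noise
    offtarget_per_sample: int = 30
    indels_per_sample: int = 20
    indel_pool_size: int = 400
    # planted signals
    plant_signals: bool = True
    density_total: int = 10
    density_shared_all: int = 3
    density_novel: int = 3
    planted_positions_per_gene: int = 24

    def __post_init__(self) -> None:
        probs = (self.p_control_known, self.p_control_novel, self.p_control_only,
                 self.p_dbsnp_control_only, self.recheck_decoy_rate,
                 self.qual_fail_rate, self.ab_fail_rate, self.het_fraction,
                 self.known_fraction_a, self.known_fraction_b)
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_cases_group_a + self.n_cases_group_b < 1:
            raise ValueError("cohort must have at least one sample")
        if self.plant_signals and self.n_genes < 5:
            raise ValueError("planted signals need at least 5 genes")
        if not (0 <= self.density_shared_all <= self.density_total):
            raise ValueError("density_shared_all must be within density_total")

    @property
    def samples(self) -> list[str]:
        return ([f"M{i:03d}" for i in range(1, self.n_cases_group_a + 1)]
                + [f"SW{i:03d}" for i in range(1, self.n_cases_group_b + 1)])

    @property
    def groups(self) -> dict[str, str]:
        return {s: (self.group_a_label if s.startswith("M") else self.group_b_label)
                for s in self.samples}


@dataclass
class GroundTruthLedger:
    """Exactly what the generator planted and drew, for verification."""

    samples: list[str]
    groups: dict[str, str]
    per_sample: dict[str, dict]         # drawn counts: target SNVs, known, novel, off-target, indels
    planted: dict                       # planted gene symbols, isoforms, sites, counts
    pools: dict                         # realized pool/catalog sizes

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class SimulatedCohort:
    """In-memory bundle of everything one simulation produced."""

    config: CohortConfig
    reference: dict[str, str]
    isoforms: list[Isoform]
    targets: set[TargetRegion]
    catalogs: dict[str, PopulationCatalog]
    sites: list[VariantSite]
    indel_records: list[tuple]
    ledger: GroundTruthLedger
    paths: dict[str, str] = field(default_factory=dict)


def genomic_position_of_cds_index(iso: Isoform, cds_idx: int) -> int:
    """0-based genomic position of the spliced-CDS base *cds_idx* (transcript 5'->3')."""
    if not (0 <= cds_idx < iso.cds_len):
        raise IndexError(f"CDS index {cds_idx} outside [0, {iso.cds_len})")
    if iso.strand == "-":
        cds_idx = iso.cds_len - 1 - cds_idx
    for s, e in iso.cds_intervals():
        if cds_idx < e - s:
            return s + cds_idx
        cds_idx -= e - s
    raise AssertionError("unreachable")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class CohortSimulator:
    """Stateful generator: reference -> catalogs -> cohort, one RNG stream."""

    def __init__(self, config: CohortConfig | None = None):
        self.config = config or CohortConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self._planted: dict = {}
        self._pools: dict = {}

    # ------------------------------------------------------------------ genes

    def _make_gene(self, symbol: str, isoform_ids: list[str], strand: str,
                   force_codons: dict[int, str] | None = None,
                   ) -> tuple[str, list[Isoform]]:
        """One gene region in local (region-relative) coordinates."""
        cfg, rng = self.config, self.rng
        n_codons = int(rng.integers(cfg.codons_min, cfg.codons_max + 1))
        body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons)]
        cds = "ATG" + "".join(body) + STOP_CODONS[int(rng.integers(0, 3))]
        for ci, codon in (force_codons or {}).items():
            cds = cds[:ci * 3] + codon + cds[ci * 3 + 3:]
        tx = _random_seq(rng, cfg.utr_len) + cds + _random_seq(rng, cfg.utr_len)

        n_ex = int(rng.integers(cfg.exons_min, cfg.exons_max + 1))
        lo, hi = cfg.utr_len + 30, len(tx) - 20
        grid = np.arange(lo, hi, 25)
        n_cuts = min(n_ex - 1, len(grid))
        cuts = sorted(int(c) for c in rng.choice(grid, size=n_cuts, replace=False))
        bounds = [0] + cuts + [len(tx)]
        exon_lens = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        introns = [int(x) for x in
                   rng.integers(cfg.intron_min, cfg.intron_max + 1, len(exon_lens) - 1)]

        # sense-region sequence and exon intervals
        pieces, exons_sense, cursor, t = [], [], 0, 0
        for i, elen in enumerate(exon_lens):
            pieces.append(tx[t:t + elen])
            exons_sense.append((cursor, cursor + elen))
            cursor += elen
            t += elen
            if i < len(introns):
                pieces.append(_random_seq(rng, introns[i]))
                cursor += introns[i]
        region = "".join(pieces)

        def sense_coord(tx_idx: int) -> int:
            off = tx_idx
            for (s, e) in exons_sense:
                if off < e - s:
                    return s + off
                off -= e - s
            raise IndexError(tx_idx)

        cds_s = sense_coord(cfg.utr_len)
        cds_e = sense_coord(cfg.utr_len + len(cds) - 1) + 1
        exons = exons_sense
        if strand == "-":
            L = len(region)
            region = str(Seq(region).reverse_complement())
            exons = sorted((L - e, L - s) for s, e in exons_sense)
            cds_s, cds_e = L - cds_e, L - cds_s
        isoforms = [
            Isoform(isoform_id=iid, gene_symbol=symbol, chrom=cfg.chrom,
                    strand=strand, exons=tuple(exons), cds_start=cds_s, cds_end=cds_e)
            for iid in isoform_ids
        ]
        return region, isoforms

    def generate_reference(self) -> tuple[dict[str, str], list[Isoform], set[TargetRegion]]:
        """Random contig with n_genes valid multi-exon genes on both strands."""
        cfg, rng = self.config, self.rng
        pieces: list[str] = []
        isoforms: list[Isoform] = []
        offset = 0
        artifact_force = {6: "AAA", 7: "AAA"}  # protein positions 7 and 8 = Lys
        for idx in range(cfg.n_genes):
            symbol = f"GENE{idx:03d}"
            n_iso = 2 if (cfg.plant_signals and idx in (0, 3)) else (
                2 if rng.random() < 0.2 else 1)
            ids = [f"NM_{100000 + idx * 10 + j:06d}" for j in range(n_iso)]
            if cfg.plant_signals and idx == 0:
                strand, force = "-", artifact_force
            else:
                strand, force = ("+" if rng.random() < 0.5 else "-"), None
            gap = _random_seq(rng, cfg.intergenic_gap)
            pieces.append(gap)
            offset += len(gap)
            region, gene_isos = self._make_gene(symbol, ids, strand, force)
            for iso in gene_isos:
                isoforms.append(Isoform(
                    isoform_id=iso.isoform_id, gene_symbol=iso.gene_symbol,
                    chrom=iso.chrom, strand=iso.strand,
                    exons=tuple((s + offset, e + offset) for s, e in iso.exons),
                    cds_start=iso.cds_start + offset, cds_end=iso.cds_end + offset))
            pieces.append(region)
            offset += len(region)
        pieces.append(_random_seq(rng, cfg.intergenic_gap))
        reference = {cfg.chrom: "".join(pieces)}
        if cfg.plant_signals:
            self._planted["gene_symbols"] = {
                "artifact": "GENE000", "density": "GENE001",
                "burden": "GENE002", "compound_het": "GENE003"}
        exon_ivs = [(max(0, s - cfg.target_pad), e + cfg.target_pad)
                    for iso in isoforms for s, e in iso.exons]
        targets = {TargetRegion(cfg.chrom, s, e) for s, e in merge_intervals(exon_ivs)}
        for iso in isoforms:
            if iso.cds_len % 3 != 0:
                raise AssertionError(f"generated invalid CDS for {iso.isoform_id}")
        return reference, isoforms, targets

    # --------------------------------------------------------------- catalogs

    def _spaced_cds_positions(self, iso: Isoform, n: int, used: set[int],
                              min_gap: int = 15) -> list[int]:
        """n 0-based CDS positions with pairwise (and vs. *used*) gap >= min_gap."""
        rng = self.rng
        candidates = [p for s, e in iso.cds_intervals() for p in range(s + 3, e - 3)]
        rng.shuffle(candidates)
        chosen: list[int] = []
        for p in candidates:
            if all(abs(p - q) >= min_gap for q in chosen) and \
                    all(abs(p - q) >= min_gap for q in used):
                chosen.append(p)
                if len(chosen) == n:
                    return sorted(chosen)
        raise ValueError(f"cannot place {n} spaced positions in {iso.isoform_id}")

    def _alt_for(self, ref: str, exclude: str | None = None) -> str:
        options = [b for b in "ACGT" if b != ref and b != exclude]
        return options[int(self.rng.integers(0, len(options)))]

    def generate_catalogs(self, reference: dict[str, str], isoforms: list[Isoform],
                          ) -> dict[str, PopulationCatalog]:
        """dbSNP stand-in + ASW/YRI/CEU site catalogs with the configured sharing."""
        cfg, rng = self.config, self.rng
        contig = reference[cfg.chrom]
        planted_genes = set(self._planted.get("gene_symbols", {}).values())
        background = [iso for iso in isoforms if iso.gene_symbol not in planted_genes]
        exonic = sorted({p for iso in background for s, e in iso.exons
                         for p in range(s, e)})
        n_needed = cfg.known_pool_size + cfg.novel_pool_size + cfg.control_only_pool_size
        if len(exonic) < n_needed:
            raise ValueError(
                f"exonic space ({len(exonic)} bp) too small for the configured "
                f"catalog pools ({n_needed} sites); add genes or shrink pools")
        chosen = rng.choice(np.array(exonic), size=n_needed, replace=False)
        chosen = [int(p) for p in chosen]
        known_pos = chosen[:cfg.known_pool_size]
        novel_pos = chosen[cfg.known_pool_size:cfg.known_pool_size + cfg.novel_pool_size]
        ctl_pos = chosen[cfg.known_pool_size + cfg.novel_pool_size:]

        def key_at(p0: int, exclude: str | None = None) -> SiteKey:
            return SiteKey(cfg.chrom, p0 + 1, self._alt_for(contig[p0], exclude))

        dbsnp = PopulationCatalog("DBSNP")
        controls = {name: PopulationCatalog(name) for name in ("ASW", "YRI", "CEU")}
        rs = 1000

        known_keys = []
        for p0 in known_pos:
            k = key_at(p0)
            known_keys.append(k)
            dbsnp.sites.add(k)
            dbsnp.rsids[k] = f"rs{rs}"
            rs += 1
            for cat in controls.values():
                if rng.random() < cfg.p_control_known:
                    cat.sites.add(k)
        novel_keys = []
        for p0 in novel_pos:
            k = key_at(p0)
            novel_keys.append(k)
            for cat in controls.values():
                if rng.random() < cfg.p_control_novel:
                    cat.sites.add(k)
            if rng.random() < cfg.recheck_decoy_rate:
                decoy = SiteKey(k.chrom, k.pos, self._alt_for(contig[p0], exclude=k.alt))
                dbsnp.sites.add(decoy)
                dbsnp.rsids[decoy] = f"rs{rs}"
                rs += 1
        for p0 in ctl_pos:
            k = key_at(p0)
            member = False
            for cat in controls.values():
                if rng.random() < cfg.p_control_only:
                    cat.sites.add(k)
                    member = True
            if member and rng.random() < cfg.p_dbsnp_control_only:
                dbsnp.sites.add(k)
                dbsnp.rsids[k] = f"rs{rs}"
                rs += 1

        self._pools = {"known": known_keys, "novel": novel_keys,
                       "ref_of": {k: contig[k.pos - 1] for k in known_keys + novel_keys}}

        if cfg.plant_signals:
            self._plan_signals(reference, isoforms, dbsnp, controls)
        self._pools["catalog_sizes"] = {"DBSNP": len(dbsnp),
                                        **{n: len(c) for n, c in controls.items()}}
        return {"DBSNP": dbsnp, **controls}

    def _plan_signals(self, reference, isoforms, dbsnp, controls) -> None:
        """Choose planted site positions and seed the catalogs accordingly."""
        cfg, rng = self.config, self.rng
        contig = reference[cfg.chrom]
        by_gene: dict[str, list[Isoform]] = {}
        for iso in isoforms:
            by_gene.setdefault(iso.gene_symbol, []).append(iso)
        syms = self._planted["gene_symbols"]

        # density gene: fixed case sites with a known shared-all subset
        iso = by_gene[syms["density"]][0]
        pos = self._spaced_cds_positions(iso, cfg.density_total, used=set())
        density_keys = [SiteKey(cfg.chrom, p + 1, self._alt_for(contig[p])) for p in pos]
        n_sh, n_nv = cfg.density_shared_all, cfg.density_novel
        for k in density_keys[:n_sh]:                 # shared by all four populations
            dbsnp.sites.add(k)
            for cat in controls.values():
                cat.sites.add(k)
        for k in density_keys[n_sh:cfg.density_total - n_nv]:   # dbSNP-known, case-only
            dbsnp.sites.add(k)
        self._planted["density_sites"] = density_keys

        # burden / compound-het genes: pools of novel positions
        for name in ("burden", "compound_het"):
            iso = by_gene[syms[name]][0]
            pos = self._spaced_cds_positions(iso, cfg.planted_positions_per_gene, used=set())
            self._planted[f"{name}_sites"] = [
                SiteKey(cfg.chrom, p + 1, self._alt_for(contig[p])) for p in pos]

        # artifact locus: codon-7 flank + codon-8 pseudo-nonsense, minus strand
        iso = by_gene[syms["artifact"]][0]
        flank_p0 = genomic_position_of_cds_index(iso, 18)   # codon 7, first base
        stop_p0 = genomic_position_of_cds_index(iso, 21)    # codon 8, first base
        # transcript codons are AAA; on the minus strand the genomic bases are T
        assert contig[flank_p0] == "T" and contig[stop_p0] == "T"
        flank = SiteKey(cfg.chrom, flank_p0 + 1, "G")   # tx A->C: missense Lys7Gln
        stopk = SiteKey(cfg.chrom, stop_p0 + 1, "A")    # tx A->T: AAA->TAA, Lys8Ter
        for k in (flank, stopk):                        # position-only dbSNP decoys
            decoy = SiteKey(k.chrom, k.pos, self._alt_for(contig[k.pos - 1], exclude=k.alt))
            dbsnp.sites.add(decoy)
        self._planted["artifact_sites"] = [flank, stopk]
        self._planted["artifact_isoforms"] = [i.isoform_id for i in by_gene[syms["artifact"]]]
        self._planted["compound_isoforms"] = [i.isoform_id
                                              for i in by_gene[syms["compound_het"]]]
        self._planted["burden_isoforms"] = [i.isoform_id for i in by_gene[syms["burden"]]]

    # ----------------------------------------------------------------- cohort

    def _draw_call(self, planted: bool = False) -> tuple[tuple[int, int], tuple[int, int]]:
        """One genotype + allelic-depth draw for a carrier."""
        cfg, rng = self.config, self.rng
        total = max(4, int(rng.poisson(cfg.depth_mean)))
        if not planted and rng.random() >= cfg.het_fraction:
            return (1, 1), (0, total)
        if planted:
            alt = total // 2
        elif rng.random() < cfg.ab_fail_rate:
            ref_frac = rng.uniform(0.78, 0.92)      # ref-heavy: fails AB < 0.75
            alt = total - int(round(total * ref_frac))
        else:
            alt = int(rng.binomial(total, 0.5))
            floor = total // 4 + 1                   # keep ref fraction < 0.75
            alt = min(max(alt, floor), total - 1)
        return (0, 1), (total - alt, alt)

    def generate_cohort(self, reference: dict[str, str], isoforms: list[Isoform],
                        catalogs: dict[str, PopulationCatalog],
                        targets: set[TargetRegion],
                        ) -> tuple[list[VariantSite], list[tuple], GroundTruthLedger]:
        """Draw per-sample calls, inject planted signals, emit merged records."""
        cfg, rng = self.config, self.rng
        contig = reference[cfg.chrom]
        samples = cfg.samples
        known = self._pools["known"]
        novel = self._pools["novel"]
        ref_of = dict(self._pools["ref_of"])

        records: dict[SiteKey, dict] = {}

        def record(key: SiteKey, ref: str, planted: bool = False) -> dict:
            if key not in records:
                if planted:
                    qual = float(rng.uniform(600, 2500))
                elif rng.random() < cfg.qual_fail_rate:
                    qual = float(rng.uniform(5, 50))
                else:
                    qual = float(rng.uniform(60, 2500))
                records[key] = {"ref": ref, "qual": qual, "gt": {}, "ad": {}}
            return records[key]

        def carry(key: SiteKey, ref: str, sample: str, planted: bool = False) -> None:
            rec = record(key, ref, planted)
            gt, ad = self._draw_call(planted)
            rec["gt"][sample] = gt
            rec["ad"][sample] = ad

        per_sample: dict[str, dict] = {}
        group_frac = {cfg.group_a_label: cfg.known_fraction_a,
                      cfg.group_b_label: cfg.known_fraction_b}

        # intergenic space for off-target SNVs and indels
        tgt = merge_intervals((t.start, t.end) for t in targets)
        free: list[int] = []
        cursor = 0
        for s, e in tgt:
            free.extend(range(cursor + 5, max(cursor + 5, s - 5)))
            cursor = e
        free.extend(range(cursor + 5, len(contig) - 5))
        free_arr = np.array(free)
        indel_pool_pos = [int(p) for p in
                          rng.choice(free_arr, size=cfg.indel_pool_size, replace=False)]
        indel_pool = [(p, contig[p:p + 2], contig[p]) for p in indel_pool_pos
                      if set(contig[p:p + 2]) <= set("ACGT")]

        indel_recs: dict[int, dict] = {}
        for sample in samples:
            frac = group_frac[cfg.groups[sample]]
            n_target = int(rng.poisson(cfg.sites_per_sample))
            n_known = int(rng.binomial(n_target, frac))
            n_novel = n_target - n_known
            for idx in rng.choice(len(known), size=min(n_known, len(known)), replace=False):
                k = known[int(idx)]
                carry(k, ref_of[k], sample)
            for idx in rng.choice(len(novel), size=min(n_novel, len(novel)), replace=False):
                k = novel[int(idx)]
                carry(k, ref_of[k], sample)
            n_off = int(rng.poisson(cfg.offtarget_per_sample))
            for p0 in rng.choice(free_arr, size=n_off, replace=False):
                p0 = int(p0)
                k = SiteKey(cfg.chrom, p0 + 1, self._alt_for(contig[p0]))
                carry(k, contig[p0], sample)
            n_ind = int(rng.poisson(cfg.indels_per_sample))
            for idx in rng.choice(len(indel_pool), size=min(n_ind, len(indel_pool)),
                                  replace=False):
                p0, iref, ialt = indel_pool[int(idx)]
                rec = indel_recs.setdefault(
                    p0, {"ref": iref, "alt": ialt, "qual": float(rng.uniform(60, 2500)),
                         "gt": {}})
                rec["gt"][sample] = (0, 1)
            per_sample[sample] = {
                "group": cfg.groups[sample], "n_target_snvs": min(n_target,
                    min(n_known, len(known)) + min(n_novel, len(novel))),
                "n_known_drawn": min(n_known, len(known)),
                "n_novel_drawn": min(n_novel, len(novel)),
                "n_offtarget": n_off, "n_indels": n_ind,
            }

        planted_counts: dict[str, dict[str, int]] = {}
        if cfg.plant_signals:
            dens = self._planted["density_sites"]
            for i, k in enumerate(dens):           # each density site in 1-2 samples
                n_car = 1 + int(rng.random() < 0.4)
                for si in rng.choice(len(samples), size=n_car, replace=False):
                    carry(k, contig[k.pos - 1], samples[int(si)], planted=True)
            for name, floor in (("burden", 1), ("compound_het", 2)):
                pool = self._planted[f"{name}_sites"]
                counts = {}
                for sample in samples:
                    n = floor + int(rng.poisson(0.5))
                    picks = rng.choice(len(pool), size=n, replace=False)
                    for idx in picks:
                        k = pool[int(idx)]
                        carry(k, contig[k.pos - 1], sample, planted=True)
                    counts[sample] = n
                planted_counts[name] = counts
            for k in self._planted["artifact_sites"]:   # het in every sample
                rec = record(k, contig[k.pos - 1], planted=True)
                depth = max(4, int(rng.poisson(cfg.depth_mean)))
                for sample in samples:
                    rec["gt"][sample] = (0, 1)
                    rec["ad"][sample] = (depth - depth // 2, depth // 2)

        sites: list[VariantSite] = []
        for key in sorted(records):
            rec = records[key]
            genotypes, depths = {}, {}
            for sample in samples:
                if sample in rec["gt"]:
                    genotypes[sample] = rec["gt"][sample]
                    depths[sample] = rec["ad"][sample]
                else:
                    genotypes[sample] = (0, 0)
                    depths[sample] = (int(max(4, rng.poisson(cfg.depth_mean))), 0)
            sites.append(VariantSite(chrom=key.chrom, pos=key.pos, ref=rec["ref"],
                                     alt=key.alt, qual=round(rec["qual"], 2),
                                     genotypes=genotypes, allele_depths=depths))
        indel_records = []
        for p0 in sorted(indel_recs):
            rec = indel_recs[p0]
            gts = {s: rec["gt"].get(s, (0, 0)) for s in samples}
            indel_records.append((cfg.chrom, p0 + 1, rec["ref"], rec["alt"],
                                  round(rec["qual"], 2), gts))

        dens_total = cfg.density_total if cfg.plant_signals else 0
        planted = {}
        if cfg.plant_signals:
            planted = {
                "gene_symbols": self._planted["gene_symbols"],
                "burden_isoforms": self._planted["burden_isoforms"],
                "compound_isoforms": self._planted["compound_isoforms"],
                "artifact_isoforms": self._planted["artifact_isoforms"],
                "burden_counts": planted_counts.get("burden", {}),
                "compound_het_counts": planted_counts.get("compound_het", {}),
                "artifact_sites": [f"{k.chrom}:{k.pos}:{k.alt}"
                                   for k in self._planted["artifact_sites"]],
                "density": {"n_total": dens_total,
                            "n_shared_all": cfg.density_shared_all,
                            "n_novel": cfg.density_novel},
            }
        ledger = GroundTruthLedger(
            samples=samples, groups=cfg.groups, per_sample=per_sample,
            planted=planted, pools=dict(self._pools.get("catalog_sizes", {})))
        return sites, indel_records, ledger

    # -------------------------------------------------------------- top level

    def run(self, out_dir: str | None = None) -> SimulatedCohort:
        reference, isoforms, targets = self.generate_reference()
        catalogs = self.generate_catalogs(reference, isoforms)
        sites, indels, ledger = self.generate_cohort(reference, isoforms,
                                                     catalogs, targets)
        cohort = SimulatedCohort(config=self.config, reference=reference,
                                 isoforms=isoforms, targets=targets,
                                 catalogs=catalogs, sites=sites,
                                 indel_records=indels, ledger=ledger)
        if out_dir is not None:
            cohort.paths = _write_cohort(cohort, out_dir)
        return cohort


def _write_fasta(path: str, reference: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_cohort(cohort: SimulatedCohort, out_dir: str) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    cfg = cohort.config
    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "models": os.path.join(out_dir, "models.refflat"),
        "targets": os.path.join(out_dir, "targets.bed"),
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "ledger": os.path.join(out_dir, "ledger.json"),
        "config": os.path.join(out_dir, "config.json"),
    }
    _write_fasta(paths["reference"], cohort.reference)
    write_gene_models(paths["models"], cohort.isoforms)
    write_targets(paths["targets"], cohort.targets)
    for name, cat in cohort.catalogs.items():
        p = os.path.join(out_dir, f"catalog_{name.lower()}.tsv")
        write_catalog(p, cat)
        paths[f"catalog_{name}"] = p
    contig_lengths = {c: len(s) for c, s in cohort.reference.items()}
    write_vcf(paths["vcf"], cohort.sites, cfg.samples,
              contig_lengths=contig_lengths, indel_records=cohort.indel_records)
    cohort.ledger.to_json(paths["ledger"])
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, sort_keys=True)
    return paths


def simulate_cohort(config: CohortConfig | None = None,
                    out_dir: str | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort (reference, models, catalogs, VCF, ledger)."""
    return CohortSimulator(config).run(out_dir)
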
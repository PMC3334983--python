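import random

import pytest

from exoscreen.annotate import Annotation
from exoscreen.datasets import load_gene_counts
from exoscreen.formats import Isoform, PopulationCatalog, SiteKey, VariantSite
from exoscreen.screens import (
    AssocRecord,
    allele_count_pct,
    artifact_flags,
    burden_screen,
    compound_het_screen,
    gene_exon_bases,
    gene_summary,
    non_common_density,
    round_density,
    select_candidate_genes,
)
from oracles import per_base_membership


def iso(iid="NM_1", gene="G1", exons=((0, 1000),), cds=(10, 970), strand="+"):
    return Isoform(iid, gene, "1", strand, exons, cds[0], cds[1])


def site(pos, samples_gt, alt="T", qual=500.0):
    gts = {}
    ads = {}
    for s, gt in samples_gt.items():
        gts[s] = gt
        ads[s] = (10, 10) if gt != (0, 0) else (20, 0)
    return VariantSite(chrom="1", pos=pos, ref="A", alt=alt, qual=qual,
                       genotypes=gts, allele_depths=ads)


def ann_for(v, isoform):
    return Annotation(site_key=v.key, isoform_id=isoform.isoform_id,
                      gene_symbol=isoform.gene_symbol, effect_class="missense")


class TestExonBases:
    def test_single_exon_footprint(self):
        assert gene_exon_bases([iso(exons=((100, 1412),), cds=(150, 1400))]) == 1312

    def test_identical_isoforms_union_idempotent(self):
        a = iso("NM_1")
        b = iso("NM_2")
        assert gene_exon_bases([a, b]) == gene_exon_bases([a])

    def test_overlapping_exon_sets_match_per_base_oracle(self):
        rng = random.Random(4)
        isoforms = []
        all_ivs = []
        for i in range(3):
            ivs = sorted((s, s + rng.randrange(30, 90))
                         for s in rng.sample(range(0, 2000, 100), 4))
            merged = []
            for s, e in ivs:  # make each isoform's exons valid (non-overlapping)
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            isoforms.append(iso(f"NM_{i}", exons=tuple(merged),
                                cds=(merged[0][0], merged[0][0])))
            all_ivs.extend(merged)
        expected = sum(1 for p in range(2200) if per_base_membership(p, all_ivs))
        assert gene_exon_bases(isoforms) == expected


class TestDensity:
    def test_worked_example(self):
        # 10 case variants, 3 shared across all four populations, 1312 bp
        d = non_common_density(10, 3, 1312)
        assert round(d, 2) == 5.34
        assert round_density(d) == 5.3

    def test_all_shared_gives_zero(self):
        assert non_common_density(2, 2, 1277) == 0.0

    def test_empty_gene_zero(self):
        assert non_common_density(0, 0, 500) == 0.0

    def test_zero_footprint_undefined(self):
        assert non_common_density(5, 1, 0) is None
        assert round_density(None) is None

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            non_common_density(3, 5, 100)

    def test_rounding_is_half_up(self):
        assert round_density(2.25) == 2.3
        assert round_density(2.2499) == 2.2
        assert round_density(5.335365853658536) == 5.3

    def test_published_gene_rows_reproduce(self):
        """Every self-consistent published gene row's one-decimal density
        comes back from its own (exon bases, total, shared-all) inputs."""
        df = load_gene_counts(consistent_only=True)
        assert len(df) == 17
        for gene, row in df.iterrows():
            d = non_common_density(int(row.case_snps), int(row.shared_all),
                                   int(row.exon_bases))
            assert round_density(d) == row.published_density, gene


class TestAlleleCountPct:
    def test_one_in_twenty_is_five_percent(self):
        assert allele_count_pct(1, 10) == 5.0

    def test_bounds(self):
        assert allele_count_pct(0, 7) == 0.0
        assert allele_count_pct(14, 7) == 100.0
        with pytest.raises(ValueError):
            allele_count_pct(15, 7)


class TestGeneSummary:
    def test_columns_match_set_oracle(self):
        rng = random.Random(6)
        the_iso = iso(exons=((100, 600), (700, 1000)), cds=(150, 950))
        positions = rng.sample(range(101, 600), 12) + rng.sample(range(701, 1000), 6)
        samples = ["s1", "s2", "s3"]
        sites_by_sample = {s: [] for s in samples}
        all_sites = []
        for p in positions:
            carriers = rng.sample(samples, rng.randrange(1, 3))
            v = site(p, {s: ((0, 1) if s in carriers else (0, 0)) for s in samples})
            all_sites.append(v)
            for s in carriers:
                sites_by_sample[s].append(v)
        pool = {v.key for v in all_sites}
        db = PopulationCatalog("DBSNP", set(rng.sample(sorted(pool), 8)))
        cats = [PopulationCatalog(n, set(rng.sample(sorted(pool), 6)))
                for n in ("ASW", "YRI", "CEU")]
        gs = gene_summary("G1", [the_iso], sites_by_sample, db, cats)
        assert gs.n_total == len(pool)
        assert gs.n_known == len(pool & db.sites)
        assert gs.n_total == gs.n_known + gs.n_novel
        shared = pool & cats[0].sites & cats[1].sites & cats[2].sites
        assert gs.n_shared_all == len(shared)
        expected = (gs.n_total - len(shared)) / (gs.exon_bases / 1000)
        assert gs.non_common_density == pytest.approx(expected)
        assert gs.exon_bases == 800

    def test_gene_with_no_variants_all_zero(self):
        gs = gene_summary("G1", [iso()], {"s1": []}, PopulationCatalog("DBSNP"),
                          [PopulationCatalog("ASW")])
        assert (gs.n_total, gs.n_known, gs.n_novel, gs.n_shared_all) == (0, 0, 0, 0)
        assert gs.non_common_density == 0.0


class TestBurdenAndCompoundHet:
    def setup_cohort(self, counts_per_sample, n_positions=8):
        """Build sites so sample i carries counts_per_sample[i] novel sites."""
        samples = [f"s{i}" for i in range(len(counts_per_sample))]
        the_iso = iso()
        positions = [20 + 15 * i for i in range(n_positions)]
        sites_by_sample = {s: [] for s in samples}
        anns = []
        all_sites = {}
        for i, s in enumerate(samples):
            for p in positions[:counts_per_sample[i]]:
                if p not in all_sites:
                    all_sites[p] = site(p, {t: (0, 0) for t in samples})
                all_sites[p].genotypes[s] = (0, 1)
                sites_by_sample[s].append(all_sites[p])
        for v in all_sites.values():
            anns.append(ann_for(v, the_iso))
        return the_iso, anns, sites_by_sample

    def test_strict_universality(self):
        _, anns, sbs = self.setup_cohort([1] * 9 + [0])
        assert burden_screen(anns, sbs, PopulationCatalog("DBSNP")) == []

    def test_all_samples_qualify(self):
        _, anns, sbs = self.setup_cohort([1] * 10)
        (hit,) = burden_screen(anns, sbs, PopulationCatalog("DBSNP"))
        assert hit.counts == {f"s{i}": 1 for i in range(10)}
        assert hit.screen == "burden"

    def test_compound_het_needs_two_everywhere(self):
        _, anns, sbs = self.setup_cohort([2] * 10)
        (hit,) = compound_het_screen(anns, sbs, PopulationCatalog("DBSNP"))
        assert all(c == 2 for c in hit.counts.values())
        _, anns, sbs = self.setup_cohort([2] * 9 + [1])
        assert compound_het_screen(anns, sbs, PopulationCatalog("DBSNP")) == []

    def test_compound_subset_of_burden(self):
        _, anns, sbs = self.setup_cohort([3, 2, 2, 1])
        b = {h.isoform_id for h in burden_screen(anns, sbs, PopulationCatalog("DBSNP"))}
        c = {h.isoform_id for h in compound_het_screen(anns, sbs, PopulationCatalog("DBSNP"))}
        assert c <= b

    def test_enlarging_case_set_never_enlarges_burden_hits(self):
        _, anns, sbs = self.setup_cohort([1, 1, 1, 0])
        small = {s: sbs[s] for s in ("s0", "s1", "s2")}
        db = PopulationCatalog("DBSNP")
        hits_small = burden_screen(anns, small, db)
        hits_all = burden_screen(anns, sbs, db)
        assert {h.isoform_id for h in hits_all} <= {h.isoform_id for h in hits_small}

    def test_dbsnp_sites_do_not_qualify(self):
        _, anns, sbs = self.setup_cohort([1] * 4)
        db = PopulationCatalog("DBSNP", {a.site_key for a in anns})
        assert burden_screen(anns, sbs, db) == []

    def test_homozygous_site_counts_once_by_default(self):
        the_iso, anns, sbs = self.setup_cohort([1, 1])
        for s in sbs:
            for v in sbs[s]:
                v.genotypes[s] = (1, 1)
        db = PopulationCatalog("DBSNP")
        assert compound_het_screen(anns, sbs, db) == []
        hits = compound_het_screen(anns, sbs, db, count_hom_as_two=True)
        assert len(hits) == 1 and all(c == 2 for c in hits[0].counts.values())


class TestArtifactFlags:
    def build_hit(self, vectors, positions, dbsnp_positions=()):
        samples = [f"s{i}" for i in range(len(vectors[0]))]
        sites = []
        for p, vec in zip(positions, vectors):
            gts = {s: g for s, g in zip(samples, vec)}
            sites.append(site(p, gts))
        from exoscreen.screens import ScreenHit
        hit = ScreenHit("NM_1", "G1", "compound_het",
                        counts={s: 2 for s in samples},
                        member_sites={v.key for v in sites})
        sbs = {s: sites for s in samples}
        db = PopulationCatalog("DBSNP",
                               {SiteKey("1", p, "C") for p in dbsnp_positions})
        return hit, sbs, db

    def test_universal_heterozygosity(self):
        hit, sbs, db = self.build_hit([[(0, 1)] * 10], [100])
        assert "universal_heterozygosity" in artifact_flags(hit, sbs, db)

    def test_not_flagged_when_one_sample_hom(self):
        hit, sbs, db = self.build_hit([[(0, 1)] * 9 + [(1, 1)]], [100])
        assert "universal_heterozygosity" not in artifact_flags(hit, sbs, db)

    def test_correlated_haplotype_within_span(self):
        vec = [(0, 1), (0, 0), (0, 1), (1, 1)]
        hit, sbs, db = self.build_hit([vec, list(vec)], [100, 103])
        assert "correlated_haplotype" in artifact_flags(hit, sbs, db)

    def test_vectors_differing_in_one_sample_not_correlated(self):
        v1 = [(0, 1), (0, 0), (0, 1), (1, 1)]
        v2 = [(0, 1), (0, 1), (0, 1), (1, 1)]
        hit, sbs, db = self.build_hit([v1, v2], [100, 103])
        assert "correlated_haplotype" not in artifact_flags(hit, sbs, db)

    def test_distant_identical_vectors_not_correlated(self):
        vec = [(0, 1)] * 4
        hit, sbs, db = self.build_hit([vec, list(vec)], [100, 300])
        flags = artifact_flags(hit, sbs, db, correlated_span_bp=100)
        assert "correlated_haplotype" not in flags

    def test_catalog_recheck_position_only(self):
        # member alt is T; dbSNP holds a C at the same position
        hit, sbs, db = self.build_hit([[(0, 1)] * 3], [100], dbsnp_positions=[100])
        assert "catalog_recheck_hit" in artifact_flags(hit, sbs, db)

    def test_flags_match_vector_comparison_oracle(self):
        rng = random.Random(17)
        for _ in range(25):
            n_sites, n_samp = rng.randrange(2, 5), rng.randrange(2, 6)
            positions = sorted(rng.sample(range(100, 400, 10), n_sites))
            vectors = [[rng.choice([(0, 0), (0, 1), (1, 1)]) for _ in range(n_samp)]
                       for _ in range(n_sites)]
            hit, sbs, db = self.build_hit(vectors, positions)
            flags = artifact_flags(hit, sbs, db, correlated_span_bp=50)
            expect_univ = any(all(g == (0, 1) for g in vec) for vec in vectors)
            expect_corr = any(
                vectors[i] == vectors[j] and abs(positions[i] - positions[j]) <= 50
                for i in range(n_sites) for j in range(i + 1, n_sites))
            assert ("universal_heterozygosity" in flags) == expect_univ
            assert ("correlated_haplotype" in flags) == expect_corr


class TestCandidateGenes:
    RECORDS = [
        AssocRecord("rs10", "GA", 1e-6, True, True),
        AssocRecord("rs11", "GB", 2e-6, False),
        AssocRecord("rs12", "GC", 3e-6, True, False),
        AssocRecord("rs13", "GD", 4e-6, False),
        AssocRecord("rs14", "GA", 5e-6, True),
        AssocRecord("rs15", "GE", 6e-5, True),
    ]

    def test_top_k_then_nonsynonymous(self):
        assert select_candidate_genes(self.RECORDS, 5) == ["GA", "GC"]

    def test_k_exceeding_records_returns_all_nonsyn_genes(self):
        assert select_candidate_genes(self.RECORDS, 100) == ["GA", "GC", "GE"]

    def test_all_synonymous_empty(self):
        recs = [AssocRecord(f"rs{i}", "G", 0.01 * (i + 1), False) for i in range(5)]
        assert select_candidate_genes(recs, 5) == []

    def test_deleterious_sublist(self):
        assert select_candidate_genes(self.RECORDS, 5, deleterious_only=True) == ["GA"]

    def test_ties_broken_by_snp_id(self):
        recs = [AssocRecord("rsB", "G2", 0.5, True),
                AssocRecord("rsA", "G1", 0.5, True)]
        assert select_candidate_genes(recs, 1) == ["G1"]

    def test_invalid_p_value_rejected(self):
        with pytest.raises(ValueError):
            AssocRecord("rs1", "G", 0.0, True)

    def test_read_assoc_records_tsv(self, tmp_path):
        from exoscreen.screens import read_assoc_records
        p = tmp_path / "assoc.tsv"
        p.write_text("snp_id\tgene\tp\tnonsyn\tdeleterious\n"
                     "rs1\tGA\t1e-5\t1\t0\n"
                     "rs2\tGB\t0.5\t0\t1\n")
        recs = read_assoc_records(str(p))
        assert recs == [AssocRecord("rs1", "GA", 1e-5, True, False),
                        AssocRecord("rs2", "GB", 0.5, False, True)]
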
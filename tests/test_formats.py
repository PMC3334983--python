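import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from exoscreen.formats import (
    ConfigurationError,
    Isoform,
    GeneModelError,
    BedFormatError,
    SiteKey,
    VariantSite,
    VcfParseError,
    merge_intervals,
    read_catalog,
    read_gene_models,
    read_targets,
    read_vcf,
    site_key,
    write_catalog,
    write_gene_models,
    write_vcf,
)
from oracles import per_base_membership

VCF_META = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=100000>\n"
    "##contig=<ID=10,length=135000000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
)


def make_vcf(path, body_lines, samples=("S1", "S2")):
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_META + header + "\n" + "".join(l + "\n" for l in body_lines))
    return str(path)


class TestReadVcf:
    def test_empty_vcf(self, tmp_path):
        scan = read_vcf(make_vcf(tmp_path / "e.vcf", []))
        assert list(scan) == []
        assert scan.indel_count == 0

    def test_artifact_locus_record(self, tmp_path):
        """A het-in-all-samples T>A call at a chr10 duplication-artifact position."""
        line = "10\t126717592\t.\tT\tA\t1500\tPASS\t.\tGT:AD\t0/1:20,19\t0/1:18,22"
        (v,) = read_vcf(make_vcf(tmp_path / "a.vcf", [line]))
        assert v.key == SiteKey("10", 126717592, "A")
        assert v.ref == "T"
        assert all(v.is_het(s) for s in ("S1", "S2"))
        assert v.allele_depths["S1"] == (20, 19)

    def test_multiallelic_decomposition(self, tmp_path):
        # hand decomposition: S1 is A/C -> (0,1) vs C and (0,0) vs G;
        # S2 is C/G -> (1,0)-sorted het vs C and het vs G
        line = "1\t500\trs1\tA\tC,G\t90\tPASS\t.\tGT:AD\t0/1:10,5,0\t1/2:0,7,8"
        scan = read_vcf(make_vcf(tmp_path / "m.vcf", [line]))
        assert len(scan) == 2
        vc = next(v for v in scan if v.alt == "C")
        vg = next(v for v in scan if v.alt == "G")
        assert vc.genotypes == {"S1": (0, 1), "S2": (1, 0)}
        assert vg.genotypes == {"S1": (0, 0), "S2": (0, 1)}
        assert vc.allele_depths["S2"] == (0, 7)
        assert vg.allele_depths["S2"] == (0, 8)
        # decomposition conserves the number of alt alleles
        assert len(scan) == 2

    def test_indels_skipped_and_counted(self, tmp_path):
        lines = [
            "1\t100\t.\tAT\tA\t99\tPASS\t.\tGT:AD\t0/1:5,5\t0/0:9,0",
            "1\t200\t.\tC\tCTT\t99\tPASS\t.\tGT:AD\t0/0:9,0\t1/1:0,9",
            "1\t300\t.\tG\tT\t99\tPASS\t.\tGT:AD\t0/1:5,5\t0/1:5,5",
        ]
        scan = read_vcf(make_vcf(tmp_path / "i.vcf", lines))
        assert len(scan) == 1 and scan[0].pos == 300
        assert scan.indel_count == 2
        assert scan.indels_by_sample == {"S1": 1, "S2": 1}

    def test_chr_prefix_normalized(self, tmp_path):
        path = tmp_path / "c.vcf"
        meta = VCF_META.replace("ID=1,", "ID=chr1,")
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1"
        path.write_text(meta + header + "\n" + "chr1\t42\t.\tA\tG\t60\tPASS\t.\tGT:AD\t0/1:5,5\n")
        (v,) = read_vcf(str(path))
        assert v.chrom == "1"

    def test_unknown_sample_raises(self, tmp_path):
        path = make_vcf(tmp_path / "s.vcf", [])
        with pytest.raises(ConfigurationError, match="S9"):
            read_vcf(path, ["S1", "S9"])

    def test_malformed_record_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1"
        path.write_text(VCF_META + header + "\n" + "1\tnot_a_pos\t.\tA\tG\t60\n")
        with pytest.raises(VcfParseError):
            list(read_vcf(str(path)))


class TestVcfRoundTrip:
    def test_write_then_read_preserves_fields(self, tmp_path):
        rng = random.Random(0)
        samples = ["S1", "S2", "S3"]
        sites = []
        for i in range(20):
            gts = {s: rng.choice([(0, 0), (0, 1), (1, 1)]) for s in samples}
            sites.append(VariantSite(
                chrom="1", pos=100 + 13 * i, ref="A", alt=rng.choice("CGT"),
                qual=float(rng.randrange(51, 3000)),
                genotypes=gts,
                allele_depths={s: (rng.randrange(0, 40), rng.randrange(0, 40))
                               for s in samples}))
        path = tmp_path / "rt.vcf"
        write_vcf(str(path), sites, samples)
        back = read_vcf(str(path), samples)
        assert len(back) == len(sites)
        original = {v.key: v for v in sites}
        for v in back:
            o = original[v.key]
            assert (v.ref, v.pos, v.chrom) == (o.ref, o.pos, o.chrom)
            assert v.qual == pytest.approx(o.qual, abs=0.01)
            assert {s: tuple(sorted(g)) for s, g in v.genotypes.items()} == \
                   {s: tuple(sorted(g)) for s, g in o.genotypes.items()}
            assert v.allele_depths == o.allele_depths


class TestTargets:
    def test_empty_bed(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert read_targets(str(p)) == set()

    def test_overlapping_intervals_merge(self, tmp_path):
        p = tmp_path / "o.bed"
        p.write_text("1\t100\t200\n1\t150\t250\n")
        (t,) = read_targets(str(p))
        assert (t.start, t.end) == (100, 250)

    def test_bad_interval_raises(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("1\t500\t400\n")
        with pytest.raises(BedFormatError):
            read_targets(str(p))

    def test_merge_against_per_base_oracle(self, tmp_path):
        raw = [(10, 40), (35, 60), (100, 130), (125, 150), (200, 210)]
        p = tmp_path / "m.bed"
        p.write_text("".join(f"1\t{s}\t{e}\n" for s, e in raw))
        merged = [(t.start, t.end) for t in sorted(read_targets(str(p)))]
        for pos in range(0, 260):
            assert per_base_membership(pos, merged) == per_base_membership(pos, raw)
        # merged set is disjoint
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert e1 < s2

    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 50)), max_size=15))
    def test_merge_idempotent_and_order_independent(self, raw):
        ivs = [(s, s + l) for s, l in raw]
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        assert merge_intervals(reversed(ivs)) == merged


class TestGeneModels:
    def test_minus_strand_exons_sorted_ascending(self, tmp_path):
        p = tmp_path / "g.refflat"
        p.write_text("TOY\tNM_1\t1\t-\t100\t400\t120\t380\t2\t100,300,\t200,400,\n")
        (iso,) = read_gene_models(str(p))
        assert iso.exons == ((100, 200), (300, 400))
        assert iso.strand == "-"

    def test_shared_gene_symbol_isoforms(self, tmp_path):
        p = tmp_path / "c.refflat"
        p.write_text(
            "CTBP2\tNM_001329\t10\t-\t1000\t2000\t1100\t1900\t1\t1000,\t2000,\n"
            "CTBP2\tNM_001083914\t10\t-\t1000\t2300\t1100\t1900\t2\t1000,2100,\t2000,2300,\n")
        isos = read_gene_models(str(p))
        assert [i.isoform_id for i in isos] == ["NM_001329", "NM_001083914"]
        assert {i.gene_symbol for i in isos} == {"CTBP2"}

    def test_cds_lengths_match_hand_splice(self, tmp_path):
        p = tmp_path / "l.refflat"
        rows = [
            # (exons, cds) -> hand-computed spliced CDS length
            ("A\tNM_A\t1\t+\t0\t300\t30\t270\t1\t0,\t300,", 240),
            ("B\tNM_B\t1\t+\t0\t500\t50\t450\t2\t0,250,\t200,500,", 350),
            ("C\tNM_C\t1\t-\t0\t600\t100\t580\t3\t0,200,400,\t150,350,600,", 380),
        ]
        p.write_text("".join(r + "\n" for r, _ in rows))
        for iso, (_, expected) in zip(read_gene_models(str(p)), rows):
            assert iso.cds_len == expected

    def test_noncoding_transcript_flagged(self, tmp_path):
        p = tmp_path / "n.refflat"
        p.write_text("NC\tNR_1\t1\t+\t0\t300\t300\t300\t1\t0,\t300,\n")
        (iso,) = read_gene_models(str(p))
        assert not iso.is_coding

    def test_cds_outside_exons_raises(self, tmp_path):
        p = tmp_path / "bad.refflat"
        p.write_text("X\tNM_X\t1\t+\t100\t400\t250\t320\t2\t100,350\t200,400\n")
        with pytest.raises(GeneModelError):
            read_gene_models(str(p))

    def test_round_trip(self, tmp_path):
        iso = Isoform("NM_9", "G9", "2", "-", ((10, 50), (90, 200)), 20, 150)
        p = tmp_path / "rt.refflat"
        write_gene_models(str(p), [iso])
        assert read_gene_models(str(p)) == [iso]


class TestCatalog:
    def test_empty(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert len(read_catalog(str(p), "X")) == 0

    def test_duplicates_kept_first(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("1\t100\tA\trs1\n1\t100\tA\trs2\n1\t200\tC\n")
        cat = read_catalog(str(p), "X")
        assert len(cat) == 2
        assert cat.rsids[SiteKey("1", 100, "A")] == "rs1"

    def test_size_matches_distinct_key_oracle(self, tmp_path):
        rng = random.Random(1)
        rows = [(rng.randrange(1, 3), rng.randrange(1, 40), rng.choice("ACGT"))
                for _ in range(100)]
        p = tmp_path / "r.tsv"
        p.write_text("".join(f"{c}\t{pos}\t{a}\n" for c, pos, a in rows))
        cat = read_catalog(str(p), "X")
        assert len(cat) == len({(str(c), pos, a) for c, pos, a in rows})

    def test_round_trip(self, tmp_path):
        from exoscreen.formats import PopulationCatalog
        cat = PopulationCatalog("Y", sites={SiteKey("1", 5, "G"), SiteKey("2", 9, "T")},
                                rsids={SiteKey("1", 5, "G"): "rs77"},
                                frequencies={SiteKey("1", 5, "G"): 0.125})
        p = tmp_path / "rt.tsv"
        write_catalog(str(p), cat)
        back = read_catalog(str(p), "Y")
        assert back.sites == cat.sites
        assert back.rsids == cat.rsids
        assert back.frequencies == cat.frequencies


class TestCatalogMatching:
    def test_site_vs_position_matching(self):
        from exoscreen.formats import PopulationCatalog
        cat = PopulationCatalog("X", sites={SiteKey("1", 100, "C")})
        other_allele = SiteKey("1", 100, "T")
        assert not cat.contains(other_allele)
        assert cat.contains(other_allele, match_on="position")
        with pytest.raises(ValueError):
            cat.contains(other_allele, match_on="rsid")


class TestSiteKey:
    def test_identity_semantics(self):
        v = VariantSite(chrom="10", pos=126717592, ref="T", alt="A", qual=60.0)
        assert site_key(v) == SiteKey("10", 126717592, "A")
        w = VariantSite(chrom="10", pos=126717592, ref="T", alt="G", qual=60.0)
        assert site_key(v) != site_key(w)
        assert len({site_key(v), SiteKey("10", 126717592, "A")}) == 1

    def test_invalid_sites_rejected(self):
        with pytest.raises(ValueError):
            VariantSite(chrom="1", pos=10, ref="A", alt="A", qual=1.0)
        with pytest.raises(ValueError):
            VariantSite(chrom="1", pos=0, ref="A", alt="C", qual=1.0)
        with pytest.raises(ValueError):
            VariantSite(chrom="1", pos=10, ref="AT", alt="A", qual=1.0)
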
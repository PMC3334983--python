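# exoscreen

Rare-variant screening for small case-only exome cohorts.

`exoscreen` implements the post-calling analysis of an exome pilot screen in
a complex disease (its original application was young-onset ischemic stroke:
10 male cases, 8 African-American and 2 European-Caucasian, with no matched
controls): quality filtering of called SNVs, isoform-aware functional
annotation, variant-sharing analysis against public control-population
catalogs, a gene-level rare-variation density statistic, and
burden / compound-heterozygote screens with diagnostics for
segmental-duplication artifacts.  It is aimed at statistical geneticists
prototyping rare-variant analyses at small scale, where every step must be
auditable and every screen testable against planted ground truth.

## What it computes

Per sample, SNVs inside the capture targets are filtered by

* site quality `QUAL > 50` (strict),
* allele balance at heterozygous calls `ref_reads / (ref + alt) < 0.75` (strict),
* a clustering rule: every SNV inside any 10 bp window holding more than
  two of that sample's SNVs is removed (dense clusters signal misalignment).

A variant is **novel** (the operational "rare") when its `(chrom, pos, alt)`
key is absent from a dbSNP stand-in.  The case **pool** is the union of
sites over all cases; sharing with control catalogs (e.g. 1000 Genomes
ASW / YRI / CEU site lists) is computed set-wise.  For a gene *g* with
exonic footprint *L(g)* bp, *n* case variants of which *s* sit in the
intersection of cases with **all** control populations, the
**non-common SNP density** is

```
density(g) = (n - s) / (L(g) / 1000)    [variants per kb]
```

The **burden screen** reports transcript isoforms in which every case
carries ≥ 1 novel variant; the **compound-heterozygote ("double-hit")
screen** requires ≥ 2 distinct novel sites per case per isoform (unphased).
Hits are probed for duplication-artifact signatures: a member site
heterozygous in *every* sample, nearby member sites with perfectly
correlated genotype vectors, and "novel" sites that re-match dbSNP when the
allele is ignored.

A fully seeded synthetic-cohort generator (`exoscreen.simulate`) emits a
reference FASTA, refFlat gene models, capture BED, catalog TSVs, a
multi-sample VCF and a ground-truth ledger, with a density-enriched gene,
a universal-burden gene, a compound-het gene and a duplication-artifact
locus planted for end-to-end validation.

## Worked example

```python
from exoscreen import CohortConfig, PipelineConfig, run_pipeline, simulate_cohort
from exoscreen.screens import round_density

cohort = simulate_cohort(CohortConfig(seed=1), out_dir="sim")
p = cohort.paths
result = run_pipeline(PipelineConfig(
    vcf=p["vcf"], targets=p["targets"], models=p["models"],
    reference=p["reference"], dbsnp=p["catalog_DBSNP"],
    catalogs={n: p[f"catalog_{n}"] for n in ("ASW", "YRI", "CEU")},
    out_dir="reports", groups=cohort.config.groups))

novel = result.group_means["n_pass_and_novel"]
print(f"mean novel SNVs/sample: {novel['African-American']:.1f} (African-American) "
      f"vs {novel['Caucasian']:.1f} (Caucasian)")
print(f"case pool: {result.overlap.set_sizes['cases']} sites, "
      f"{result.overlap.shared_all} shared by all four populations")
print(f"burden screen: {len(result.burden_hits)} isoforms; "
      f"double-hit screen: {len(result.compound_het_hits)} isoforms")
dens = next(g for g in result.gene_summaries
            if g.gene_symbol == cohort.ledger.planted["gene_symbols"]["density"])
print(f"planted density gene {dens.gene_symbol}: {dens.n_total} case SNVs, "
      f"{dens.n_shared_all} shared-all, {dens.exon_bases} exonic bp "
      f"-> {round_density(dens.non_common_density)}/kb")
for hit in result.compound_het_hits:
    if len(hit.artifact_flags) == 3:
        print(f"duplication-artifact candidate {hit.gene_symbol}/{hit.isoform_id}: "
              f"{', '.join(sorted(hit.artifact_flags))}")
```

This prints:

```
mean novel SNVs/sample: 212.9 (African-American) vs 99.5 (Caucasian)
case pool: 4846 sites, 1293 shared by all four populations
burden screen: 32 isoforms; double-hit screen: 14 isoforms
planted density gene GENE001: 10 case SNVs, 3 shared-all, 1410 exonic bp -> 5.0/kb
duplication-artifact candidate GENE000/NM_100000: catalog_recheck_hit, correlated_haplotype, universal_heterozygosity
duplication-artifact candidate GENE000/NM_100001: catalog_recheck_hit, correlated_haplotype, universal_heterozygosity
```

The two ancestry groups show the configured known/novel split (the group
simulated with the lower dbSNP-known fraction yields roughly twice the novel
calls); the planted density gene reproduces exactly the counts the generator
ledger promised (10 total, 3 shared by all four populations); and only the
planted duplication artifact carries all three diagnostic flags at once —
background double-hit isoforms may trip one flag by chance, which is exactly
why the three signatures are reported jointly.

The same stages are scriptable from a shell via the `exoscreen` CLI
(`simulate`, `filter`, `annotate`, `overlap`, `screen`, `run-all`,
`fixtures`); `exoscreen run-all --help` lists the inputs.

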
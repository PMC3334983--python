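# Methods

## Scope and model

`exoscreen` analyses called biallelic SNVs from a small case-only exome
cohort.  It deliberately starts *after* alignment and variant calling:
its inputs are a multi-sample VCF, the capture-target BED, refFlat-style
transcript models, the reference FASTA, and site-list catalogs standing
in for dbSNP and for control populations.  Base-quality recalibration,
realignment, duplicate removal and the calling itself are upstream
concerns; indels are parsed and counted but excluded from every analysis.

Variant identity throughout is the `SiteKey` `(chromosome, 1-based
position, alternate allele)`.  Catalog membership — including dbSNP
novelty — is decided on this key, not on rsIDs, because control catalogs
are consumed as plain site lists.  An allele-agnostic (position-only)
recheck exists solely as an artifact diagnostic.  Chromosome names are
normalised by stripping a leading `chr`; all internal interval arithmetic
is 0-based half-open with conversion confined to the I/O layer.

## Quality filters

Per sample, over the sites where that sample carries an alternate allele,
in fixed order after target restriction:

1. **Site quality**: `QUAL > 50`, strict, site-level.
2. **Allele balance**: at heterozygous calls the reference-read fraction
   must be `< 0.75`, strict.  The fraction is undefined — and the filter
   passes by convention — for homozygous calls, missing depths, or zero
   total depth.  Alternate-fraction and max-fraction variants are
   available (`ab_mode`); callers differ on this convention and the
   reference-fraction reading is the default.
3. **Window density**: an SNV fails if it lies in *any* 10 bp window
   containing more than two of the sample's SNVs; all SNVs inside a
   violating window fail, not just the excess.  Equivalently, whenever
   three consecutive sites span ≤ 9 bp all three are removed.  This is
   the simplest deterministic reading of a "max two per 10 bp" rule; a
   cap-at-two variant would need an arbitrary choice of survivors.

Two consequences worth noting.  The chain is applied per sample, so a
site can pass for one sample and fail for another (via balance or
clustering).  And the chain is *not* jointly monotone: tightening the
quality threshold can delete a member of a dense window and thereby
rescue its neighbours from the clustering rule.  Monotonicity holds for
each filter in isolation and is tested that way.

## Annotation

Each (SNV, overlapping isoform) pair receives exactly one effect class:
`utr5`, `utr3`, `intronic`, `noncoding-transcript`, or — inside the CDS —
`coding-synonymous`, `missense`, `nonsense`, or `stop-loss`; SNVs
touching no transcript get one `intergenic` record.  The affected codon
is rebuilt from the spliced CDS (exonic CDS segments concatenated in
genomic order, reverse-complemented for minus-strand models), so codons
spanning an exon junction are handled naturally rather than as a special
splice-region class.  Translation uses the standard nuclear code; no
selenocysteine handling.  Protein positions are 1-based counting the
initiator methionine.  `stop-loss` (reference codon is a stop, alternate
is not) is included so the classes partition all pairs; it preserves the
defining biconditionals (nonsense ⇔ alt is a stop and ref is not;
synonymous ⇔ equal residues; missense ⇔ both non-stop and different).
Models whose CDS length is not a multiple of 3 are excluded from
annotation and logged rather than guessed at.  A disagreement between the
VCF REF and the reference base is a hard error naming the site.

## Sharing and the density statistic

The case pool is the union of post-filter site keys over all cases —
variants seen at least once in any individual, not unique-per-sample
counts.  All intersections with the control catalogs are derived from one
exact-membership (Venn) partition, so pairwise/3-way/all-way counts are
mutually consistent by construction.

For a gene with exonic footprint `L` bp (union over all its isoforms'
exons), `n` case variants and `s` of them in the all-way intersection of
cases with every control catalog, the non-common SNP density is
`(n − s) / (L / 1000)` variants per kb.  "Non-common" subtracts only the
sites shared by *all* populations simultaneously: a variant shared with
some but not all controls still counts, which suits a search for
cross-ancestry excess variation.  The stricter reading — subtract
anything present in any control — is available as `non_common_mode =
"union"`.  Full precision is kept internally; report columns round
half-up to one decimal.  An empty footprint makes the density undefined
(reported missing), not zero.

The shipped per-gene fixture table (`exoscreen.datasets`) carries the
published counts of the original pilot.  Three of its twenty rows
(HLA-DPB1, NAT10, FMO2) print a one-decimal density that cannot be
obtained from their own printed inputs under any standard rounding
(20.3 vs 20.2, 2.4 vs 2.3, 2.7 vs 2.6); they are retained in the fixture
but excluded from `consistent_only` selections and from the acceptance
checks rather than reverse-engineered.

## Screens and artifact diagnostics

"Rare" for both screens defaults to dbSNP-novelty; absence from the
control catalogs can be required additionally.  The burden screen keeps
isoforms where every case carries ≥ 1 qualifying site; the double-hit
screen requires ≥ 2 *distinct* sites per case.  Phase is not used (none
is available in this design), so a "compound heterozygote" here is the
unphased two-site pattern.  A homozygous novel genotype counts as one
site by default (`count_hom_as_two` flips this); with no phasing there is
no way to know whether two haplotypes are hit, and the conservative
count avoids manufacturing double-hits from single sites.

Candidate hits are probed for three signatures of an unannotated
segmental duplication, whose co-aligning paralogous reads fake variants:

* `universal_heterozygosity` — some member site heterozygous in every
  sample (a real rare variant should not be);
* `correlated_haplotype` — two member sites within 100 bp (configurable)
  with byte-identical genotype vectors across all samples;
* `catalog_recheck_hit` — a "novel" member site matching dbSNP when the
  allele is ignored.

Each flag alone can fire on honest data (singleton pairs in one sample
produce identical vectors, for instance); the diagnosis is the
conjunction, and the report keeps the flags separate for that reason.

GWAS-seeded candidate selection takes association records (SNP, gene,
p-value, nonsynonymous flag, optional precomputed deleteriousness flag),
keeps the k smallest p-values with ties broken by SNP id for determinism,
filters to nonsynonymous, and returns distinct gene symbols in selection
order.

## Synthetic cohort generator

The generator emulates the pilot's study conditions, scaled to desk size:

* **Cohort**: 8 + 2 diploid cases in two ancestry groups.
* **Genome**: one contig, 60 multi-exon genes (2–4 exons, 200–500 codons,
  30 bp UTRs, both strands, ~20 % with a duplicate isoform), every CDS
  starting ATG, ending in a stop, length divisible by 3.  Capture targets
  are the exon union padded by 20 bp.
* **Calls**: per-sample site counts Poisson with mean 2,000 — the
  published per-sample totals (~26–32 K) scaled down so the whole suite
  runs in seconds.  Known-variant fractions are 88.5 % and 95 % for the
  two groups, matching the published post-filter known/novel split.
  Sites are drawn from shared pools (4,000 dbSNP-member, 1,500 novel,
  2,000 control-only sites), giving realistic cross-sample sharing.
* **Catalog structure**: dbSNP-member case sites enter each control
  catalog independently with probability 0.7; novel sites with 0.05; 2 %
  of novel sites get a position-only dbSNP decoy to exercise the
  allele-agnostic recheck.
* **Call quality**: ~5 % of sites draw `QUAL ≤ 50`, ~3 % of het calls
  draw reference-heavy depths failing the balance filter; with incidental
  window-rule losses the overall removal rate lands near the ~8–14 %
  seen in the published per-sample summaries (used as a realism guide,
  not a target).  Planted sites always pass: high quality, balanced
  depths, ≥ 15 bp spacing from any other pooled site so the window rule
  cannot claim them.
* **Planted signals**, recorded exactly in a ground-truth ledger:
  a density gene with 10 case sites of which 3 are shared by all four
  populations and 3 are novel (the published kappa-casein shape); a
  burden gene (≥ 1 novel site per case); a compound-het gene (≥ 2 per
  case); and an artifact locus on a forced minus-strand gene — protein
  positions 7 and 8 forced to Lys (genomic `TTT`), a genomic T→A at
  codon 8 making an unphased pseudo-nonsense call heterozygous in every
  sample, a perfectly correlated flank 3 bp away, and dbSNP decoys at
  both positions under a different allele.

Everything is drawn from a single seeded NumPy generator; a seed fully
determines every output byte.  Off-target SNVs and short indels are mixed
in to exercise target restriction and non-SNV counting.

What the generator does **not** emulate: read-level evidence (no
FASTQ/BAM, no depth-of-coverage structure beyond per-site AD), linkage
disequilibrium beyond the one planted correlated pair, population
substructure or admixture, and realistic per-kb variant density — packing
2,000 sites per sample into a ~70 kb exonic footprint makes background
genes far denser than real exome data, so per-gene density *rankings* on
synthetic cohorts are not meaningful; the planted density gene validates
the arithmetic, not a ranking.  Passing end-to-end tests therefore show
the bookkeeping and set/codon arithmetic are right under the planted
truth, not that the screens would be well-powered on real exomes.

## Numerical and design choices

* Strict inequalities at both filter thresholds; boundary cases (QUAL
  exactly 50, balance exactly 0.75) fail.
* Report rounding is decimal half-up (`5.35 → 5.4`), computed with
  `Decimal`, so Python's banker's rounding cannot flip a printed value.
* Deterministic orderings everywhere: annotation records by
  (chrom, pos, alt, isoform), screen hits by isoform id, top-k selection
  ties by SNP id, serialized JSON with sorted keys — identical inputs
  give byte-identical reports.
* Multi-allelic VCF records are decomposed per alternate allele; in a
  decomposed record, other alternate alleles are treated as reference
  for genotype purposes.
* Degenerate inputs: empty VCFs produce valid all-zero reports; genes
  with no case variants report zero density; a gene with an empty
  footprint reports a missing density.

## Problem sizes

Default test and demonstration scale: 10 samples, 60 genes (~70 kb
exonic), ~2,000 sites per sample (~5,500 distinct records), catalogs of
4–6 K sites.  Generation takes a few seconds and a full pipeline run a
few seconds more on one core; the oracle-equivalence suites use 1,000
random window-filter instances, 50 random Venn instances and 100 random
coding SNVs per strand.

## Known limitations

* Phase-blind compound-het calls overcount genes where two "hits" sit on
  the same haplotype; without phasing this is irreducible.
* The window filter's all-fail semantics makes the filter chain
  non-monotone as a whole (see above).
* dbSNP matching requires the alternate allele; a catalog that records a
  different alt at the same position makes a truly known variant look
  novel — precisely the failure mode the position-only recheck flags.
* Control catalogs are site lists without genotypes or frequencies, so
  frequency-aware filtering (e.g. keep-if-frequency-unknown) is limited
  to what the optional catalog frequency column provides.
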
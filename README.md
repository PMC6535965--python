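# budsport

Paired-sample detection and characterization of somatic loss-of-heterozygosity
(LOH) events, built around the classic system of a fruit-tree **bud sport**: a
branch that mutates somatically and changes phenotype — here a flat peach
(*Prunus persica*) whose sport bears round fruit because one chromosome arm
lost the haplotype carrying the dominant flat-shape allele.

Given genotype calls for the wild type and its sport (the same individual, so
nearly every site should agree), the package answers four questions:

1. **How different are the two genomes?** Genotypes at biallelic SNPs are
   coded 0/1/2 (hom-ref / het / hom-alt) and summarized per scaffold as a
   discordance count *D* over *N* called SNPs on *L* bp, with rate *D/L* and
   density *N/L* — the arithmetic of a paired-discordance table, including a
   double-haploid self-comparison control that puts an empirical floor on the
   calling error rate.
2. **Where is the LOH event?** A site is LOH-discordant when the wild type is
   het (1) but the sport is hom (0 or 2). Runs of ≥ 5 consecutive discordant
   sites seed segments; runs are merged across at most 5 interrupting
   concordant-het sites (het false negatives), concordant-hom sites being
   uninformative, and the het→hom transition is reported as a bracket
   `(last concordant-het position, first discordant position)`.
3. **Copy-neutral or deletion?** Per-site depth ratios r = DP_sport/DP_wild
   are compared between the candidate region and the genome-wide baseline;
   the normalized median ratio (region/genome) is ≈ 1 for copy-neutral LOH
   and ≈ 0.5 for a hemizygous deletion, independent of library size.
4. **Which haplotype survived?** From phased haplotypes, a 2×2 identity
   matrix (fraction of matching alleles between each sport and wild
   haplotype) shows whether both sport haplotypes descend from a single wild
   haplotype; a genotype–phenotype table tests the dominance rule "carrying
   the dominant marker allele ⇒ flat fruit".

A fully seeded synthetic generator (`budsport.synthetic_data`) reproduces the
study conditions — eight peach scaffolds with their published SNP counts, the
event-interval composition (8,501 het + 2,014 hom-variant sites distal to the
22,195,188 bp breakpoint, 36 het dropouts), per-scaffold background error
counts, 28×/26× negative-binomial depths — and plants a configurable event:
copy-neutral LOH, hemizygous deletion, or none. It also models the two
break-induced-replication timings: repair in **G1** yields one daughter-cell
class (all hom distal to the break), repair in **G2** yields a het/hom mosaic.

## Worked example

Simulate the event-scaffold preset, scan it, and check the depth verdict:

```bash
budsport simulate --preset pp06 --seed 1 -o demo/sim
budsport scan demo/sim/pair.vcf -o demo/scan
# 1 segment(s); brackets: ['Pp06:(22,192,831; 22,195,542)']
head -2 demo/scan/segments.tsv
# scaffold  start     end       n_sites  n_discordant  n_interrupting_het  n_concordant_hom  consistency_pct
# Pp06      22195542  30766614  10515    8465          36                  2014              99.66
budsport depth demo/sim/pair.vcf --region Pp06:22195189-30767194 -o demo/depth
# { ... "normalized_ratio": 1.0055, "fraction_in_band": 0.9272, "verdict": "copy_neutral" }
```

The scanner recovers a single segment spanning the 10,515 distal SNPs: 8,465
het→hom conversions, 36 interrupting het calls (99.66% of sites consistent
with LOH), and a transition bracket that contains the planted breakpoint at
22,195,188 bp. The depth verdict is copy-neutral: the region's median depth
ratio is indistinguishable from the genome-wide one (a deletion would halve
it). `budsport haplotrace demo/sim/phased_truth.vcf -o demo/hap` then
identifies which wild haplotype both sport haplotypes descend from.

The same subcommands run on real data: one two-sample VCF (or two
single-sample VCFs) with GT/DP/GQ fields, hard-filtered first with
`budsport filter` (QD, MQ, FS, rank-sum, SOR and GQ gates, first-failure
attribution per rule).

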
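# Methods

## Problem and model

A bud sport is a somatic lineage of the same individual, so its genome should
match the parent branch at essentially every site; the analysis model treats
observed genotype discordance as the sum of (a) a low, genome-wide
genotyping-error floor and (b) zero or one long somatic event per scaffold.
The event of interest is loss of heterozygosity (LOH): a contiguous interval
where sites heterozygous in the wild type are homozygous in the sport. Two
physical mechanisms are distinguished by read depth: **copy-neutral LOH**
(one haplotype replaced by a copy of the other, e.g. via break-induced
replication; depth unchanged) and **hemizygous deletion** (one copy lost;
depth halved over the interval).

## Genotype coding and discordance statistics

Biallelic SNP genotypes are coded 0 (hom-ref), 1 (het), 2 (hom-alt); missing
calls get a sentinel distinct from 0. Per scaffold, discordance D, called
SNPs N and length L give rate D/L and density N/L, reported in
3-significant-figure scientific notation (uppercase E, no leading zero in
the exponent) and, for densities, as "1 SNP/X bp" with X = L/N rounded to
two significant figures (kb phrasing at ≥ 1 kb). Two discordance definitions
are exposed: `any_mismatch` (any genotype difference; used for the summary
tables) and `loh_only` (wild 1 → sport 0/2; used by the scanner). The
denominators are scaffold lengths, not SNP counts — that is what reproduces
the published-style rates exactly.

A self-comparison control (a double-haploid sample coded against its own
reference, where the true genotype is 0 everywhere) decomposes the error
floor into het inconsistencies (paralog-collapse candidates) and hom
inconsistencies (likely reference-assembly errors).

## Hard filtering

The site-level filter thread follows GATK-style hard filters with the gates
QD < 10, MQ outside (59.9, 60.1), FS > 15, |MQRankSum| > 0.04,
ReadPosRankSum < −1.5, SOR > 2, |ClippingRankSum| > 0.3, plus per-genotype
GQ < 20 and completeness. Rank-sum windows printed as two one-sided
conditions are implemented as absolute-value bounds; ReadPosRankSum is
one-sided by default (matching the printed thread) with a two-sided switch.
An absent INFO metric means the rule cannot fire (logged), and fail counts
use first-failure attribution in the listed order, so they sum to the number
of rejected sites.

## LOH scanning

Sites are classified relative to the pair: `D` (wild het, sport hom — event
evidence), `H` (het in both — an interruption: either retained
heterozygosity or a het false negative), `R` (wild hom, sport het —
gain-of-heterozygosity, evidence against), and transparent
(concordant-homozygous or hom/hom mismatches — a site with no wild-type
heterozygosity carries no information about losing it). The scan runs on the
informative (non-transparent) subsequence:

1. take maximal runs of consecutive `D`;
2. merge adjacent runs separated by ≤ `max_gap_sites` (default 5) `H` sites
   and no `R`;
3. emit a merged cluster as a segment iff it contains at least one run of
   ≥ `min_run` (default 5, inclusive; a strict-greater switch exists)
   consecutive `D` sites.

Treating concordant-hom sites as transparent is essential: the real event
interval is ~19% concordant-hom, so counting those toward the merge gap
would fragment a single biological event into several segments in a large
share of realizations. Letting clusters absorb sub-threshold `D` runs
(rather than requiring every constituent run to seed) keeps the reported
discordant count equal to the full event content when an interruption falls
near the segment edge.

Segment coordinates are the first/last discordant SNP (1-based inclusive;
optionally extended to the scaffold end for terminal segments). Consistency
is the fraction of all sites inside the segment that do not contradict LOH,
i.e. `(n_sites − n_interrupting_het)/n_sites`. The het→hom transition is
reported as a bracket — (last concordant-het position upstream of the
segment, first discordant position) — never a single guessed base; the
bracket covers the true breakpoint except when a background miscall lands
within the merge gap of the event edge, which is indistinguishable from
event evidence in the data (probability ≈ 0.3% per realization at the
default error density).

## Depth-ratio discrimination

Per-site ratios r = DP_sport/DP_wild (orientation invertible) are summarized
by medians — robust to depth outliers — inside the candidate region and
genome-wide excluding it. The verdict uses the normalized ratio
region_median/genome_median, which cancels library-size differences:
< 0.75 → deletion, > 0.85 → copy-neutral, else ambiguous. The thresholds
are midpoints between the expectations 0.5 (deletion) and 1.0 (neutral)
with an ambiguity buffer; fewer than 50 region sites forces an ambiguous
verdict. Zero-depth sites are excluded and counted. The report also carries
the share of region ratios in [0.5, 1.5] and below 1.

## Haplotype tracing and the dominance rule

Given four phased haplotypes over the event interval, entry (i, j) of the
identity matrix is the fraction of sites where sport haplotype i matches
wild haplotype j. If both sport rows argmax on the same wild haplotype with
margin ≥ 0.05 (an artifact choice; there is no field-standard criterion for
"derived from"), that haplotype is called the origin and the other lost.
Phasing is consumed, not computed. The dominance check takes an
(accession, phenotype, genotype) table and reports the share of flat
accessions carrying ≥ 1 dominant (T) allele, whether every round accession
is A/A, and all accessions violating a strict dominance-determination rule
(round carriers and flat non-carriers). Allele labels are whatever strand
the input uses; no strand flipping is attempted.

## Synthetic generator

The generator's defaults are the study conditions: eight scaffolds
(47.9–18.5 Mb, 225,694,811 bp total) with their published per-scaffold SNP
counts (237,256 on placed scaffolds); an event scaffold whose distal
interval (breakpoint 22,195,188 bp to the 30,767,194 bp telomere) carries
exactly 8,501 het and 2,014 hom-variant wild-type sites; 36 het-dropout
sites left concordant-het inside the event; per-scaffold background
genotype-error counts (102 total, matching the observed background
discordance; on the event scaffold they are planted proximal to the
breakpoint only, since the observed distal discordance is purely the
event); and depths drawn as negative binomial with means 28×/26×.

Choices where the source documents give no value, made once:

* **SNP positions** are uniform per scaffold (density is documented only at
  scaffold resolution); real SNPs cluster, which the tests therefore do not
  exercise.
* **Het fraction outside the event interval** defaults to the event
  interval's composition (8,501/10,515 ≈ 0.808), the only interval whose
  composition is documented.
* **Depth dispersion** defaults to k = 200 (variance m + m²/k — mildly
  overdispersed beyond Poisson). Independent per-sample counts at 26–28×
  put at most ~94% of depth ratios in [0.5, 1.5] even at the Poisson limit;
  k = 200 gives ~93%, the closest realistic match to the ~95% in-band share
  of the study system without modelling between-sample depth correlation.
  Verdict accuracy is insensitive to this parameter.
* **Het dropouts** are planted among interior distal het sites (not the
  first or last), so the configured count is realized as interruptions
  inside the called segment — the published count is by definition counted
  within the event.
* **Errors** are planted as exact counts by default so tests are non-flaky;
  a Bernoulli per-site rate mode is available.

Mechanism models: under **G1** repair every distal wild-het site becomes
homozygous for the retained haplotype's allele. Under **G2** with
`mosaic_fraction` f < 1 the sport sample is a cell mixture; at a former het
site the expected alt-read fraction is f·a + (1−f)/2 (a ∈ {0,1} the
retained allele), alt reads are binomially sampled from the site's depth,
and the genotype is re-called with hom thresholds at 25%/75% alt fraction.
`simulate_cell_lineage` exposes the daughter-class model directly: G1 yields
one class; G2 yields the deterministic first-division pair {het, hom} plus
Bernoulli(1/2) lineage membership for further daughters.

What the generator does **not** emulate: read-level errors and mapping
artifacts (errors enter only as genotype flips), SNP clustering, GC/
mappability depth waves, between-sample depth correlation, multiallelic
sites and indels (emitted VCFs are pure biallelic SNPs), and structural
variants other than the single planted event. Passing tests therefore show
that the statistics and the scanner behave correctly under the stated
composition and error rates — not that they are robust to artifacts absent
from the model.

## Numerical and interface conventions

Coordinates are 1-based inclusive everywhere in memory; conversion to BED's
0-based half-open convention happens only in the writer (and is round-trip
tested). Two single-sample VCFs are matched on (scaffold, position, ref,
alt); allele-mismatched positions are dropped and counted. Simulated output
is a deterministic, byte-identical function of the seed, which is why the
generator writes VCF text directly. Percentages are rounded to 1 decimal
(consistency to 2); rates use 3 significant figures.

## Problem sizes

The seeded studies in the test suite and the acceptance script use the full
event-scaffold preset (35,486 sites) at 100 replicates for segment
recovery, verdict accuracy (50 copy-neutral + 50 deletion) and breakpoint
coverage, 50 replicates for origin recovery, 1,000 daughters for the
mechanism distributions, and 1,000 random ≤ 50-site inputs for the
scanner-vs-enumeration equivalence check; unit tests use a miniature 400-
site single-scaffold configuration.

## Known limitations

* The scanner is a run test, by design; it does not segment copy number
  (no HMM/CBS) and will not find events shorter than `min_run` informative
  sites or events interrupted by > `max_gap_sites` consecutive het calls.
* The transition bracket inherits the error-merging ambiguity described
  above; with real data the bracket should be read together with the
  per-site discordance track.
* The depth verdict assumes the candidate region is a minority of the
  genome (the baseline excludes it but must remain representative).
* The dominance check is a tabulation, not an association test; it carries
  no population structure correction.
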
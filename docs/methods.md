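# Methods

This note documents the models, estimators, conventions and design
decisions behind `radscan`, and what the simulation-based tests do and do
not establish about real data.

## Data model

Genotypes are diploid, biallelic, stored as alt-allele dosage in {0, 1, 2}
with −1 for missing. SNP sites are grouped into short RAD loci (default
94 bp) by a locus catalog that also records, per locus, the set of
individuals with sequence data. Missingness is locus-level at generation
(an individual that lacks a locus is missing all of its SNPs) but the data
model tolerates site-level missingness, and all downstream statistics use
pairwise/groupwise deletion. Multi-allelic records are dropped at VCF
ingest with a count kept.

Two conventions worth stating explicitly:

* **Minor allele at an exact 50/50 tie.** The globally minor allele is the
  rarer of ref/alt among called individuals; at an exact tie the alt
  allele is designated minor. The tie case is the only place where
  swapping ref/alt labels changes `minor_allele_carrier_count`; the
  property is tested.
* **Apomorphic SNP.** A site is apomorphic when exactly one individual
  carries ≥ 1 copy of the minor allele — the definition is
  individual-based, so a heterozygous singleton and a homozygous singleton
  are treated alike.

## Filtering cascade

Stages run in a fixed order: blacklist → coverage → D1 → D2 → D3. A locus
failing both the SNP-richness cap and the coverage threshold is attributed
to the blacklist stage. "10 or more SNPs blacklisted" and "maximum of 9
SNPs retained" are the same rule, implemented as removal when
`snp_count > max_snps` with `max_snps = 9` by default. The coverage
threshold may be given as an absolute count or as a fraction of
individuals; a fraction converts by ceiling (0.9 of 40 individuals → 36).
D1 orders sites by catalog locus order then offset, and removes columns
that are monomorphic (a possibility after subsetting); D2's random rule
draws uniformly per locus from a generator seeded by the configuration, so
repeat runs are identical; `rule="first"` (lowest offset) is offered for
fully deterministic pipelines. The assembly-parameter criterion —
maximise the number of polymorphic loci under the SNP cap covered in at
least the coverage threshold of individuals — breaks ties toward the
smallest (m, M, n) lexicographically and flags that a tie occurred.

## FST estimators

The scan's default estimator is the two-population Weir–Cockerham θ̂ for
diploid samples, computed from the variance components a (among
populations), b (among individuals within populations) and c (within
individuals), with θ̂ = a/(a+b+c). The per-side inputs are the called
sample size nᵢ, alt frequency p̂ᵢ and observed heterozygote frequency ĥᵢ.
Under reciprocal fixation b and c vanish algebraically, so the
implementation returns exactly 1.0 there rather than the last-bit rounding
of the floating-point ratio. The alternative Hudson-type estimator is

    num = (p̂₁−p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1)
    den = p̂₁(1−p̂₂) + p̂₂(1−p̂₁)

with n counted in alleles. Both estimators:

* are undefined when either side has fewer than `min_called` (default 2)
  called individuals, or when the denominator is zero (both sides
  monomorphic for the same allele);
* may be negative when the between-side variance falls below its sampling
  expectation — values are reported raw and never clamped, and a negative
  value can never exceed a positive threshold;
* are accompanied by per-side sample sizes and frequencies, the allele
  elevated on the ultramafic side (None when frequencies are equal), and a
  reciprocal-fixed-difference flag.

`min_called = 2` exists to prevent single-individual artifacts at sites
where locus dropout has hollowed out one side; the D1 coverage filter
makes such sites rare but not impossible.

## Replicated outlier scan and classification

A locus qualifies for a pair when *any* of its SNPs has F<sub>ST</sub>
strictly above the threshold for that pair ("over 0.5" is read as >, never
≥). A locus is a candidate when it qualifies in at least `min_pairs`
(default 2) of the sister-pair contrasts; the qualifying SNP may differ
between pairs. Contrasts are defined over arbitrary individual sets, so a
side may pool two species. Candidates are classified
`collateral_shared` when one single SNP site qualifies in ≥ 2 pairs with
the same allele elevated on the ultramafic side in each, else
`parallel_distinct` — collateral evolution means the same variant was
recruited across splits (ancestral sorting or introgression), parallel
means the locus was hit repeatedly through different variants.

**Fixed-difference fraction.** The denominator is the set of qualifying
SNPs deduplicated across pairs; a site counts as fixed when it is a
reciprocal fixed difference in at least one pair in which it qualifies.
The complement ("not fixed") is the headline number: a low fixed fraction
indicates soft, possibly polygenic differentiation rather than complete
sweeps.

## Synthetic radiation generator

The generator exists to give every stage a ground truth. Frequencies
evolve down a rooted population tree under the hierarchical
Balding–Nichols model: along a branch with drift intensity c, the child
frequency is Beta(p(1−c)/c, (1−p)(1−c)/c), which preserves the mean and
has variance p(1−p)c. The default topology is a coarse radiation: two
outgroup populations on long branches (c = 0.3) straight from the root,
and a rapid clade with short internal branches (c = 0.02) carrying four
sister pairs whose tips drift at c = 0.1 — star-like structure with most
differentiation on the tip branches. Defaults: 8 diploids per population,
2000 loci of 94 bp, SNPs per locus zero-truncated Poisson(2) capped at 15,
ancestral frequencies Uniform(0.05, 0.95), locus dropout 0.1 per
individual×locus, 50 planted adaptive loci with δ = 0.8 targeting all four
pairs, plus planted SNP-rich loci (10–15 SNPs, paralog mimics) and planted
singleton SNPs.

Selection is modelled as a deterministic post-drift displacement: at a
causal site the ultramafic-side tip frequency moves by +δ/2 and the
volcanic side by −δ/2, clipped to [0, 1]. The scan only ever sees
frequencies, so a displacement isolates exactly the mechanism under test
without committing to a selection coefficient or a sweep model.
`shared_allele` loci displace one causal site in the same direction in
every target pair; `independent_allele` loci displace a different causal
site per pair (such loci are forced to carry at least one SNP per target
pair). Causal sites draw their ancestral frequency from
Uniform(0.2, 0.8) — intermediate-frequency standing variation — because a
±δ/2 displacement applied at an extreme ancestral frequency is annihilated
by clipping on one side, which would model a planted locus that carries no
usable contrast.

What the generator does **not** emulate: linkage between SNPs of one locus
(sites are conditionally independent given the tree, whereas real RAD
SNPs within 94 bp are in near-complete LD), sequencing error,
allele-dropout biased toward heterozygotes, introgression between
non-sister populations, and selection as a dynamic process. Consequently,
passing recovery tests show that the scan and classifier respond correctly
to frequency displacement under drift and dropout — not that the method is
robust to paralogy, allele dropout or LD structure in real libraries (the
blacklist stage addresses paralogy separately).

## Recovery behaviour and a known limitation

At the default conditions (δ = 0.8, tip c = 0.1, 8 diploids/side,
threshold 0.5, ≥ 2 of 4 pairs) the scan recovers ≈ 94 % of planted loci
while flagging ≈ 2 % of neutral loci (10 seeds). Neutral sister-side
F<sub>ST</sub> at c = 0.1 with 8–10 diploids/side occasionally exceeds 0.5
by drift plus sampling noise (≈ 2 % of site×pair combinations), which sets
the neutral flag rate and also bounds the classification accuracy: a
causal site displaced for one pair already qualifies there, so a single
spurious exceedance in another pair with matching polarity flips a planted
`independent_allele` locus to `collateral_shared`. With one causal site
per pair and four target pairs this happens at roughly 10 % of
independent-variant loci (measured ≈ 11 % over 10 seeds at δ = 0.9,
10 diploids/side), while shared-variant loci classify correctly ≈ 98 % of
the time. The asymmetry is intrinsic to threshold-based classification at
these sample sizes, not a property of the implementation; larger samples
or a higher threshold for the shared-site evidence would reduce it.

## Numerical and I/O choices

* Hamming distances between individuals count dosage mismatches under
  pairwise deletion (heterozygotes are a third state, so 0/1, 1/2 and 0/2
  each count one mismatch); normalisation by jointly called sites is the
  default, and pairs with zero jointly called sites are NaN and listed.
  An alternative would be IUPAC-symbol comparison of exported sequences;
  dosage counting was chosen because it treats het/hom differences
  consistently with the genotype model.
* VCF output is minimal v4.2 with GT only; locus id and 0-based offset
  travel in ID (`locus_offset`) and INFO, with CHROM = locus and POS =
  offset + 1, so files remain valid for generic tooling.
* Structure export codes alleles A/C/G/T → 1/2/3/4 with −9 for missing,
  two rows per individual; PHYLIP export uses IUPAC ambiguity codes for
  heterozygotes and N for missing; the Hamming matrix can be written as a
  NEXUS distances block for network software.
* All randomness (simulation, D2 draws) flows through
  `numpy.random.default_rng` seeded from explicit configuration values;
  identical configurations produce byte-identical outputs, which is
  asserted in tests.
* The pipeline writes every stage's outputs before the next stage runs,
  and the run summary embeds the tool version and a SHA-256 hash of the
  semantic configuration (paths excluded), so a summary identifies its
  analysis exactly.

## Problem sizes used in the test suite

Recovery experiments run at 2050 loci × 10 populations × 8 diploids
(sensitivity/specificity, 10 seeds) and 400 loci × 10 diploids per
population (classification, 10 seeds); fixture and round-trip tests use
120–300 loci. These sizes give per-quantity Monte-Carlo standard errors of
about 1–3 percentage points, small enough to compare against the stated
recovery bounds.
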
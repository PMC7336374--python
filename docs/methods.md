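# Methods

## Genetic model

The simulator models a cross between a fully homozygous EMS-mutagenized
line and its non-mutagenized parent. All induced variants are private to
the mutant line and homozygous, so the F1 is heterozygous at every one of
them. One variant is causal for a fully penetrant recessive phenotype:
an F2 individual is phenotypically mutant iff it carries two mutant
alleles at that locus, which yields the classical 3:1 segregation.

Meiosis uses a no-interference crossover model with a uniform genetic
map. Crossover counts per chromosome are Poisson in the genetic length,
so the recombination fraction between loci at map distance *d* Morgans is
Haldane's r = (1 − e^(−2d))/2. Internally, gamete haplotypes at the
marker loci are sampled as a Markov chain along each chromosome — initial
phase Bernoulli(1/2), phase switch between adjacent markers
Bernoulli(r(d)) — which is distributionally identical to explicit
crossover simulation at the markers (the switch indicator is the parity
of a Poisson count on a disjoint interval) and fully vectorizable. Tests
verify the empirical recombination fraction against the closed form.

Bulk sequencing is modelled at the read-count level: per site and bulk,
total depth is Poisson(mean depth) and each read carries the mutant
allele with probability q(1−e) + (1−q)e, where q is the realized bulk
allele frequency and e a symmetric per-read miscall rate. Read alignment,
genotype likelihoods and FASTQ synthesis are deliberately out of scope;
allele counts are the unit of exchange.

### Key expectations (all oracle-checked in the tests)

| quantity | value |
|---|---|
| MP-bulk frequency at recombination fraction r from the causal locus | 1 − r |
| WP-bulk frequency at r | (1 + r)/3, monotone from 1/3 (r=0) to 1/2 (r=1/2) |
| unlinked site, either bulk | 1/2 |

The 1/3 arises from the WP class composition AA : Aa = 1 : 2:
(0·1 + 1·2)/(2·3). `expected_wp_index` computes it from the class
weights rather than hard-coding it.

## Default parameters

| parameter | default | why |
|---|---|---|
| recombination rate | 4 cM/Mb | rice-like order of magnitude; one knob, closed-form Haldane oracles |
| EMS spectrum | 100% G:C→A:T | EMS chemistry; configurable fraction |
| penetrance / phenotyping error | 1 / none | phenotype treated as exact |
| F2 population | 208, classes free to segregate | bulks are topped up from extra simulated batches if a class is short; a fixed-class option reproduces a particular observed draw (e.g. 164 WP : 44 MP) |
| bulks | 30 + 30 individuals | the mapping design emulated |
| depth, error | Poisson mean 30 per bulk, e = 0.005 | short-read bulk sequencing at ~30× |
| window / step | 1 Mb / 1 kb, anchored at 0, half-open | standard sliding-window smoothing of per-site indices |
| region rule | window mean ≥ 0.9, ≥ 10 consecutive windows, overlapping runs merged | literal mean = 1 is brittle at finite depth with nonzero error |
| depth filter | ≥ 10 reads in both bulks | indices from fewer reads are sampling noise |
| MP criterion | index ≥ 1.0 − 0.1 | at 30× and e = 0.005 a literal 1.0 rejects ~14% of true causal sites (0.995^30) |
| WP criterion | band [0.1, 0.6) AND exact binomial test vs 1/3 at α = 0.01 | calibrated; see below |
| ranking | ascending \|WP index − 1/3\|, ties by genomic coordinate | the causal pattern is the WP index nearest 1/3 |

## Calibration of the WP criterion

The WP index of the true causal site is noisy for two stacked reasons:
the realized bulk composition (the number of heterozygotes among the 30
sampled WP plants is Binomial(30, 2/3), so the true bulk frequency has
SD ≈ 0.043) and read sampling at ~30× (SD ≈ 0.086). Their combination
gives the causal site's WP index an SD of ≈ 0.096 around 1/3, so any
band tight enough to read as "exactly about 1/3" misses a material
fraction of true causal sites: a band of [1/6, 1/2) with a binomial test
at α = 0.05 retains a true causal site with probability 0.904
(`wp_retention_probability`, an exact computation over the
composition × depth × read mixture, covered by a test).

The shipped defaults — band [0.1, 0.6) with α = 0.01 — retain a true
causal site with probability 0.982 at the design depth while still
rejecting sites fixed in both bulks (index ≈ 1; leakage < 1e-12).
Unlinked sites (index ≈ 1/2) are excluded almost entirely by the MP
filter (an unlinked site reaches MP index ≥ 0.9 at 30× with probability
≈ 4e-6), so the band's upper bound does not need to separate 1/3 from
1/2 on its own. The binomial consistency test uses the two-sided
minimum-likelihood convention (sum of outcomes no more probable than the
observed one); note that at very high depth it becomes sensitive to the
bulk-composition deviation itself, so retention is not monotone in
depth — another reason the band and the test are combined.

When an index table carries no read depths (e.g. a published candidate
table), the depth filter and the consistency test are not evaluable and
are treated as non-binding; the band, MP, region and coding-effect
filters fully determine the outcome.

## Coding-effect annotation

Gene models are strand-aware spliced CDS interval sets (read from GFF3 +
FASTA, or constructed synthetically). Region classes follow annotator
convention with precedence exonic > UTR > intronic > upstream/downstream
(1 kb flank by default) > intergenic; ties across genes go to the nearest
transcript start, then to the smaller gene id. Substitution effects are
computed by codon replacement under the standard genetic code and checked
against a whole-CDS re-translation oracle; indel effects are computed by
rebuilding the mutated CDS and re-translating from codon 1. Frameshift
effects report both the codon containing the edit point and the first
codon whose amino acid actually changes, because the two differ in
general and published frameshift positions do not always state their
convention; the premature-stop field is the first stop codon in the
mutated frame. In-frame indels are categorized nonsynonymous (protein
altered, frame preserved). Splice-site effects and organellar codes are
out of scope.

The synthetic causal gene model anchors its reading frame so the causal
variant falls on the first base of a codon whose EMS substitution is
nonsynonymous (CTC→TTC Leu>Phe for C→T, GAT→AAT Asp>Asn for G→A); other
simulated variants that happen to fall inside the CDS keep their
reference bases in the generated sequence and are annotated honestly.

## What the simulator does and does not emulate

It emulates the design quantities that drive the statistics: segregation,
linkage decay around the causal locus, bulk composition noise, and
read-sampling noise with a miscall rate. It does not emulate alignment
artefacts, mapping bias, copy-number variation, residual heterozygosity
in the mutant parent, selfing-generation structure, variant-calling
errors, or non-uniform recombination. Passing tests therefore show that
the statistics and decision rules behave as designed under the stated
model, not that the pipeline is robust to every artefact of real
resequencing data.

## Problem sizes used in the shipped checks

The test suite and acceptance script use desk-scale designs chosen to
make sampling error small relative to the tested effects: 100,000 F2
individuals for the segregation ratio, 60,000 individuals per
recombination fraction for the linkage laws (3-SE bounds), 500 SNPs over
5 Mb for the window oracle, and 100 seeded end-to-end runs at the default
design for causal-SNP recovery (expected retention 0.98; required ≥ 95).

## Numerical and degenerate-input choices

Zero-depth sites are emitted by the simulator and carry undefined (NaN)
indices; the depth filter is the single place coverage decisions happen.
Windows with no defined member index carry an undefined mean. Unsorted
input tables are rejected rather than silently sorted (except by the
file readers, which sort and validate on ingest). All randomness flows
from one `numpy` Generator per run, so every artifact is byte-identical
for a given (config, seed).
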
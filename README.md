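# mutmaplite

Bulked-segregant SNP-index mapping for EMS-induced recessive mutants
(MutMap-style), with a forward cross simulator, sliding-window candidate
region detection, a dual-bulk causal-SNP filter, and coding-effect
annotation.

## The problem and the method

A recessive mutant recovered from an EMS-mutagenized line (the motivating
case is a rice floral-organ mutant) is crossed back to its non-mutagenized
parent. Every induced SNP segregates in the F2, and two DNA bulks are
sequenced: plants showing the **m**utant **p**henotype (MP) and plants
**w**ithout it (WP). For each SNP the **SNP index** of a bulk is the
fraction of reads carrying the non-reference (mutant-line) allele:

    SNP index = alt reads / (ref reads + alt reads)

Under a monogenic, fully penetrant recessive model:

* MP bulk at the causal SNP: all individuals are homozygous mutant, so the
  index is 1 (exactly 1 when sequencing error is zero).
* WP bulk at the causal SNP: the class is AA : Aa = 1 : 2, so the expected
  index is 2a / [A + A + 2(A + a)] = **1/3**.
* Unlinked SNPs: expectation 1/2 in both bulks.
* A linked SNP at recombination fraction *r* from the causal locus has
  expectation 1 − *r* in the MP bulk and (1 + *r*)/3 in the WP bulk
  (both laws are verified against an enumeration oracle in the tests).

The pipeline smooths MP-bulk indices with a sliding window (1 Mb window,
1 kb step), detects the candidate region (window mean ≥ 0.9), and then
filters single SNPs by the dual-bulk criterion — MP index 1 (within an
error tolerance) **and** WP index about 1/3 (a calibrated band plus an
exact binomial consistency test) — requiring an exonic nonsynonymous
effect and ranking candidates by |WP index − 1/3|.

Because no real sequencing accompanies the package, a forward simulator
generates the study design from first principles: EMS variants (G:C→A:T
biased), F1 heterozygous everywhere, F2 meiosis with a no-interference
(Haldane) crossover model, recessive phenotyping, bulks of 30, and
Poisson-depth / binomial-allele read sampling.

## Worked example

The package ships the published candidate table of the motivating study:
ten SNPs on chromosome 12 with MP index 1. Replaying the filter cascade:

```
$ mutmaplite table1-demo
SNPs with MP index 1:        10
in 23-27 Mb region:          6
nonsynonymous (exonic):      2
pass dual-bulk WP criterion: 1
candidate: chr12:26056055 (WP index 0.35)
```

Ten SNPs have MP index 1; six lie in the 23–27 Mb candidate region; two
are exonic nonsynonymous; and the WP criterion (index about 1/3) leaves a
single candidate — the SNP at 26,056,055 with WP index 0.35, the causative
C→T substitution (CDS position 745, codon 249, Leu→Phe).

A fully simulated run at the default study design (30 Mb chromosome,
300 EMS SNPs, bulks of 30, ~30× depth, 0.5% read error):

```
$ mutmaplite run-all --seed 1 --out-dir out/
seed = 1
candidates = 1
top candidate = chr1:14356528 (WP index 0.226)
```

Here the simulator's ground truth places the causal SNP at chr1:14356528;
the pipeline recovers it as the unique top-ranked candidate (its WP index,
0.226, is one binomial draw around the expected 1/3). `out/` contains the
allele counts (TSV + simplified VCF), per-SNP indices, the window series
for both bulks, candidate regions (BED), the ranked candidate report with
all filter verdicts, the simulator truth, and a seed-stamped run log.

The same steps are available piecemeal (`simulate`, `index`, `windows`,
`candidates`, `annotate`) and as library functions (`mutmaplite.run_pipeline`,
`mutmaplite.candidate_snp_filter`, ...).

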
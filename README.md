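# salmhc

Genotyping and population-diversity analysis of the major histocompatibility
complex (MHC) in Atlantic salmon (*Salmo salar*): the single classical class I
locus *UBA* and the tightly linked class II pair *DAA*/*DAB*. The package is
aimed at molecular ecologists comparing immune-gene diversity between wild
river populations and escaped farmed salmon from amplicon-sequencing data.

It covers the full path from reads to population statistics:

* **Amplicon genotyping** — primer demultiplexing with zero mismatches,
  FLASH-style paired-read merging, abundance ranking of unique merged reads,
  selection of the top candidates above a 1% abundance floor, 0–2 nt frame
  trimming, and calling of at most two alleles per single-copy locus.
* **Allele nomenclature** — Smith–Waterman comparison (EMBOSS `water` default
  scoring) against a reference library of `Sasa-UBA*13:01`-style names. A new
  sequence differing from its closest match by more than T amino acids
  (T = 4 for *UBA*, 3 for *DAA*/*DAB*) opens a new two-digit family; smaller
  non-synonymous differences extend the family with a four-digit number;
  synonymous variants get a six-digit extension; longer but otherwise
  identical sequences get an `_L` suffix. *UBA* alpha-1 domains are assigned
  to the ancient cross-species lineages I–VIII by Jukes–Cantor distance,
  d = −(3/4)·ln(1 − 4p/3), to per-lineage exemplars.
* **Haplotypes** — parsimony phasing of unphased *DAA*×*DAB* genotypes
  (homozygote anchoring, then iterative resolution by the known-haplotype
  set, then frequency parsimony), with flags for singleton combinations and
  for alleles that segregate with multiple partners (1 aa apart → point
  mutation; more → recombination/gene conversion).
* **Diversity statistics** — observed heterozygosity H_O; unbiased gene
  diversity H_E = N/(N−1)·(1 − Σ p_i²); rarefied allelic richness
  A_R(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)] on allele copies; Nei-style
  multi-population F_ST; a seeded Monte-Carlo permutation test for
  heterozygote deficit (mid-p); homozygosity rates.
* **Richness extrapolation** — exact rarefaction curves; matching of the
  observed allele-accumulation curve to hypothetical populations with
  increasing allele numbers K; extrapolated allele counts at larger sample
  sizes with bootstrap intervals; Shannon–Weaver diversity H′ = −Σ p ln p;
  leave-one-third-out accumulation bootstraps; Michaelis–Menten saturation
  fits D(n) = D_max·n/(K_half + n) with leave-half-out bootstrap intervals.
* **Synthetic data** — a first-class generator for allele libraries (with
  the class I hallmark of alpha-1 lineages shuffled onto different alpha-2
  backgrounds), skewed frequency spectra, genotypes with controllable
  homozygote excess F, and error-bearing paired reads with a truth manifest,
  so the whole pipeline is testable without any sequence download.

## Worked example

Simulate one population at a class I locus with 25 alleles and a homozygote
excess of F = 0.2, then summarize it:

```sh
$ salmhc simulate --locus UBA --k-true 25 --n 40 --inbreeding-f 0.2 --seed 7 --outdir demo
$ salmhc diversity --genotypes demo/genotypes.csv --locus UBA --out demo/summary.tsv --seed 7
$ cat demo/summary.tsv
population  locus  N_ind  N_all  Ho     He      AR      HWE_p  homozygosity
sim         UBA    40     15     0.625  0.886   11.54   0.0    0.375
```

Of the 25 true alleles, 15 were carried by the 40 sampled fish. Observed
heterozygosity (0.625) sits far below the gene diversity expected under
random mating (0.886) — the simulated homozygote excess — and the
permutation test rejects Hardy–Weinberg equilibrium (p ≈ 0). Rarefied
allelic richness standardized to 17 individuals is 11.5 alleles.
Extrapolating the allele count to a tenfold sample:

```sh
$ salmhc rarefy --genotypes demo/genotypes.csv --locus UBA --n-prime 400 --seed 7 --out demo/extrap.json
[salmhc] rarefy: UBA n=40->400: 15 -> 22.0 alleles (13.2-28.6)
```

The accumulation-curve match estimates a population allele number of
K ≈ 23, so roughly 7 additional rare alleles are expected to surface in a
sample of 400 fish (the truth here is 25).

Other subcommands: `genotype` (FASTQ pairs → genotype table), `classify`
(name candidate sequences against a library), `haplotype`, `accumulate`
(bootstrap curves and saturation fits) and `report`.

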
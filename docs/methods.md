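# Methods

This note documents the models, estimators and numerical choices behind
`salmhc`, and what the synthetic data do and do not establish about real
amplicon data.

## The genotyping model

Each locus (*UBA*, *DAA*, *DAB*) is single-copy, so a diploid carries at
most two alleles. The pipeline assumes reads have been quality- and
adapter-trimmed upstream; within the package the only read-level filter is
a mean-Phred floor (default Q20) and a length floor. Stages:

1. **Primer demultiplexing** with zero mismatches: a pair is assigned to a
   primer pool iff read 1 starts exactly with the pool's forward primer and
   read 2 with its reverse; primers are stripped. Exact matching is strict
   (a primer-region sequencing error discards the pair) but makes pool
   assignment unambiguous; with three *UBA* forward primers partitioning
   the alpha-1 lineages, cross-pool bleed would otherwise mix lineages.
2. **Merging**: read 2 is reverse-complemented and slid along read 1; among
   overlaps of at least 10 nt with mismatch density ≤ 0.25, the one with
   the most matching bases wins, and disagreeing overlap bases take the
   higher-quality call (read 1 on ties). Only suffix–prefix ("innie")
   overlaps are considered; 3′ read-through past the opposite primer is
   assumed removed by the upstream trimming step.
3. **Collapse and selection**: merged reads are grouped by exact string
   equality, ranked by count (count ties broken lexicographically so output
   never depends on input order), and at most the top 5 sequences holding
   ≥ 1% of the pool's merged reads survive. The 1% floor is the permissive
   end of the 1–2% range used in practice, so weakly amplified second
   alleles survive; both knobs are configurable.
4. **Frame adjustment**: 0–2 nt are trimmed from each end (9 combinations);
   the trim whose frame-0 translation has no internal stop and the longest
   peptide wins, ties preferring the smallest offsets. Candidates whose
   every trim contains an internal stop are rejected as non-coding.
5. **Classification and calling**: each surviving candidate is mapped to
   the *closest* library allele (Smith–Waterman, see below), so
   sequencing-error variants of one allele pool their read support.
   Candidates are unified across primer pools; more than two distinct
   alleles keeps the best-supported two and flags `excess_alleles`; a
   single allele is called homozygous, flagged `low_support` when the
   merged read depth is below 50 (the depth floor is a package choice —
   upstream tools are silent on one); no candidates flags
   `missing_genotype`.

Naming novel alleles is deliberately separated from genotyping: the
`assign_name` decision table would mint a new six-digit name for every
1-nt sequencing-error variant, so it is reserved for curated candidates
(the `classify` subcommand), mirroring how new alleles are verified
manually before database submission.

## Alignment and nomenclature

Alignments are Smith–Waterman local alignments with the EMBOSS `water`
default scoring: nucleotide match +5 / mismatch −4, protein BLOSUM62, gap
open 10, extend 0.5. Identity and similarity are percentages over
alignment columns. Two consequences worth knowing: a disagreeing terminal
column is clipped from the optimal local alignment (so a sequence one
substitution away at its very end can still show 100% identity — percent
ties are therefore broken by alignment score, which favours the longer
perfect alignment); and between unrelated sequences a short local match
can report a deceptively small amino-acid difference, which is why
closest-match ranking goes by identity and score first.

The naming decision table, relative to the closest reference: identical
nucleotides → existing name; longer sequence containing the reference →
`_L` suffix; synonymous difference → next six-digit extension;
1…T amino-acid difference → next four-digit number in the matched family;
more than T → new two-digit family (T = 4 for *UBA*, 3 for class II).
Amino-acid differences count substitutions plus gap columns over the
locally aligned peptide span (gap treatment is a package definition; the
field convention does not specify one). Differences are measured on the
sequenced fragment only; allele pairs known to differ only outside the
fragment remain unresolvable by design and must be merged by
configuration. Numbers are allocated first-come; callers sort candidates
by (descending read support, name) so reruns reproduce identical names.
`_L` variants and six-digit siblings count as the same allele in every
statistic.

Alpha-1 lineage assignment computes Jukes–Cantor distances,
d = −(3/4)·ln(1 − 4p/3), over the aligned ungapped columns (≥ 50 required)
against one exemplar per lineage; p ≥ 0.75 is reported as saturated, a
best-versus-second margin under 0.01 flags ambiguity. This replaces a full
maximum-likelihood phylogeny: for assignment to deeply divergent,
well-separated lineages, nearest-exemplar distance is sufficient and
orders of magnitude cheaper.

## Haplotype phasing

*DAA* and *DAB* sit ~3 kb apart and recombine rarely, so phase is inferred
by parsimony rather than likelihood (sample sizes here would not support
EM): individuals homozygous at either locus are unambiguous and seed the
known-haplotype set; double heterozygotes are resolved iteratively when
exactly one of their two phasings is supported by a known haplotype; the
remainder fall back to most-frequent-haplotype parsimony (ties by name)
and are flagged `inferred`. Haplotype counts conserve copies (two per
resolved individual). Consistency flags: count-1 combinations are
`singleton` (possible typing artefacts); an allele carried by two or more
haplotypes each seen at least twice marks them `conflicting`, annotated
`point_mutation` when the partners differ by one amino acid and
`recombination_or_conversion` otherwise. As a cross-check, *DAA* allelic
richness can be recomputed from *DAB*-linked haplotypes; the two counts
agree whenever every *DAA* allele rides a phased haplotype.

## Diversity statistics

* H_O: fraction of called individuals whose alleles differ. Individuals
  missing a call at a locus are excluded from that locus entirely, keeping
  copy totals even.
* H_E = N/(N−1)·(1 − Σ (N_i/N)²) on allele copies — the probability that
  two copies drawn without replacement differ (hence counts (1,1) give 1).
* A_R(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)], hypergeometric rarefaction on
  allele copies, evaluated with log-gamma functions for stability; the
  diploid standard size of 17 individuals means g = 34 copies. A_R(N)
  equals the observed allele count exactly.
* F_ST: Nei/Chesser-corrected G_ST with unweighted population means and the
  harmonic mean sample size; the observed-heterozygosity term of the full
  estimator is omitted because the inputs are allele-copy counts (under
  random pairing of copies its expectation is absorbed by the 2ñ/(2ñ−1)
  factor). Monomorphic-everywhere input is reported as undefined, not 0.
* Hardy–Weinberg: the observed copies are randomly re-paired into diploids
  (≥ 10⁴ seeded permutations); the statistic is the homozygote count and
  the p-value is one-sided toward heterozygote deficit. The **mid-p**
  convention (ties counted half) is used because the plain fraction is
  conservative for a discrete statistic and visibly non-uniform under the
  null; mid-p calibrates to uniformity (KS check in the test suite).

## Richness extrapolation and saturation

The observed accumulation curve is the exact rarefaction curve of the
sample (expected distinct alleles at g = 2, …, 2n copies; ~25 grid
points). Hypothetical populations with K alleles are generated from a
fitted frequency-spectrum model; the expected accumulation curve of a
multinomial sample from frequencies q is analytic,
A(g) = Σ_j [1 − (1 − q_j)^g]. The matched K minimizes the L2 distance
between observed and hypothetical curves, ties preferring smaller K.

Two spectrum models are provided. The default is the geometric
rank-frequency family p_i ∝ r^i with r fitted jointly on a grid — the
match is then fully deterministic. A Gaussian kernel on observed log
frequencies is available as `model="kernel"`; it is only calibrated near
saturation, because a kernel fitted to observed frequencies carries no
mass below the sample's detection limit and therefore understates the
rare-allele tail of skewed spectra (measured: median matched K ≈ 37 when
the truth is 69).

Extrapolated richness at n′ > n individuals is
N_obs + [A(2n′) − A(2n)] under the matched population — continuous in n′
and exactly N_obs at n′ = n. The interval is a parametric bootstrap:
samples of the observed size are redrawn from the matched population,
re-matched (cheap, against a precomputed curve bank) and re-extrapolated;
the 2.5/97.5 percentiles form the band.

**Identifiability limits.** Alleles whose population frequency is well
below 1/(2n) are invisible at sample size n, and no accumulation-based
procedure can count them: e.g. under a geometric spectrum with r = 0.7,
populations with 30 and with 69 alleles produce identically distributed
samples at n ≤ 45, and their allele numbers cannot be told apart even in
the median. Matched K values should be read as estimates of the
*detectable* allele number; the recovery study in the test suite documents
exactly which configurations are and are not recoverable.

Accumulation bootstraps follow the leave-one-third-out scheme (1000
iterations by default, seeded); a nested subsample grid yields smooth
curves for fitting. Michaelis–Menten saturation curves
D(n) = D_max·n/(K_half + n) are fitted by nonlinear least squares with
multi-start initialization from the Lineweaver–Burk linearization
(1/D regressed on 1/n) plus perturbed starts, parameters bounded positive;
D_max confidence bands come from refitting on random half-subsets of the
points ("leave-half-out").

## The synthetic-data generator

The generator emulates the features of the study system that the
statistics depend on:

* **Libraries.** Class I alleles are concatenations of an alpha-1 domain
  (236 nt, the standard alpha-1 alignment frame) and an alpha-2/downstream
  tail; alleles sharing a lineage carry the identical alpha-1 founder on
  distinct alpha-2 backgrounds, reproducing the intron-mediated
  domain-shuffling signature. Lineage founders diverge from a common root
  at 0.30 substitutions/site, alpha-2 backgrounds and class II alleles at
  0.08 — giving within-locus identities of roughly 85–100% for class II
  and down to ~60% between class I lineages. All sequences are built
  codon-safely (no frame-0 stops), and the alpha-1/alpha-2 junction is
  constrained so any alpha-1 recombines onto any alpha-2 without creating
  a stop. The alpha-2 tail is 16 nt, which keeps the class I insert
  (252 nt) on the same read-length scale as the class II insert (261 nt):
  with one-read-scale amplicons, the error-free template remains the modal
  merged sequence at realistic per-base error rates, which is what makes
  abundance-threshold genotyping work — for both the simulated and the
  real assay design.
* **Spectra.** Geometric p_i ∝ r^i (r = 0.8–0.9 reproduces the observed
  gene diversities of ~0.89–0.95 and a long rare tail with
  population-private alleles) or symmetric Dirichlet.
* **Genotypes.** With inbreeding-style parameter F, an individual is
  autozygous with probability F: P(hom i) = p_i² + F·p_i(1−p_i),
  P(het i,j) = 2·p_i·p_j·(1−F); marginals are unbiased for p. F ≈ 0.2
  reproduces the class I homozygote excess; class II is simulated at
  F = 0.
* **Reads.** Amplicon = forward primer + allele + reverse-complemented
  reverse primer; mates are the amplicon's first L bases and the first L
  of its reverse complement, truncated at the opposite primer boundary
  (read-through removal is upstream trimming's job). Substitution errors
  are i.i.d. per base with a constant matching Phred quality; depth
  defaults to 500 pairs per individual per locus (a test-power choice —
  real depths are not standardized), split binomially between a
  heterozygote's alleles. Each individual draws from an independent
  substream keyed by a hash of its ID, so any subset of a cohort
  regenerates identically.

What the generator does **not** emulate: indels and chimeric reads
(quality-filtered merged amplicon data are substitution-dominated),
quality-score trajectories, index hopping, and PCR amplification bias
beyond the binomial allele split. Passing tests therefore demonstrate the
pipeline's statistical logic, not robustness to indel-rich or
chimera-rich libraries.

## Problem sizes in the validation suite

The test suite and the acceptance script size their simulations for
single-CPU runs: genotyper recovery uses 20 seeds × 10 individuals at
depth 500 and 1% error; Hardy–Weinberg calibration uses 500 null data sets
with 10⁴ permutations each; allele-number recovery uses 9 seeds per
configuration of the (K, r, n) grid; the synthetic study in
`scripts/acceptance.py` uses the real sample-size layout (eight rivers,
17–52 wild fish each, 88 escapees). All randomness flows from explicit
seeds; reported intervals are percentile-based.
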
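# Methods

This note records the models, estimators and design choices behind
`cottonpop`, in the order the pipeline runs them.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic allotetraploid panel

All statistics in this package are functions of population allele
frequencies, so the generator is a Balding–Nichols frequency hierarchy
rather than a coalescent simulator: it reproduces exactly the moments the
downstream estimators consume, runs in seconds, and makes planted truth
trivially available.  The hierarchy is

1. ancestral frequency `p ~ Uniform(0.05, 0.95)` per site;
2. species drift: each species' frequency `~ Beta(p(1−F)/F, (1−p)(1−F)/F)`
   with `F = F_species`; a fraction `fixed_diff_fraction` of sites is
   forced to alternate fixation (1, 0)/(0, 1) between the species — the
   "nearly fixed interspecific" class;
3. group drift: G. hirsutum races and cultivars, and G. barbadense
   cultivars, drift further from their species frequency with group-level
   F values; the outgroup drifts directly from `p` with `F_outgroup`;
4. genotypes are `Binomial(2, freq)` dosages, masked at `missing_rate`.

Tetraploidy is structural: A and D subgenomes are separate chromosomes
(reads are assumed uniquely assigned to one subgenome before genotyping),
so each site is an ordinary diploid biallelic locus.  The desk-scale layout
is 4 chromosomes (A01, A02, D01, D02) of 2 Mb with full-length homoeologous
A↔D correspondences.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| panel sizes | 33 races / 52 Gh cultivars / 52 Gb cultivars / 10 outgroup | the real panel's group sizes |
| `fixed_diff_fraction` | 0.3 | yields ≈ 34–35% nearly fixed sites among common SNPs, the observed share |
| `F_species` | 0.1 | with the fixed differences, joint best match to the observed nearly-fixed share; see F_ST caveat below |
| `F_race` / `F_cultivar` | 0.25 / 0.75 | expected diversity ratio (1−F_c)/(1−F_r) = 1/3 ≈ the observed 34% cultivar/race bottleneck; cultivar drift is triple race drift |
| `F_barbadense` | 0.25 | modest cultivar-level drift |
| `F_outgroup` | 0.8 | a far outgroup that roots every tree |
| `snp_density` | 14 /kb | sets realized race diversity at π ≈ 0.002 per bp, the observed level, so windows sit above the scan's 0.001 masking floor; the model's per-site heterozygosity is lower than the empirical one, and density compensates |
| `missing_rate` | 0.068 | the panel's reported missing-call rate |

Planted features: `plant_sweeps` redraws cultivar genotypes inside target
windows from near-fixed frequencies, keeping just enough residual
minor-allele sites (MAF 0.05) to land the race/cultivar ratio at the
configured target in expectation; `plant_introgressions` redraws recipient
genotypes inside a block from the empirical donor-species frequencies;
`plant_admixture` redraws a target group genome-wide from the mixture
`α·f_A + (1−α)·f_B`.  Every stochastic operation emits a truth record.

### What the generator does not emulate

No linkage beyond block-level copying (no recombination map), no mutation
model or sequencing error, no genotype-likelihood uncertainty, no
paralog/repeat artifacts, and the drift hierarchy cannot jointly match all
published summary statistics: with the group drift required by the
bottleneck ratio, realized species-level Hudson F_ST is ≈ 0.70, above the
reported 0.63–0.65, because group drift adds between-species frequency
variance the estimator correctly counts.  Passing tests therefore
demonstrate correctness of the estimators and recovery of planted signals
under a realistic frequency structure — not robustness to read-level
artifacts of real data.

## Filtering cascade

Order is fixed: non-singleton → MAF/missing → spacing; each step only
removes sites.  Allele frequency is alt-allele count over called-allele
count throughout (missing calls leave the denominator).  The non-singleton
threshold defaults to "alt present in ≥ 2 accessions" (the definition the
reported SNP set satisfies; the source describes it once as "more than
two", and the threshold is a parameter for that stricter reading).  The
MAF/missing rule is applied over all accessions, strict inequalities on
both sides.  The spacing filter repeatedly takes the closest conflicting
pair (leftmost on ties) and deletes one member uniformly at random,
seeded; the survivor set is verified ≥ 10 bp spaced by a brute-force scan
in the tests.

## Estimators

- **π**: per-site unbiased heterozygosity `2p̂(1−p̂)·n/(n−1)` (n = called
  alleles) summed over variant sites, divided by the full window length —
  unsequenced positions are assumed monomorphic.  Equivalent to mean
  pairwise allele differences, which is the oracle used in tests.
- **F_ST**: Hudson's estimator, per-window as ratio of sums
  `Σ[(p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1)] / Σ[p₁q₂ + p₂q₁]`; robust to
  unequal sample sizes, unbiased under identical populations (verified on
  split-half nulls).
- **Ka/Ks**: NG86 site counting per codon (each of the 9 single-base
  mutations contributes 1/3 site; mutations to stop count as
  nonsynonymous), ratio of SNP-class densities `(N/Nsites)/(S/Ssites)`.
  No multiple-hit correction: the quantity is a polymorphism-class ratio,
  not a divergence rate.
- **LD**: squared Pearson correlation of unphased dosages,
  pairwise-complete over missing calls, binned by physical distance.
- **Simple matching distance**: 1 − matches/jointly-called over dosage
  states {0, 1, 2}; a metric on complete data; pairs with no jointly
  called site are flagged.
- **NJ**: classical Saitou–Nei with the lexicographically-first minimal-Q
  pair joined on ties (determinism); branch lengths not clamped, so
  additive matrices are reproduced to machine precision (tested to 1e-9).
- **PCA**: genotype column centered by 2p̂ and scaled by √(p̂(1−p̂));
  missing dosages mean-imputed (zero after centering); eigendecomposition
  of the accession covariance; sign fixed by making the largest-magnitude
  coordinate positive per component.

## Sweep scan

Windows (100 kb) with diversity < 0.001 in *both* races and cultivars are
masked out of the ratio track.  A window with π_cultivar = 0 but
qualifying π_race gets a +∞ ratio (reported; sorts above any finite
value) — the synthetic generator can produce exact zeros even though the
largest published signal is finite.  Regions are maximal runs of directly
adjacent windows with ratio > 25 (strict, matching the published
threshold); a masked or sub-threshold window breaks a run — the simplest
deterministic merge rule.  The permutation null reshuffles race/cultivar
labels with group sizes preserved and records the per-window exceedance
fraction (the direct reading of a per-window false-positive rate, rather
than a max-statistic).  Homoeologous pairing transfers a sweep interval
linearly through the A↔D homoeolog map and looks for windows with ratio
above a softer threshold (default 15) on the partner subgenome.  QTL
"overlap" is strict half-open interval intersection (zero flank by
default, configurable) since no flank distance is defined for it.

## Introgression calling

Per 1-Mb block: simple-matching distances → NJ → root on the outgroup →
core clades.  The core clade of species S is the smallest rooted clade
containing ≥ 90% of S's accessions (configurable); an accession of the
other species inside S's core is "placed in S", and a block whose two
core clades share leaves is unresolvable and contributes no calls.  The
90% tolerance bounds how many migrants a species of size k can shed:
⌈0.9k⌉ must remain placeable, which matters for small synthetic panels.
One event is emitted per (block, direction) with ≥ 2 placed accessions;
direction follows the recipient (an accession carrying the other species'
haplotype sits in the donor's clade).  Same-block support is required;
nearby blocks are not merged.

### Direction/subgenome bias tests and the published p-values

The observed direction counts are tested against a balanced expectation in
the 2×2 table `[[n₁, n₂], [E, E]]`, `E = round((n₁+n₂)/2)`.
`direction_bias_test` returns both

- `p_fisher` — the two-sided Fisher exact p (point probabilities ≤ the
  observed one, summed over the hypergeometric), verified in the tests
  against an exhaustive enumeration oracle; and
- `p_chi2` — the Pearson chi-square p without continuity correction on the
  same table.

For the published counts these differ: (265, 119) gives Fisher
p = 1.09e-07 but chi-square p = 8.04e-08, and (250, 134) gives 3.05e-05 vs
2.29e-05.  The values printed in the original analysis match the
chi-square to four significant figures, not the exact test, so the
chi-square is reported by `scripts/acceptance.py` as the faithful
reproduction of that computation, with the exact values alongside.

## f3 three-population test

`f3(C; A, B) = Σ[(c−a)(c−b) − ĥ_c/(2n_c)] / Σ ĥ_c` over sites, with
`ĥ_c = 2c(1−c)·n_c/(n_c−1)` the unbiased target heterozygosity and `n_c`
the called allele count — the standard finite-sample-corrected estimator
normalized by target heterozygosity.  The correction term makes the
numerator unbiased for (c−a)(c−b) under binomial sampling of the target.
Standard error comes from a delete-one jackknife over contiguous site
blocks (≥ 20 blocks required; block size defaults to the 1-Mb analysis
blocks when driven from the pipeline), `Z = f3/SE`.  Under pure drift f3
is positive; a significantly negative value indicates the target is
admixed between populations related to the two sources.

## Expression rules

Tissue specificity: for each gene and focal tissue, the two-sided 95%
t-interval of the other tissues' FPKM values; the default is the
prediction-style interval `m ± t·s·√(1 + 1/n)` (the interval for one new
observation), with the tighter mean interval `m ± t·s/√n` available via a
flag — the published rule names the t distribution but not the interval
type.  A degenerate interval (zero variance among reference tissues) flags
any differing focal value.  Domestication contrast: per-gene Fisher exact
test on `[[c_dom, T_dom−c_dom], [c_wild, T_wild−c_wild]]` read counts,
called at p < 0.05 and library-normalized fold change > 2, direction
recorded.  FPKM quantification from reads is upstream of this package.

## Numerical and engineering choices

- Internal coordinates are 0-based half-open everywhere; VCF/GFF are
  1-based at the I/O boundary only.  Multiallelic VCF records are dropped
  by default (biallelic analysis), with an optional split mode.
- All randomness flows from explicit integer seeds; the pipeline derives
  named per-stage substreams by hashing `(master_seed, stage_name)`, so
  every stage is independently reproducible and manifests carry SHA-256
  checksums of every artifact.
- Problem sizes: the default desk-scale run (4 × 2 Mb, 14 SNPs/kb, 147
  accessions, 200 permutations, 8 NJ trees of 147 taxa) completes the full
  domestication + introgression pipeline in well under a minute on one
  core; the test suite's Monte-Carlo loops (10–20 seeds per claim) were
  sized to keep the whole suite around three minutes.
- Known limitations: species-level F_ST runs high at the default drift
  configuration (above); the spacing filter's random thinning means
  downstream site sets are seed-dependent; block-jackknife SEs assume
  weak dependence between blocks, which the generator satisfies by
  construction (no long-range linkage).
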
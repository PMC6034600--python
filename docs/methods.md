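# Methods

This note records the statistical model behind each stage of `xstrkit`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Data model

An X-STR genotype table holds one row per individual with a sex annotation.
Validation enforces the X-chromosomal constraint: exactly one allele per
locus for males (a duplicated label in a male cell is collapsed; two
distinct labels are an error naming the offending samples), an unordered
pair for females (phase is unknown, so pairs are stored sorted). Allele
labels are repeat counts with an optional microvariant suffix ("25.1" = 25
repeats + 1 base) and are kept as exact integer pairs — they are category
labels, never floating-point numbers. Missing calls (empty cell or `NA`)
exclude an individual from that locus's statistics only; this per-locus
complete-case rule is a package choice, as typing studies rarely state one.

## Allele frequencies and pooling

Males contribute one chromosome per locus, females two. The pooled
frequency defaults to `p = (2 p_f + p_m) / 3`, the weighting conventional
in X-STR panel reports; it is exact only when the numbers of male and
female individuals are equal, so the chromosome-weighted estimator
`p = (2 n_f p_f + n_m p_m) / (2 n_f + n_m)` (the maximum-likelihood pooled
estimate) is offered alongside. The default stays with the conventional
form for comparability with published tables; recovery tests use the
chromosome-weighted form because its sampling error is the plain binomial
`sqrt(p(1-p)/N)` over `N = n_m + 2 n_f` chromosomes.

Male/female homogeneity ("no gender bias") is tested with a G statistic on
the 2×k stratum-by-allele chromosome-count table, with a permutation null
(stratum labels shuffled over the pooled chromosomes, i.e. a multivariate
hypergeometric draw with fixed margins) and add-one correction
`p = (b+1)/(B+1)`. A one-way ANOVA on frequencies is sometimes seen here,
but allele counts are categorical and a contingency-table test is the
statistically well-posed version of the same question; its type-I error is
verified by simulation in the suite.

## Forensic-efficiency parameters

All eight per-locus parameters are closed forms in the power sums
`Qk = sum p_i^k` (see the README table). Points worth recording:

* **Het is expected heterozygosity** (gene diversity), not the observed
  proportion of heterozygous females — forced by the identity
  `PDM = Het = 1 - Q2` that the published panels print.
* **PE** uses the heterozygosity-based form `H^2 (1 - 2H(1-H)^2)`; it
  reproduces published PE columns from published Het at 4 decimals.
* **MEC Kishida** (mother/daughter/alleged-father trio with an X marker)
  equals PIC.
* **MEC Desmarais duo** is derived here from first principles for a
  hemizygous alleged father: his single X allele must miss both of the
  daughter's alleles, giving `sum_f p_f (1 - p_f)^2 = 1 - 2 Q2 + Q3` in
  expectation over daughters.
* **MEC Krüger** (deficiency cases) is the classical codominant trio
  exclusion power, which expands to
  `1 - 2 Q2 + Q3 + 3 (Q2 Q3 - Q5) - 2 (Q2^2 - Q4)` — note the fifth power
  sum; `Q5` is therefore carried in the `PowerSums` container. The form was
  validated against a published 19-locus panel by recovering `Q2, Q3, Q4`
  from the other columns row-by-row and checking that the implied `Q5` lies
  within its mathematically forced interval `[Q4^2/Q3, Q4]` for every row.
* The ordering MEC Krüger ≤ MEC duo holds for every informative published
  row but is **not** a theorem — near-monomorphic vectors reverse it — so
  the property suite does not assert it globally.

Cumulative values `1 - prod(1 - v)` are accumulated as `sum log(1 - v)`;
the complement is exact to double precision and the final subtraction is
done in decimal arithmetic so tails down to 10⁻²² print correctly. Reports
round per-locus values to 4 decimals and print cumulatives at full
precision.

## Exact tests

**Hardy–Weinberg.** Only females carry X genotypes. The test is the
conditional exact probability test: given allele counts `a_i`, a genotype
table with heterozygote count `h` has probability
`n! 2^h prod a_i! / ((2n)! prod n_ij!)`, and the p-value sums the
probabilities of all tables no more probable than the observed one.
`enumerate` mode walks every table with the observed margins (intended for
≤ ~4 alleles at small n); `monte-carlo` mode samples tables independently
by randomly pairing the `2n` chromosomes — an exact draw from the
conditional distribution — with add-one correction. Independent sampling
was chosen over a Markov chain: it is unbiased, trivially parallel, and
adequate at panel scale; agreement with full enumeration is part of the
oracle suite, as is agreement of the enumeration itself with a brute-force
enumeration of all perfect matchings of labelled chromosomes at tiny n.
Ties in table probability are resolved with a 1e-9 slack on the log scale
so enumeration and sampling treat the observed table identically.
Monomorphic loci return p = 1 with a warning.

**Linkage disequilibrium.** A permutation G-test on the genotype×genotype
contingency table of a locus pair in females with complete calls at both
loci; one genotype column is permuted B times (default 10⁴),
`p = (b+1)/(B+1)`, never zero. Inputs are canonically sorted before the
seeded permutation stream so the p-value is invariant to input row order.
This is a test of association only; D′/r² estimation is out of scope.
Bonferroni helpers provide α/m with `m = C(L,2)` pairs (171 for 19 loci)
or `m = L` for the HWE family.

## Haplotypes

Males read linked-locus haplotypes directly, so haplotype tables use males
only; females would require EM-based phasing, deliberately not implemented.
The seven-group default covers the 19-locus panel; groups are configurable
from a plain-text file. Diversity uses the unbiased estimator
`HD = n (1 - sum f_i^2) / (n - 1)` — the `n/(n-1)` correction is the
standard choice for haplotype data and makes `HD = 1` exact when all `n`
observed haplotypes are distinct. Males missing any member-locus call are
excluded from that group and reported in an excluded tally.

## Population comparison

`D_A = 1 - (1/L) sum_loci sum_i sqrt(x_i y_i)` over the shared locus set,
with each vector renormalized over the allele union before the square-root
sum (published tables are rounded to 4 decimals, so raw sums can miss 1 by
up to ~1e-4). UPGMA is implemented directly: size-weighted average linkage,
merge height = half the inter-cluster distance (ultrametric by
construction), ties broken lexicographically on cluster labels (each
cluster labelled by its smallest leaf) for full determinism; output is
rooted Newick. The MDS is classical/Torgerson — double-center the squared
distances, eigendecompose, scale eigenvectors — rather than an iterative
stress-majorization, because it is deterministic, closed-form and exactly
recovers Euclidean configurations; coordinates are meaningful only up to
rotation/reflection (sign convention: first nonzero loading of each axis
positive). Requesting more dimensions than the configuration's rank is an
error; the all-zero matrix maps to the origin.

## Synthetic populations

The generator's defaults mirror the design of the study the package
targets: 19 loci named after the AGCU X-19 panel, grouped into its seven
linkage groups, 5–26 alleles per locus, 156 males + 111 females.
Frequencies are symmetric Dirichlet draws (concentration 1.0, which
reproduces the realistic Het range ~0.6–0.95 for these allele counts) over
consecutive repeat-number labels; each label independently becomes a
microvariant with probability 0.1, matching panels where microvariants such
as 18.1/19.1 are common. Female genotypes follow the inbreeding model
`P(ii) = f p_i + (1-f) p_i^2`, `P(ij) = (1-f) 2 p_i p_j` with `f = 0` by
default (Hardy–Weinberg); `f > 0` spikes HWE violations for power checks.
A linkage group may be given an explicit haplotype distribution, in which
case whole haplotypes are drawn (two per female, inbreeding applied at the
haplotype level), inducing the within-group association the LD test should
detect; ungrouped loci segregate independently. Missing calls are masked
i.i.d. at a configurable rate (0 by default). Population sets for the
comparison stage drift from a common ancestor by the Balding–Nichols
construction (Dirichlet with concentration `p (1-d)/d`); `d = 0` returns
exact copies, and a two-level variant (between-cluster 0.3, within-cluster
0.05 by default) plants recoverable cluster structure.

What the generator does **not** emulate: mutation processes or realistic
allele-frequency spectra beyond the Dirichlet family, partial-amplification
artifacts (dropout is i.i.d., not fragment-length-dependent), genotyping
error, relatedness among samples, and realistic recombination — linkage is
all-or-nothing at the group level. Passing recovery tests therefore shows
the estimators and tests are correct under their stated sampling models,
not that real data meet those models.

## Problem sizes and numerical tolerances in the suite

Frequency-recovery checks use a three-standard-error band plus a
one-to-two-chromosome continuity allowance (`3·SE + 1/N` or `2/N`): for
rare alleles the expected count is below 1 and the estimator's
discreteness, not its standard error, dominates — a bare 3·SE band would
reject correct code. Heterozygosity and haplotype-diversity checks use
delta-method standard errors (`2 sqrt((Q3 - Q2^2)/N)` and the analogue in
haplotype moments). Calibration experiments run 500 replicates (HWE
p-value uniformity, Kolmogorov–Smirnov distance < 0.1), 1000 replicates
(LD type-I error within 0.05 ± 0.02; at this size the band is ~3 standard
errors of the rate estimator), and 100 replicates (two-cluster UPGMA
recovery ≥ 95%). Monte-Carlo HWE tests in simulations use 2000 table
draws — the resolution needed at α = 0.05 — while single-analysis defaults
stay at 10⁴ replicates.

## Known limitations

* The Genepop export encodes males as single 3-digit haploid codes; it
  exists to cross-check the female-only exact tests against the reference
  implementation and is not a general-purpose converter.
* The exact-probability HWE enumeration is exponential in allele count;
  use Monte-Carlo beyond ~4 alleles.
* MDS coordinates from different runs/tools agree only up to rigid motion
  (and, for iterative implementations, convergence error).
* Published inter-population distances can be reproduced only with the
  external populations' frequency tables, which are not bundled; the
  comparison machinery is validated on synthetic population sets instead.
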
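# Methods

## Data model

Genotypes are diploid calls at named microsatellite loci, stored as
unordered integer allele pairs (codes 1–999; 0 = missing) in an
individuals × loci × 2 array. GenePop (2- and 3-digit dialects) is the
exchange format; individual metadata (origin, sex/tactic, total length in
cm, body weight in g, tag) travels in a sidecar TSV joined on the
individual id, because GenePop has no metadata slots. Allele codes are
opaque: no size-to-repeat-unit conversion is attempted. All per-locus
statistics define their sample size as the number of individuals with
non-missing calls at that locus. A locus can be flagged as null-bearing;
it stays in the table and in genotype echoes but is excluded from
multilocus F-statistics, diversity means and the main parentage scoring
(it re-enters only to break assignment ties).

## Diversity and differentiation

* **Expected heterozygosity** uses the Nei–Chesser small-sample estimator
  including the observed-heterozygosity correction term,
  `He = n/(n-1) · (1 − Σp² − Ho/(2n))`. The variant without the `Ho/(2n)`
  term differs only at O(1/n); the corrected form is the published 1983
  estimator and is what the tests' rational-arithmetic oracle evaluates.
* **Allelic richness** is hypergeometric rarefaction to a standardized
  number of gene copies `g` (default 2 × the smallest per-locus sample
  size, i.e. copies, not individuals — the FSTAT convention):
  `Ar = Σ_a [1 − C(2N−N_a, g)/C(2N, g)]`, computed in exact rational
  arithmetic.
* **F-statistics** are Weir–Cockerham variance components, per allele and
  locus: θ = a/(a+b+c) among populations, f (F_IS) = 1 − c/(b+c) within.
  Multilocus values are always ratios of summed components, never means of
  per-locus ratios; negative estimates are retained. Loci monomorphic in
  the analysed groups contribute nothing to the sums.
* **Hardy–Weinberg exact test**: the chain state is the assignment of the
  fixed multiset of gene copies to individuals; one step swaps the
  contents of two uniformly chosen allele slots. This leaves allele counts
  invariant and has the exact conditional distribution of genotype arrays
  as its stationary law, so the visited-state fraction whose conditional
  probability is ≤ the observed array's estimates the exact p. Chain
  defaults are the conventional heavy setting (10⁵ dememorization steps,
  1,000 batches × 5 × 10⁴ iterations); analyses in this repository run
  reduced chains (10³/10²/5 × 10²) sized by the batch-mean Monte-Carlo
  standard error, which the result reports.
* **Association (LD) test**: genotypic contingency G statistic with the
  null distribution from permuting one locus's genotypes among
  individuals; p = (1 + #{G* ≥ G})/(n_perm + 1), which is exactly
  (discretely) uniform under the null.
* **Differentiation p-values** come from the same permutation logic with
  the summed-over-loci allele-count G statistic, individuals permuted
  among groups.
* **Null-allele frequency** is the heterozygote-deficit ratio
  `fn = (He − Ho)/(He + Ho)`, signed (negative under heterozygote excess),
  chosen over iterative ML because the study-style summary tables report
  signed values; the simple ratio reproduces that behaviour with no
  genotype-class iteration.
* **FDR**: Benjamini–Hochberg for single test families,
  Benjamini–Yekutieli (harmonic-sum inflation) for pairwise tables;
  adjusted p-values are monotone in rank and order-invariant.

## Marker power and parentage

PIC follows Botstein; the probability of identity is
`I = Σp⁴ + Σ_{i<j}(2p_i p_j)²` per locus, multiplied across loci.
Exclusion probabilities are exact Hardy–Weinberg expectations derived by
enumeration-free closed sums for three configurations: P1 (random
candidate against the offspring genotype alone), P2 (candidate second
parent given one known true parent), PP (random candidate pair jointly).
Panel-level exclusion multiplies non-exclusion across loci. All four
indices are verified against exhaustive-enumeration oracles in rational
arithmetic for panels of up to four alleles.

The assignment engine scores every mother × father pair for every
offspring. The per-locus likelihood under a trio is the Mendelian
transmission probability smoothed by a genotype-replacement error model
(observed genotype = truth with probability 1 − e, otherwise a random
Hardy–Weinberg draw; default e = 0.02); the reference likelihood is a
random Hardy–Weinberg draw, and the LOD is the summed log ratio. Candidate
lists are sex-aware (mothers = females; fathers = nesting + sneaker
males). Round 1 accepts the highest-LOD pair with zero Mendelian
mismatches; offspring unresolved there are rescored allowing ≤ 2
mismatching loci — mirroring a re-genotyping rescue loop without wet-lab
re-typing. LOD ties are never broken arbitrarily: in round 2 the flagged
null-bearing loci arbitrate, otherwise the offspring is reported
ambiguous. Allele frequencies for scoring are taken from the pooled
(adults + offspring) sample so every observed allele has positive
frequency.

A marker-ranking power simulation draws candidate pools and trios from
given frequencies and reports cumulative assignment success as loci are
added in descending Q(P2), the ranking convention of parentage power
studies.

## Effective number of breeders

Family sizes are tallied per contributing parent (≥ 1 assigned offspring)
per sex; excluding sneaker males removes sneaker-sired offspring from both
parental tallies. V_k is the population variance (divide by N) over
contributors, the moment convention of the Crow–Kimura derivations; k̄N
therefore equals the offspring total exactly. Per sex,
`Nb = (k̄N − 2)/(k̄ − 1 + V_k/k̄)`; the sexes combine as
`4·Nb_f·Nb_m/(Nb_f + Nb_m)`. Report tables round half-up to one decimal;
internal values keep full precision. Feeding published rounded (N, k̄,
V_k) census triples through these formulas reproduces the published
one-decimal values in all but two cells that sit within one rounding step
of a boundary (evaluating with the unrounded mean k̄ = total/N lands
exactly on the published value), and one published cell is known not to
follow from its printed inputs at all; these are reported, not corrected.

## Mating models

One record per male × female combination (the "pair universe"): origin
indicators for each sex (west = 1), a same-origin indicator, a size
covariate per sex, and a sneaker indicator. The size covariate defaults to
total length (cm); weight/length (g·cm⁻¹) is available by configuration —
the study literature is ambiguous between the two, and the worked
closed-form predictions evaluate printed coefficients directly, so they do
not depend on this choice. Success (≥ 1 sampled offspring) is modelled by
logistic regression on all pairs; offspring number by a log-link Poisson
on successful pairs only. Both are ML fits via statsmodels GLM (IRLS, Wald
standard errors), wrapped in Model classes whose `fit()` returns a results
object with `summary()`. Cross-checks fit the hand-written likelihoods by
generic numerical optimisation and agree to 10⁻⁶.

Assortative mating is a 2×2 Yates-corrected chi-square of mating-pair
counts by male origin × female origin, each distinct parental pair counted
once regardless of family size (offspring-weighted counting available);
the Yates term clamps |O − E| − 0.5 at zero so near-exact tables cannot
inflate the statistic.

## Synthetic mesocosm

The generator's defaults are the study conditions. Ancestral allele
frequencies per locus come from a symmetric Dirichlet (concentration 0.5,
4–30 alleles per locus — chosen to span the observed panel's 4–40 allele
range and ≈ 0.75 total gene diversity); each population draws
Dirichlet(p_anc·(1−F)/F) with F = 0.094 (Balding–Nichols), the variance
model whose among-population component Weir–Cockerham θ estimates, so the
estimator recovers F without calibration. Adult censuses are the study's
per-origin × tactic counts (64/9/76 south, 59/24/86 west; the published
per-origin release totals differ from these subgroup sums by two fish —
the subgroup counts are used, preserving the 162 female × 156 male pair
universe). Lengths and weights are truncated normals with the published
means, SDs and ranges per origin × tactic.

Mating applies the logistic success model per pair (Bernoulli) with the
published coefficient vector, then a zero-truncated Poisson for offspring
number of successful pairs — truncation keeps the "success ⇔ ≥ 1
offspring" invariant consistent with the two-stage model. Transmission is
Mendelian; with probability 0.02 per locus the recorded offspring genotype
is replaced by a random Hardy–Weinberg draw. One locus carries a null
allele (ancestral frequency 0.073, shared by both populations);
heterozygotes with the null are recorded as visible homozygotes and null
homozygotes as missing. 651 offspring are sampled uniformly without
replacement from all produced (the real total production in the basin is
unknown; here it is whatever the mating model yields, typically ~700).

What the generator does **not** emulate: nest-site dynamics and
male–male aggression, the extreme family-size skew of the real spawning
season (a Poisson count model underdisperses relative to the observed
variances of up to ~2,000, so simulated Nb is much higher than the
study's), overlapping generations, survival, and sampling bias in
offspring collection. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative model, not that
the model captures every feature of the real basin.

## Numerical conventions and edge cases

Monomorphic loci: He = 0, HW p = 1 (flagged), excluded from multilocus
F-statistic sums; both-groups-fixed-same-allele loci are skipped in θ.
fn is undefined (NaN) when He + Ho = 0. Exact-test comparisons use a 10⁻⁹
log-probability tolerance to absorb float noise in tie detection. GLM
convergence: IRLS, |Δdeviance| < 10⁻⁸, ≤ 100 iterations; complete
separation is surfaced via the statsmodels warning and the `converged`
flag. All Monte-Carlo procedures take explicit seeds and are reproducible
bit-for-bit; the pipeline manifest records seeds, configuration and report
hashes, and a rerun with the same seed is byte-identical.

## Problem sizes used in the test suite

The suite runs the full default-scale simulation (318 adults, 11 loci,
651 sampled offspring) for the end-to-end recovery checks; divergence
recovery averages 20 replicate seeds at 50 loci × 200 diploids; the
exact-test validity checks use two-allele samples small enough for full
enumeration and 200 replicate LD tests of 50 individuals with 200
permutations each; oracle equivalence uses panels of ≤ 4 alleles and ≤ 20
individuals where exhaustive rational enumeration is feasible. Reduced
Markov-chain settings (10³ dememorization, 100 × 500 iterations) keep the
chain's Monte-Carlo standard error well below the tolerances tested.
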
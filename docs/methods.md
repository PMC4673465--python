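# Methods

`popdiff` measures how human populations differ at a dense SNP window —
canonically the MHC region on chromosome 6 (25–35 Mb, Build 37) — at three
levels: single-SNP allele frequencies, multi-SNP haplotypes at gene loci,
and the practical consequence of those differences for genotype imputation.
This note records the models, the defaults and why, and what the synthetic
data do and do not establish.

## Quality control

Markers are retained when their call rate is **strictly greater** than the
threshold (default 0.95) and when an exact Hardy–Weinberg test gives
P > 0.05. The HWE test is the standard conditional exact test: given the
observed allele counts, the probability of each heterozygote count is
computed in closed form and the p-value sums all outcomes no more probable
than the observed one. By default the test runs within each population and
a marker must pass everywhere — pooling genotypes across differentiated
populations manufactures heterozygote deficits (Wahlund effect) and would
discard exactly the differentiated markers this package is meant to
measure. A pooled mode exists for comparison.

Marker intersection across panels is keyed by (chromosome, position);
allele pairs must agree up to allele order and strand flip, coding is
flipped to a common orientation when the order differs, and A/T and C/G
SNPs are dropped because their strand cannot be resolved across genotyping
arrays.

## SNP-level F_ST

Between two populations with allele frequencies p1 and p2 at a SNP,

    F_ST = (p1 − p2)² / (4 p̄ (1 − p̄)),   p̄ = (p1 + p2)/2,

the Nei form, identical to (H_T − H_S)/H_T with H_T = 2p̄q̄ and
H_S = (2p1q1 + 2p2q2)/2. Monomorphic sites contribute 0 and are included
in averages by default (excludable by flag). Population distance matrices
average this quantity over a marker set — by default the chr6 25–35 Mb
window when the map covers it.

This plug-in estimator carries an upward finite-sample bias of order
1/n_haplotypes and, under island-model differentiation F, has expectation
≈ F/(2−F) rather than F — both are properties of the estimator, not bugs,
and the tests check it against a Monte-Carlo of the same quantity. A
Weir–Cockerham sample-size-corrected theta (haploid-data form) is available
via `estimator="weir_cockerham"` for sensitivity analysis; its per-marker
values may be slightly negative under no differentiation and are clipped
only after averaging.

## Haplotype-level F_ST

At each gene region the distinct haplotype strings act as alleles of one
multi-allelic locus, and differentiation is the frequency-based G_ST:
H_S is the mean within-population expected heterozygosity
1 − Σ p_h², H_T the same for the pooled (equal-weight mean) frequency
vector, and G_ST = (H_T − H_S)/H_T. This reduces exactly to the SNP formula
when the "haplotypes" are the two alleles of one SNP. It is a
frequency-spectrum measure, not an AMOVA variance decomposition; no
bit-equality with AMOVA-based software is claimed, and permutation
significance of individual cells is out of scope.

## Haplotype catalogs, major haplotypes, dissimilarity

Regions are 1-based inclusive on both ends. User-supplied gene coordinates
are extended by a 100 kb buffer on each side (clamped at position 1); the
packaged HLA loci in `popdiff.regions` are already-extended spans and are
used as-is. A catalog enumerates distinct haplotypes in first-appearance
order with per-population counts; frequencies divide by 2 × sample count.

A *major* haplotype reaches the threshold frequency (≥, inclusive) in at
least one population — 10% for HLA-A/-B/-C/-DR, 6% for HLA-DQ/-DP by
convention (class II loci span more SNPs, hence more, rarer haplotypes).
Labels H1, H2, … are assigned by descending maximum population frequency
with a lexicographic tie-break, purely for reproducibility; the labels are
arbitrary identifiers, not HLA allele names.

Dissimilarity between two haplotypes is 100 × Hamming distance / n SNPs,
reported to two decimals; the per-haplotype minimum over all other major
haplotypes summarises how isolated each major haplotype is (an en-dash is
emitted when only one major haplotype exists). Ancestry-group sharing
classifies a haplotype as present in a group when any member population
carries it at non-zero frequency, yielding a Venn partition.

## Ordination

Subject-level PCA standardizes genotypes per marker: center by the mean,
scale by √(p(1−p)) with the shrunk frequency p = (1+Σg)/(2+2n) (the
EIGENSOFT convention; plain p̂ by flag), zero missing entries after
centering, drop markers that do not vary. Scores come from the SVD;
eigenvalue signs are fixed by making each component's largest-magnitude
loading positive. Population-level coordinates can be obtained by averaging
sample coordinates per population.

Population-level PCoA is classical MDS of the F_ST matrix: double-center
the elementwise-squared distances, B = −½ C D⁽²⁾ C, eigendecompose, embed
on the positive eigenpairs. F_ST matrices are generally non-Euclidean; the
magnitude of discarded negative eigenvalues is reported as a diagnostic
(`negative_eigenvalue_mass`). Whether to decompose the raw matrix or the
double-centered squared form was an open design choice; classical MDS was
chosen because it is the standard with a recovery guarantee for Euclidean
inputs (verified in tests to 1e-10 on constructed geometries).

## Top-quantile F_ST enrichment

Pooling per-SNP F_ST over all C(K,2) population pairs, the top
`ceil(q × N)` values are selected (ties broken deterministically by pair
then SNP id). Under the null that top membership ignores the pair identity,
a record involves a focal population with probability (K−1)/C(K,2) = 2/K;
the p-value is the one-sided exact binomial upper tail. For K = 7 the null
probability is 2/7 ≈ 0.2857.

## Li–Stephens imputation and the masking protocol

A target haplotype is modelled as a mosaic of the N reference haplotypes:
a hidden Markov chain over reference rows with per-interval switch
probability ρ (jump target uniform over rows, so the stay probability is
1 − ρ + ρ/N), emitting the copied allele with miscopy probability ε at
typed markers; masked markers emit nothing. Defaults ε = 0.01, ρ = 0.05
per interval — deliberately generic values for a dense, uniformly spaced
map; ρ is constant per interval (distance-dependent switch rates and
recombination-map calibration, as production imputation engines use, are
out of scope). Dosage at a masked site marginalises the posterior:
P(allele 1) = Σ_s γ_s (ε + (1−2ε)·ref_s). Genotype dosage is the sum over
the sample's two haplotypes. Forward–backward is computed with per-marker
scaling; posteriors are normalized to 1e-10.

The accuracy protocol masks a fixed random subset of markers (400 of
1,607 by default), shared across all panels and target populations of a
run so panels are compared on identical ground. Each masked marker is
scored by the squared Pearson correlation r² between true genotype and
imputed dosage across target samples (19 per population by default);
markers with zero variance on either side are skipped and counted, not
scored zero. Discordance = 1 − mean r². Per-marker-then-mean is the
default aggregation (the imputation-field convention); a pooled-r² mode
exists because the alternative reading is defensible. Target and reference
sample sets must be disjoint — enforced, since imputing a sample against a
panel containing it overstates accuracy.

## Synthetic data: what it emulates, what it does not

The generator mirrors the study design the package targets: K populations
of 200 diploid samples (plus 19 held-out targets where imputation is
evaluated), 1,607 SNPs in the 25–35 Mb window of chromosome 6.

* **Balding–Nichols layer** — ancestral frequency per marker
  ~ Uniform(0.05, 0.95) (clipped support keeps markers polymorphic and the
  estimators well-conditioned), population frequencies
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F). F defaults to 0.01, the magnitude of the
  largest between-cohort distances reported for closely related
  populations at the MHC. Sites are independent: the right null for
  SNP-level statistics, no LD.
* **Founder-mosaic layer** — a shared pool of founder haplotypes (default
  12) sampled from one ancestral frequency vector; each population draws
  founder-usage weights from a symmetric Dirichlet (concentration 1.0 by
  default; smaller values give stronger haplotype-frequency contrast);
  haplotypes switch founders with probability 0.02 per marker and flip
  alleles with probability 0.002. This creates exactly the regime of
  interest — the same major haplotypes everywhere, at different
  frequencies — plus block-wise LD from the mosaic structure.

One global seed drives everything through deterministic sub-streams, so a
configuration is a complete specification of a dataset.

Not emulated: coalescent genealogy, recombination-rate variation,
demographic events, genotyping error beyond the flip rate, phasing error
(panels are generated phased; statistical phasing is out of scope, as is
any liftover between genome builds). Passing tests therefore demonstrate
estimator correctness and the qualitative panel-matching effect under
controlled differentiation; they do not certify accuracy numbers on real
MHC data, whose LD structure is far richer.

## Problem sizes used in the shipped checks

The parameter-recovery check runs 50 replicate cohorts at the full study
geometry (2 × 200 diploids × 1,607 SNPs) against a 500,000-marker
Monte-Carlo of the estimator's expectation. The imputation protocol check
runs 20 replicates at full geometry (200-sample panels, 19 targets, 400
masked SNPs) with one target population against matched and mismatched
panels. Copying-model correctness is established by exhaustive path
enumeration on ≤ 4-marker, ≤ 4-haplotype configurations, where the path
sum is tractable exactly.

## Known limitations

* The Nei-form estimator is biased upward by sampling at fixed sample
  size; cross-cohort comparisons should hold sample sizes equal or use the
  Weir–Cockerham switch.
* G_ST at gene regions saturates as haplotype diversity grows (many rare
  haplotypes push H_S toward 1); values are comparable across populations
  within a region, less so across regions with very different SNP counts.
* The copying model uses uniform jump targets and constant ρ, so its
  absolute discordance is not comparable to production engines with
  calibrated recombination maps; only contrasts between panels are
  interpreted.
* Multi-allelic variants are not supported anywhere.
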
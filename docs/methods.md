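# Methods

`lofgwas` compares genome-wide mapping strategies for binary
loss-of-function (LOF) traits in structured, highly inbred panels. This
note documents the statistical models, the synthetic-data generator
that stands in for real panels, the numerical choices, and the limits
of what the simulations demonstrate.

## The mapping problem

A classic complication for association mapping of qualitative traits is
the combination of *allelic heterogeneity* (several independent LOF
alleles at one gene), *complementary epistasis* (a homozygous LOF
genotype at any one of several genes abolishes the phenotype), and
population structure. When multiple LOF alleles arise on a shared,
older haplotype, intermediate-frequency markers tagging that haplotype
covary with the phenotype more strongly than any single causal allele —
a synthetic association. Linear models reward covariation at *both*
alleles of a marker, so they rank such tags above the true causal SNP.

## The loss-of-function genome scan

For each SNP, samples homozygous for allele 1 and allele 2 form two
disjoint classes (heterozygotes are excluded; the panels modeled here
are nearly fully inbred). With `L1/W1` and `L2/W2` the LOF/wild-type
phenotype counts in the two classes and

```
P = (L1 + L2) / (L1 + L2 + W1 + W2)
```

the pooled LOF proportion, the scan statistic is

```
LOF = min( BinomTest(L1; L1 + W1, P),  BinomTest(L2; L2 + W2, P) )
```

The exact binomial test is two-sided by default under the
minimum-likelihood convention: the p-value sums Binomial(n, P)
probabilities of all outcomes no more likely than the observed count,
with a relative tie tolerance of 1e-7 guarding floating-point
near-ties. A one-sided `greater` option tests pure enrichment of the
LOF phenotype, which matches the scan's verbal motivation (an allele
*often* found with the LOF phenotype and *rarely or never* with the
wild type); the two-sided default additionally counts depletion at the
wild-type allele class as signal. On the worked tannin-panel counts
(78, 0, 112, 139) the two conventions give 4.2e-19 and 2.5e-19
respectively — the same order of magnitude, so the default follows the
convention of the general-purpose exact test.

Degenerate cases are exact: an empty allele class contributes p = 1
(zero trials), and P = 0 or 1 forces the observation, also giving
p = 1. p-values are floored at 1e-320; a SNP with no scorable
homozygous calls is reported missing rather than p = 1.

## Linear-model engines

The binary trait is treated as a quantitative 0/1 response, the
standard practice of mixed-model GWAS tools for scored qualitative
traits. All engines consume mean-imputed real dosages (the LOF scan
never does) and report a 1-df partial F (equivalently squared t) test
for the SNP term with denominator df = n − p − 1, p counting the
intercept and covariates.

* **GLM**: ordinary least squares of trait on intercept (+ optional
  principal-component covariates) + dosage, vectorized across markers
  by residualizing trait and dosages against the covariate space.
* **MLM**: y = Xb + u + e with u ~ N(0, σg²K). REML estimation
  profiles the likelihood over δ = σe²/σg² after a one-time spectral
  decomposition of K: a 100-point log grid on [1e-5, 1e5] refined by
  bounded scalar minimization (tolerance 1e-8 on the objective). The
  REML criterion includes ln|X'V⁻¹X| − ln|X'X| so it is invariant to
  reparameterization of the fixed effects. A refined optimum at the top
  of the grid is reported cleanly as σg² = 0 (δ = ∞), under which the
  scan reduces exactly to the GLM. Default scanning mode is P3D:
  variance components are fitted once on the no-SNP model and reused
  for every marker via generalized least squares in the rotated space.
* **MLM, exact mode**: δ is re-optimized for every marker. The per-SNP
  profile uses maximum likelihood rather than REML, because ML values
  of nested fixed-effect models are directly comparable (adding the SNP
  column can never reduce the maximized likelihood), whereas REML
  values across different fixed-effect designs are not. The Wald F at
  the per-SNP optimum keeps the same df convention as P3D.
* **CMLM**: samples are clustered on the kinship-derived distance
  d_ij = max(K) − K_ij (average linkage by default; complete linkage
  available) and each candidate group count replaces K by the
  group-mean kinship expanded through the sample-to-group incidence.
  The group count maximizing the null REML log-likelihood over a
  ~10-point log-spaced grid from 1 to n wins; the boundary counts are
  special-cased so that n groups reproduces the MLM exactly and 1 group
  collapses (through the σg² boundary) to the GLM.

Kinship is the VanRaden method-1 centered genomic relationship matrix,
K = WWᵀ / (2Σ pⱼ(1−pⱼ)) with markers centered at twice their allele
frequency; an identity-by-state alternative is provided. Structure
covariates are principal components of the column-centered (not
variance-standardized) dosage matrix — equivalent to classical MDS on
Euclidean genotype distances — with the number of components chosen by
BIC = n·ln(RSS/n) + (k+1)·ln(n) over nested least-squares fits,
ties to the smaller k.

## Synthetic panels

The generator emulates the architecture that produces synthetic
associations, at desk scale (default 4 subpopulations × 75 fully
inbred samples, 20,000 neutral SNPs on 10 chromosomes):

* Neutral SNPs draw ancestral frequencies uniformly on a mirrored MAF
  band (default 0.05–0.5) and per-subpopulation frequencies from the
  Balding–Nichols Beta model at Fst = 0.2; inbred genotypes are
  2·Bernoulli(subpop frequency).
* Gene A is a tag haplotype (default panel MAF ~0.42, in the 0.3–0.45
  band typical of indirect associations) carrying two mutually
  exclusive LOF alleles — a focal allele at panel frequency ~0.235 and
  a rarer second allele (~0.095) — present *only* on tag carriers.
  Five additional markers are noisy copies of the tag column (5 %
  per-sample flips), giving imperfect LD without a coalescent; the
  argument needs intermediate-frequency tag-linked markers, not a
  realistic LD decay profile.
* Gene B, on another chromosome, carries an independent LOF allele
  (mean frequency 0.11) that also abolishes the phenotype.
* The phenotype is 0 with probability `penetrance` (default 1) for any
  homozygous LOF genotype at A or B, and 0 with probability
  `phenocopy_rate` (default 0.29) otherwise. The phenocopy channel
  represents LOF phenotypes caused by loci outside the simulated pair;
  in the real tannin panels well over half the LOF-phenotype samples
  carry wild-type alleles at the mapped gene, and the defaults
  reproduce that composition (pooled LOF proportion ~0.58 with the
  focal allele explaining ~40 % of the LOF class). All per-subpopulation
  frequencies follow decreasing gradients so the causal alleles are
  themselves structured; published sources give only qualitative
  race-level patterns, so the gradients are design choices fixed once.

These defaults were calibrated to the printed end-to-end signature of
the motivating study: the focal causal SNP's contingency table
(pooled proportion 190/329, pure LOF class of ~78 carriers), the tag
MAF band, and the published rank/p-value contrast in which tag SNPs
outrank the causal SNP under a naive GLM while the LOF scan ranks the
causal SNP first with a ~e¹⁴ margin over the best tag.

What the simulations do **not** capture: realistic LD decay and local
haplotype structure (tags are noisy column copies), structured
phenocopies (the unmapped LOF mass is spread uniformly, whereas real
unexplained alleles cluster by subpopulation), genotyping error, and
missingness patterns of reduced-representation sequencing. Passing
benchmarks therefore demonstrate the ordinal behavior of the scan
statistics under the modeled architecture, not performance guarantees
on real panels.

## RIL families

Biparental recombinant inbred lines are simulated forward from two
fully homozygous parents (a configurable fraction of markers
polymorphic between them): F1 heterozygous everywhere polymorphic, then
t generations of selfing (default 5, i.e. F6) with two independent
gametes per plant per generation. Crossovers follow the Haldane
(no-interference) model; since a Poisson crossover process observed at
marker loci is equivalent to independent Bernoulli strand switches
between adjacent markers with r = (1 − exp(−2d))/2, the simulator
draws interval switches directly — exact and fully vectorized.
Closed-form checks: residual heterozygosity halves per generation
(0.5⁵ ≈ 0.031 at F6) and the fixation-limit recombinant fraction
between markers at single-meiosis recombination fraction r approaches
2r/(1+2r).

## Numerical and procedural choices

* Genotype codes count copies of allele 1 (VCF REF); orientation is
  irrelevant to the LOF scan and only flips effect signs in linear
  engines. Positions are 1-based; SNP ids are `S{chrom}_{pos}`.
* Monomorphic or covariate-collinear markers are reported missing
  (never p = 1); rank comparisons use competition ranking with
  deterministic (chromosome, position) tie-breaks.
* Replicate phenotype scores collapse to the unanimous value, or
  missing when replicates disagree (segregating accessions are dropped
  from analysis, as in field practice).
* MAF filtering (default min 0.01) is applied before scans; the source
  study states no explicit filter, so the default is conservative and
  exposed in configuration.
* Bonferroni cutoffs are always reported at both α = 0.01 and 0.05
  because published cutoff statements mix the two conventions.
* Benchmarks derive every random stream from the per-replicate seed;
  identical seed lists give bit-identical reports. Default problem
  sizes (n = 300, 20,000 neutral SNPs, 50 replicates for the headline
  contrast; 5,000 SNPs and 20 replicates in the acceptance script) keep
  a full run in minutes on one core.

## Known limitations

* The mixed model treats a binary response as Gaussian; no logistic or
  saddlepoint corrections are provided.
* The CMLM's behavior on real data depends on structure the simulator
  reproduces only qualitatively; the benchmark checks direction
  (compression does not beat the standard MLM for structured LOF
  alleles), not the magnitudes seen in real panels.
* Exact-mode MLM re-optimization is O(markers × grid) and is intended
  for validation at moderate marker counts, not routine scans.
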
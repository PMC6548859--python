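# Methods

This note documents the models and numerical choices behind `spudsel`, what
its synthetic-data generator does and does not emulate, and the known
limitations of each stage.

## Dosage coding and calling

A tetraploid genotype is coded as its **reference-allele frequency**:
AAAA = 1.0, AAAB = 0.75, AABB = 0.5, ABBB = 0.25, BBBB = 0.0.  The expected
alternate-read fraction of a cell is therefore `1 − code`.  This single
convention is used by the caller, the imputer, the regression matrix Z and
the distance computation.

Calling is nearest-class assignment of the observed reference-read fraction,
with class boundaries {0.125, 0.375, 0.625, 0.875} — the maximum-likelihood
rule under symmetric binomial read sampling.  Fractions landing exactly on a
boundary go to the upper class (`np.digitize` convention).  Two guard rules:
cells with total depth < 5 are missing (the explicit depth-5 wording wins
over the looser "more than five reads" phrasing; both are configurable), and
a cell with 1 ≤ alt reads < 2 cannot be called heterozygous — if
nearest-class assignment would give a heterozygote it is set to homozygous
reference instead.

Calling accuracy is depth-limited in a way no implementation can avoid: at
depth 30 a true AABB cell falls outside the (0.375, 0.625) window with
probability ≈ 0.20 (Binomial(30, 0.5) tails), so ≥ 99% class concordance is
only achievable at high depth.  The recovery test therefore runs at mean
depth 200 (per-class error ≤ 5·10⁻⁴) and separately asserts concordance is
monotone in depth.

## Variant filter cascade

A locus survives iff (a) at least one sample shows ≥ 5 alternate reads
("more than four" read strictly) and, among such samples, at least one has
an alternate-read fraction ≥ 0.4; (b) its missing fraction is < 0.5 ("50% or
more" removed); and (c) MAF > 0.05 ("5% or less" removed), with
MAF = min(p̄, 1−p̄) computed on the mean dosage code over observed samples —
an allele-frequency MAF, matching the frequency coding used downstream.
The report attributes each dropped locus to its **first** failing reason in
the order depth → alt-support → fraction → missing → MAF, so retained =
input − Σ exclusive failures.  Whether the 0.4 fraction threshold was
originally applied per sample or per variant is ambiguous; it is implemented
as "at least one sample satisfies it", and the mapping-quality (> 30) and
base-quality (> 20) filters are treated as already applied upstream of the
read counts.

SNP density uses half-open bins [1 + (i−1)·B, 1 + i·B) from position 1;
default B = 100 kb (the 10 kb alternative is a parameter).

## LD-kNN imputation

For a locus with missing cells: rank all other loci by squared Pearson
correlation with it over jointly observed samples ("closest loci" = highest
LD, not physical proximity — the method's name says so); keep the top 17;
for each missing sample compute a squared Euclidean distance to every
observed sample over those loci, normalised by the number of jointly
observed loci (pairwise-complete, so residual missingness does not penalise
a sample); impute the mean code of the 11 nearest observed samples.
Defaults k = 11 / 17 loci follow the parameterisation previously validated
on diverse outcrossing populations.

Determinism and edge rules: distance ties break by sample order; imputation
reads only *observed* input values, so the result is independent of locus
processing order; fewer observed samples than k → use all; a target that is
monomorphic among observed samples (unrankable by r²) and a missing sample
with no jointly observed selected loci both fall back to the observed
column mean; a locus with zero observed samples is an error (the
missingness filter should have removed it).  Imputed values stay continuous
in [0, 1] — the regression consumes allele frequencies, so re-binning to the
five classes would only discard information.

## BayesA / BayesB Gibbs sampler

Model: y = μ1 + Zv + e with Z the (centred) frequency-coded dosage matrix.
BayesA: v_j ~ N(0, σ²_vj), σ²_vj ~ scaled-inv-χ²(df = 5, S₀) — marginally a
scaled-t prior.  BayesB: with probability π (= `prob_in`, one of
0.1/0.05/0.01/0.005 in routine use) marker j has a non-zero effect drawn as
in BayesA, else v_j = 0; the inclusion indicator is sampled from its
marginal odds with v_j integrated out, then v_j from its normal full
conditional.  π is fixed, not estimated.  `prob_in = 1` reproduces BayesA
exactly (a tested limit).

Prior scaling from a user-supplied trait heritability h²: the scale S₀ is
set so the prior **mode** of σ²_vj equals h²·var(y)/MSx, with
MSx = Σ_j var(Z_j); for BayesB the scale is divided by π so the expected
genetic variance is preserved under sparsity.  The residual prior mode is
(1 − h²)·var(y) with df = 5.  (An alternative scale without the 1/df factor
in S₀ was evaluated and rejected: it inflates the prior marker variance
five-fold, visibly under-shrinks the effects and drives the
observed-on-predicted slope far below 1.)

Numerics: columns of Z are centred (better mixing; the intercept is mapped
back to the original scale, so `predict` takes raw codes and GEBVs are
shift-invariant).  Zero-variance columns keep a zero effect with a warning.
All random variates of an iteration are pre-drawn outside the sweep, which
makes the chain (a) bit-reproducible given the seed, (b) identical with and
without the optional numba JIT, and (c) *exactly* scale-equivariant: fitting
c·y scales μ and v by c variate-for-variate.  Default chain length is
12,000 iterations with 1,000 burn-in and no thinning; the statistical test
suite uses 1,000–4,000 iterations, which is ample for posterior means at the
tested problem sizes (n ≤ 500, m ≤ 200).  Two diagnostic hooks pin the
marker and residual variances, collapsing BayesA to a Gaussian sampler whose
posterior mean is the closed-form ridge estimator — the sampler's primary
correctness oracle.

## Cross-validation, accuracy, bias

k-fold CV (default k = 5) uses a seeded random balanced partition (fold
sizes differ by ≤ 1; 169 samples split 34/34/34/34/33), no stratification.
Accuracy is the Pearson correlation of held-out GEBVs with phenotypes,
summarised as mean ± sd/√k across folds.  The ceiling on accuracy is √h².
Bias is the OLS slope of observed on the pooled out-of-fold GEBVs.

A calibration note: with the prior h² equal to the generative h², posterior-
mean GEBVs are nearly slope-1 by construction, and simulations here give
slopes at or slightly below 1.  The classic underprediction signature
(slope > 1, as seen in real cultivar data) emerges when the analysis prior
**understates** the trait's heritability — e.g. traits generated at
h² = 0.8 analysed at h² = 0.5 give mean slopes ≈ 1.06 (up to ≈ 1.3 at
stronger understatement) at n = 100.  That mirrors practice, where literature
heritabilities with acknowledged uncertainty are used for scaling, and it is
the regime the bias test exercises.

## Nei distance and neighbour joining

Individuals are treated as populations of four allele draws: p is the
dosage code itself.  J_xy, J_x, J_y are per-locus-averaged identity sums and
D = −ln(J_xy/√(J_x·J_y)) (Nei 1972 standard distance, the default variant
for frequency data).  D is invariant to ref/alt swaps; pairs with J_xy = 0
get a capped sentinel (700) with a warning.  Neighbour joining is the
classic Saitou–Nei agglomeration with Q-criterion ties broken by the
smallest current (i, j) index pair; negative branch estimates are clamped to
zero with the deficit moved to the sister branch.  Trees are skbio
`TreeNode`s (Newick round-trip guaranteed); an independent NJ implementation
(skbio's) is used as a cross-check in tests, never as the implementation.

## Synthetic cohort generator

What it emulates: an ~180-cultivar commercial tetraploid collection
genotyped by transcriptome sequencing.  Markers are placed uniformly within
gene intervals on the 12 potato chromosomes (reference assembly lengths);
by default gene-interval density rises toward chromosome ends (uniform +
reflected-Beta(0.5, 0.5) mixture) to echo the distal gene-rich organisation
of the potato genome — cosmetic and switchable.  LD comes from a
founder-haplotype pool per physical block (default 4 founders, block size
`ld_block_bp` = 1 Mb): each sample draws its four homologues i.i.d. from the
pool, so within-block loci share founder identity and are correlated while
blocks are independent.  Allele-frequency granularity is therefore
1/n_founders, and target frequencies (uniform on `maf_range`, default
0.1–0.5) are realised by assigning the alternate allele to the nearest
achievable founder count, clipped to keep every locus polymorphic.  Tests
that need near-perfect LD use 2 founders with whole-chromosome blocks;
tests that need independence use the default genome where 1 Mb blocks
rarely hold two of the sampled loci.

Reads: depth ~ Poisson(mean_depth) per cell, alternate reads ~
Binomial(depth, (1−code)(1−e) + code·e) with symmetric error rate e
(default 0.005).  Phenotypes: y = μ + Zv + e*, dense architecture uses
standard-normal effects; sparse architecture gives the n_qtl chosen loci
unit-magnitude random-sign effects (equal-variance QTL, so every simulated
QTL genuinely carries trait signal — a QTL drawn with a near-zero effect
would be undetectable by construction and would make detection benchmarks
meaningless).  Environmental variance is set from the realised genetic
variance so var(Zv)/var(y) targets h²; mean realised h² is within 0.05 of
target over 10 cohorts at n = 500.  Missingness is MCAR at a configurable
rate (the real missingness mechanism of sequencing data is not
characterised here).

What it does **not** emulate: coalescent/pedigree genealogies, allele-
specific expression, library-preparation artefacts, splice junctions,
depth–genotype confounding, informative missingness, population structure
or usage-class subdivision.  Passing tests therefore demonstrate method
correctness and statistical calibration under a clean additive tetraploid
model, not performance on any particular real cohort.

## Problem sizes used in the test suite

Statistical checks run at n = 100–500 samples and m = 40–300 markers with
1,000–20,000 Gibbs iterations, chosen so each property has comfortable
power while the whole suite and the acceptance script each complete in
well under a minute of sampler time.  The real-data scale (183,848 SNPs ×
181 cultivars) is I/O- and memory-feasible for every stage (the sampler is
O(n·m) per iteration) but is not exercised in tests.

## Known limitations

- Whether Z columns were centred in the original analyses is unknown;
  centring is used here (documented deviation risk; GEBVs are unaffected).
- The filter's alternate-fraction rule and the imputer's distance metric are
  implementation-defined where the sources are silent; both are flagged
  above and configurable.
- `FilterReport` attributes each locus to a single (first-failing) reason;
  loci failing several criteria are not double-counted by design.
- Fold assignment reuses one seed per run; reusing one split across traits
  or drawing new splits are both expressible by changing the seed.
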
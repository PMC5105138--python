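# Methods

`peachgwas` re-implements, as a tested library, the computational chain of a
resequencing association study in a self-pollinating perennial crop sampled
at three evolutionary stages (wild relatives, landraces, improved
varieties): genotype quality control, population structure, three
association models, a windowed π-ratio selective-sweep scan, windowed
linkage disequilibrium, and the integration of association signals with
sweep regions.  A synthetic-data generator emulates the sampled species so
that every stage can be verified against a machine-readable truth set
without any external data.

## Synthetic populations (`simdata`)

The generator is a hierarchy of simple, analytically tractable stages.  It
is deliberately not a coalescent simulator: the goal is data whose
*analysis-relevant* properties (structure, selfing, block LD, planted
signals, genotyping noise) are controlled and recoverable, not mutational
realism.

**Allele frequencies.**  Wild-population alternate-allele frequencies are
drawn uniformly on [0.05, 0.95]; landrace frequencies drift from wild, and
improved from landrace, via a Balding–Nichols beta around the parental
frequency.  The beta's variance coefficient is set to `2·fst` so that
Hudson's FST estimator computed between parental and daughter samples
recovers the nominal parameter: under one-step drift only the daughter
population contributes drift variance, which halves the classical
Balding–Nichols FST.  This calibration caps valid `fst` below 0.5.
Defaults: `fst_wild_landrace = 0.15`, `fst_landrace_improved = 0.05` —
strong wild/domesticated differentiation with a milder improvement
bottleneck, matching the usual pattern in perennial crop panels.

**Haplotypes and LD.**  Each subpopulation has a pool of founder
haplotypes (default 8) sampled from its frequencies.  Chromosomes are cut
into blocks with exponentially distributed lengths (default mean 50 kb, the
window scale of the LD analysis and within the 20–50 kb LD-decay range
reported for cultivated material of this species); within a block every
haplotype copies one founder, chosen independently per block.  This yields
strong within-block LD that decays sharply across block boundaries — a
Li–Stephens-style mosaic without recombination-map realism.

**Selfing.**  Individuals receive two pool haplotypes; with probability
F = 1 − (1/2)^s (s = `selfing_generations`, default 5, F ≈ 0.97) the second
is a copy of the first.  No empirical per-group inbreeding level is
available for the emulated panel, so the default is a plausible guess for a
habitual selfer and is flagged as such.  Note a small-pool bias: with few
founders, two "independent" haplotypes still share founder mosaics by
chance, so realized homozygosity slightly exceeds the closed form; the
F-recovery calibrations therefore use large founder pools (≥400), where the
unrelated-haplotype assumption holds.

**Planted signals.**  A sweep overwrites a fraction (`carrier_fraction`) of
haplotypes inside a region with one designated founder mosaic, in the
selected stage's groups (domestication: landraces *and* improved, which
descend from them; improvement: improved only).  Qualitative traits are
single-locus with complete dominance plus an independent misclassification
flip (default 2%); quantitative traits are additive over planted loci with
optional per-group mean shifts and Gaussian noise scaled on the realized
dosages to hit the target heritability exactly in-sample.

**Genotyping noise.**  Each genotype independently goes missing at
`missing_rate` (default 3%); surviving homozygotes are miscalled with
probability 1 − 0.9359 and heterozygotes with 1 − 0.8382, the concordances
measured for low-coverage sequencing of this panel.  Homozygote errors go
to heterozygote 80% of the time (het calls are the unreliable class at low
depth) and to the opposite homozygote 20%.  A synthetic GQ is drawn from
one of two fixed discrete distributions such that a GQ ≤ 3 mask removes
~70% of miscalled genotypes but only ~2% of correct ones.

**Determinism.**  One master seed; each stage draws from a child generator
`default_rng([seed, stage_offset])` with fixed offsets, so identical
configurations give byte-identical outputs and any single stage can be
replayed.

## Quality control (`genoqc`)

Two-caller site intersection is exact set intersection on
(chrom, pos, ref, alt).  Filter boundary semantics are fixed once: a
variant is removed iff MAF < `min_freq` (allele-copy counting over
non-missing genotypes; the GWAS default 0.05 can be lifted with a
keep-rare override for severely distorted traits), removed iff its missing
fraction strictly exceeds 0.20, and a genotype is masked iff GQ ≤ 3.  The
chain order is mask → missingness filter → MAF filter → imputation; the
original study does not state whether its missingness filter ran before or
after imputation, and this order is the conservative choice (imputation
cannot rescue a variant that was mostly missing as called).

Imputation fills sporadic missing genotypes from the per-variant genotype
distribution, restricted to the sample's subpopulation when labels exist
(falling back to the full panel when a subpopulation has no calls), either
deterministically (modal genotype, ties to the lower dosage) or by seeded
sampling.  This deliberately replaces a haplotype-likelihood imputer: in
the emulated study imputation mainly reduced missingness rather than
improving heterozygote accuracy, and a frequency imputer reproduces
exactly that analytically relevant effect.  The `window_snps` parameter is
retained for interface compatibility but the frequency model is
per-variant.  Imputation never alters observed genotypes.

## Population structure (`popstruct`)

PCA follows the classical genotype-covariance recipe literally: 0/1/2
dosages, per-variant mean-centring (missing entries mean-imputed), the
n×n sample covariance, and its eigendecomposition.  No variance
standardization is applied, matching the description of the original
analysis.  Component signs are arbitrary.  Two PCs are carried downstream
by default (the panel separates into two groups along PC1; the second axis
is buffer), configurable.

Kinship is the centred cross-product (VanRaden) estimator
K = W·Wᵀ / (2·Σ pⱼ(1−pⱼ)), W = dosage − 2p; the exact estimator used by
the original GWAS tool is unstated and this is the standard choice.  Its
mean diagonal approaches 1 + F for inbred panels, which the tests exploit.
An IBS-similarity alternative is selectable.

Genetic distance is allele sharing (1 − IBS) with pairwise deletion; the
original distance metric is likewise unstated.  Neighbour joining is
Saitou–Nei agglomeration (via scikit-bio) with negative branch estimates
clamped to zero; on additive matrices it recovers topology and branch
lengths exactly, which the tests assert.

## Association models (`assoc`)

Three models, mirroring the classical GWAS-tool trio:

1. **GLM (naive):** per-marker least squares of the phenotype on the
   marker alone;
2. **GLM-PCA:** the same with PC scores as fixed covariates;
3. **MLM:** y = Xβ + g·b + u + e with u ~ N(0, σ²_g K).  Variance
   components are estimated once by REML on the no-marker model and reused
   for every marker ("P3D"); each marker test is then a generalized
   least-squares F test.

Binary traits are analysed with the same linear-model F tests as
continuous ones — the behaviour of the tools this reproduces — not
logistic regression.  Marker coding is genotypic (genotype-class
indicators, up to 2 df) by default for binary qualitative traits, matching
how dominant traits are naturally captured, and additive (1 df) for
quantitative traits; both are selectable.  Samples with missing phenotype,
covariate, or genotype are dropped per marker (listwise per trait).

REML profiles the restricted likelihood down to δ = σ²_e/σ²_g via the
eigendecomposition of K projected onto the residual space of X, maximizes
on a 100-point log-spaced grid over δ ∈ [1e−5, 1e5], and refines with
bounded Brent around the best grid point.  Boundary solutions are flagged;
at the upper boundary σ²_g is reported as exactly zero.  The MLM rotates
phenotype, covariates and all complete markers into the eigenbasis of K
once, so the per-marker cost is linear in n; markers with missing
genotypes fall back to a dense Cholesky GLS on the complete subset.
Marker F tests use the Frisch–Waugh–Lovell decomposition against a
precomputed null-design projection (SVD-based, so rank-deficient covariate
sets are handled); the reported effect is the marker block's first partial
coefficient.

Significance defaults to the fixed genome-wide cutoff 1e−8 (the Bonferroni
constant of the emulated study, α/m = 0.05/4,063,377 rounded to one
significant figure), with an α/m override.  Significant variants cluster
by single linkage with a 50 kb gap (the study's merging rule is unstated;
50 kb matches its window scale and is flagged as an assumption); each
cluster's minimum-p variant is the lead (position ties break low), and
candidate regions are lead ± 25 kb.  Explained variation is the partial
R² of the marker after covariates, ×100.  QQ curves use (i − 0.5)/m
plotting positions.

## Sweep scan (`sweepscan`)

Per-site diversity is the unbiased estimator
π_site = (2n/(2n−1))·2p̂(1−p̂) over non-missing diploids — identical to the
mean pairwise difference across the 2n sampled chromosomes, which the
enumeration oracle verifies to 1e−12.  Window π sums site values over a
50 kb window (5 kb step, grid anchored at 0, trailing windows kept when
≥ half length) and divides by window length in bp, so SNP-poor windows are
not inflated; windows with fewer than 10 SNPs are excluded from quantiles.
The scan statistic is the per-window π ratio (ancestral/derived:
wild/landrace for domestication, landrace/improved for improvement);
derived π = 0 with ancestral π > 0 maps to +∞ and ranks highest.  Windows
at or above the genome-wide (not per-chromosome) 95% quantile are
selected, ties included, and merged into maximal regions.

A caveat the acceptance suite makes explicit: selecting the top 5% of
*sliding* windows and merging cannot cover exactly 5% of the genome.
Merged coverage equals 5% plus (window − step) bp per selected cluster —
each cluster contributes ~45 kb of flanks — so on a neutral 4 Mb genome
with ~8 clusters the construction covers ~15%, and the excess depends on
cluster density, not genome size.  The implementation keeps the
construction exactly as defined and reports the measured value.

## Linkage disequilibrium (`ldscan`)

Two-locus haplotype frequencies are estimated from unphased diploids by
EM: all genotype configurations except the double heterozygote are
phase-determined and counted directly; the double heterozygote's two
phasings are weighted by their current relative likelihood.  Convergence
at max frequency change < 1e−8 or 1000 iterations.  From the fitted
frequencies: D = f_AB·f_ab − f_Ab·f_aB; D′ = |D|/D_max with the usual
sign-dependent D_max; r² = D²/(p_A q_A p_B q_B).  Computing r² from the
same EM frequencies as D′ keeps the two statistics on one estimand; a
genotype-correlation r² is available as an alternative (tool defaults
differ and the emulated study's setting is unstated).

Windowed LD averages pairwise r² and D′ over all variant pairs within
non-overlapping 50 kb blocks, subsampled to 300 pairs per block (seeded)
as a documented approximation.  Blocks with mean r² ≥ 0.01 are ranked by
mean D′ / mean r², and the top 0.5% are flagged — high D′ with low r²
marks regions where variants were fixed clonally without recombination.
The min-r² guard (0.01) prevents near-equilibrium blocks from dominating
through a vanishing denominator.  The tag-SNP estimate is
floor(genome length / LD-decay distance).

## Integration (`integrate`)

All in-memory intervals and BED outputs are 0-based half-open; VCF
positions are 1-based, converted only at the I/O boundary.  Overlap
records are all candidate×sweep pairs with positive intersection.
Truth-based evaluation counts a planted locus as detected when a lead for
its trait lies within 25 kb, scores sweep recovery as planted-bp covered
by same-stage calls, and counts called regions with no truth overlap as
false positives.  `run_full` executes simulate/load → QC → structure →
association → sweep scan → LD → overlap → evaluation and writes a JSON
manifest with parameters, the seed chain, and per-stage counts, so every
reported number is replayable; identical configurations give identical
artifacts.

## Calibration experiments and problem sizes

The test suite runs everything at desk scale, chosen once:

* Unit fixtures: 1–2 chromosomes × 0.2–1 Mb, the default 129-sample panel.
* Null calibration: the three models are sized on 10,000 *independent*
  null markers (single panmictic population, one-variant LD blocks, MAF
  ≥ 0.05, permuted Gaussian phenotype).  Independence matters: with LD or
  shared structure the markers' test statistics are cross-correlated and
  the empirical rejection rate has far more variance than the binomial
  reference against which size is judged.
* Signal recovery: 20 replicates of the full study shape — 129 samples,
  2 × 2 Mb at ~200 bp spacing (≈20k markers), noisy genotypes through the
  QC chain, one dominant locus, two 150 kb domestication sweeps at carrier
  fraction 0.9.
* Noise calibration: ≥1e5 genotypes.

## What passing tests do and do not show

The generator reproduces the features the pipeline is sensitive to —
hierarchical structure, selfing homozygosity, block LD, planted
Mendelian/polygenic/sweep signals, and calibrated genotyping noise.  It
does not model recombination maps, mutation-rate variation, pedigrees,
structural variation (traits driven by transposon insertions are invisible
to SNP-based association by construction, a limitation shared with the
emulated study), gene conversion, or realistic site-frequency spectra.
Passing recovery tests therefore demonstrate correctness of the analysis
chain under its own assumptions, not power on real resequencing data.

## Known limitations

* The EM LD estimator assumes random pairing within the sample; under
  extreme inbreeding the double-heterozygote weighting is approximate
  (few double heterozygotes exist, so the effect is small in practice).
* The frequency imputer ignores haplotype context by design.
* REML is 1-D in δ and assumes a single random effect.
* Per-marker subset GLS (missing genotypes in the MLM) refits the
  whitening per marker and is O(n³) for those markers.
* Sweep calling is a quantile rule with no significance model, faithful
  to the emulated analysis.
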
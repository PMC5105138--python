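# peachgwas

A tested re-implementation of the computational chain behind a
whole-genome-resequencing association study of a self-pollinating
perennial fruit crop sampled at three evolutionary stages — wild
relatives, landraces, and improved varieties.  The package covers:

* **Genotype QC** — two-caller site intersection, GQ ≤ 3 masking,
  missingness (> 20%) and minor-allele-frequency (< 0.05) filters, and
  sporadic-missing imputation from within-group genotype frequencies.
* **Population structure** — 0/1/2 dosage encoding, sample-covariance PCA,
  VanRaden kinship, allele-sharing distances, neighbour-joining trees.
* **Association** — three models per trait: a naive GLM, GLM with PC
  covariates, and a mixed linear model
  y = Xβ + g·b + u + e, u ~ N(0, σ²_g K), with variance components
  estimated once by REML and reused for every marker test (P3D);
  Bonferroni cutoffs, lead-SNP clustering, partial-R² explained
  variation, QQ curves, segregation ratios.
* **Selective-sweep scan** — nucleotide diversity
  π = (2n/(2n−1))·2p̂q̂ per site in 50 kb / 5 kb sliding windows; windows
  in the top 5% of the ancestral/derived π ratio (wild/landrace for
  domestication, landrace/improved for improvement) are merged into
  candidate sweep regions.
* **Linkage disequilibrium** — EM haplotype-frequency estimation from
  unphased diploids, D, D′ and r² per pair, windowed means, and a
  D′/r² block ranking that flags regions fixed clonally without
  recombination; tag-SNP coverage estimates.
* **Integration** — GWAS candidate regions × sweep regions overlap, and
  truth-based recovery evaluation on synthetic data.

Because the original panel is not redistributable, the package ships a
first-class synthetic-data generator (`peachgwas.simdata`) that emulates
the study system: three subpopulations under hierarchical
Balding–Nichols drift, founder-mosaic haplotypes with block-wise LD,
strong selfing (F = 1 − (1/2)^s), planted dominant Mendelian loci,
polygenic quantitative traits, low-diversity sweep regions, and
low-coverage genotyping noise (93.59% homozygote / 83.82% heterozygote
concordance, sporadic missingness, synthetic GQ).  Every simulation
writes a truth set so recovery is measurable.  See `docs/methods.md` for
the models and their assumptions.

## Worked example

Run the full chain on a small simulated panel (129 accessions, 2
chromosomes × 1 Mb, one dominant trait, one polygenic trait, one planted
domestication sweep):

```python
from peachgwas.simdata import (SimConfig, SweepSpec,
                               QualitativeTraitSpec, QuantitativeTraitSpec)
from peachgwas.integrate import PipelineConfig, run_full

cfg = PipelineConfig(sim=SimConfig(
    seed=42, n_chrom=2, chrom_length=1_000_000, snp_spacing_mean=800,
    sweep_specs=[SweepSpec("scaffold_1", 300_000, 400_000, "domestication", 0.9)],
    qualitative_traits=[QualitativeTraitSpec("fruit_shape", misclassification_rate=0.02)],
    quantitative_traits=[QuantitativeTraitSpec("fruit_weight", heritability=0.6)],
))
manifest = run_full(cfg, "example_out")
```

The manifest records, stage by stage:

```
input        n_samples 129, n_variants 2500
qc           n_variants 1875
structure    top eigenvalues 8.92, 5.95, 1.50, ...   # two structure axes
association  n_leads 1
sweep_scan   domestication: 1 region of 145 kb
evaluation   fruit_shape detected at distance 0 bp; sweep recovery 1.0
```

and `example_out/leads.tsv` contains the lead signal:

```
trait        chrom       pos     p            mlog10p  explained_variation_pct  region
fruit_shape  scaffold_2  390890  4.55e-43     42.34    79.2                     365890-415890
```

The planted dominant locus is recovered exactly (lead at the causal
position, −log₁₀p = 42.3, explaining 79% of phenotypic variance after PC
covariates), and the planted 100 kb sweep is fully contained in the one
called domestication region.  All artifacts are plain text (VCF, TSV,
BED, newick, JSON manifest).

The same pipeline is scriptable from the shell:

```bash
peachgwas full --config config.yaml --seed 42 --out-dir example_out
peachgwas simulate | qc | structure | gwas | sweep | ld | overlap ...
```

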
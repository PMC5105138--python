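"""Structured, selfing, LD-bearing diploid population simulator.

The generator emulates the data-generating process behind a resequencing
study of a self-pollinating perennial crop sampled at three evolutionary
stages — wild relatives, landraces, and improved varieties — so that every
downstream stage (QC, structure, association, sweep scan, LD) can be
exercised and verified against a machine-readable truth set.

Model summary
-------------
* Allele frequencies drift hierarchically wild -> landrace -> improved via a
  Balding-Nichols beta around the parental frequency.  The drift parameter
  is calibrated so that Hudson's FST estimator computed between a parental
  and daughter population recovers the nominal value.
* Haplotypes are founder mosaics: each chromosome is cut into blocks with
  exponentially distributed lengths, and within a block each haplotype
  copies one of a small pool of founder haplotypes, giving tunable
  block-wise LD that decays across block boundaries.
* Individuals are formed from two pool haplotypes; with probability
  F = 1 - (1/2)**selfing_generations the second is a copy of the first
  (autozygous), reproducing the excess homozygosity of a selfer.
* Selective sweeps are planted by overwriting a fraction of haplotypes in a
  region with a single designated founder mosaic in the selected stage's
  subpopulation(s).
* Genotyping noise mimics low-coverage sequencing: sporadic missingness,
  homozygote/heterozygote miscalls at configurable accuracies, and a
  synthetic genotype-quality (GQ) score that is stochastically lower for
  miscalled genotypes so that GQ-based masking is exercisable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, Region, allele_frequencies

SUBPOPS = ("wild", "landrace", "improved")
STAGES = ("domestication", "improvement")
# Subpopulations whose haplotype pools a planted sweep overwrites: a
# domestication sweep is shared by landraces and their improved descendants.
STAGE_TARGETS = {"domestication": ("landrace", "improved"), "improvement": ("improved",)}

# Child-seed offsets for the per-stage RNG streams.
_SEED_OFFSETS = {
    "positions": 1,
    "frequencies": 2,
    "haplotypes": 3,
    "sweeps": 4,
    "diploids": 5,
    "traits": 6,
    "noise": 7,
}

# Synthetic GQ distributions (value, probability), fixed so that a GQ<=3
# mask removes ~70% of miscalled genotypes but only ~2% of correct ones.
GQ_CORRECT_VALUES = (2, 5, 10, 20, 40, 60, 99)
GQ_CORRECT_PROBS = (0.02, 0.05, 0.13, 0.20, 0.25, 0.20, 0.15)
GQ_MISCALL_VALUES = (0, 1, 2, 3, 4, 6, 10)
GQ_MISCALL_PROBS = (0.15, 0.20, 0.20, 0.15, 0.12, 0.10, 0.08)


@dataclass
class SweepSpec:
    """A region to deplete of diversity in the selected stage's groups."""

    chrom: str
    start: int
    end: int
    stage: str = "domestication"
    carrier_fraction: float = 0.9


@dataclass
class QualitativeTraitSpec:
    """A single-locus Mendelian trait with complete dominance."""

    name: str
    locus_index: int | None = None  # variant index; None -> auto-pick
    dominant_allele: str = "alt"  # which allele carries dominance: "ref"|"alt"
    misclassification_rate: float = 0.02
    min_maf: float = 0.15  # for auto-picked loci


@dataclass
class QuantitativeTraitSpec:
    """A polygenic trait: additive dosages + group shifts + Gaussian noise."""

    name: str
    n_loci: int = 5
    loci: list[int] | None = None
    effects: list[float] | None = None
    heritability: float = 0.5
    subpop_shifts: dict[str, float] | None = None
    min_maf: float = 0.1


@dataclass
class SimConfig:
    """Simulation parameters.

    The default sample composition (12 wild / 62 landrace / 55 improved)
    mirrors a typical three-stage crop resequencing panel; genotyping
    accuracies default to low-coverage sequencing concordances (93.59% for
    homozygotes, 83.82% for heterozygotes).  ``selfing_generations`` has no
    empirical anchor and defaults to 5 (F = 0.969) as a plausible level for
    a habitual selfer.  The genome defaults (2 chromosomes x 2 Mb, ~400 bp
    marker spacing) are desk-scale stand-ins for a ~225 Mb genome.
    """

    n_wild: int = 12
    n_landrace: int = 62
    n_improved: int = 55
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    snp_spacing_mean: float = 400.0
    fst_wild_landrace: float = 0.15
    fst_landrace_improved: float = 0.05
    block_length_mean: float = 50_000.0
    n_founder_haplotypes: int = 8
    selfing_generations: int = 5
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    qualitative_traits: list[QualitativeTraitSpec] = field(default_factory=list)
    quantitative_traits: list[QuantitativeTraitSpec] = field(default_factory=list)
    hom_accuracy: float = 0.9359
    het_accuracy: float = 0.8382
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hom_accuracy", "het_accuracy", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("fst_wild_landrace", "fst_landrace_improved"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
            if v >= 0.5:
                raise ValueError(
                    f"{name} must be below 0.5: the drift parameter is calibrated "
                    "to pairwise Hudson FST, which caps at 0.5 under one-step drift"
                )
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if self.n_founder_haplotypes < 1:
            raise ValueError("n_founder_haplotypes must be >= 1")
        for s in self.sweep_specs:
            if s.stage not in STAGES:
                raise ValueError(f"unknown sweep stage {s.stage!r}; expected one of {STAGES}")
            if not 0.0 <= s.carrier_fraction <= 1.0:
                raise ValueError("carrier_fraction must be in [0, 1]")
            if s.start < 0 or s.end > self.chrom_length or s.end <= s.start:
                raise ValueError(f"sweep interval {s.start}-{s.end} outside chromosome bounds")

    @property
    def n_samples(self) -> int:
        return self.n_wild + self.n_landrace + self.n_improved

    @property
    def subpop_sizes(self) -> dict[str, int]:
        return {"wild": self.n_wild, "landrace": self.n_landrace, "improved": self.n_improved}

    def chrom_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_chrom)]

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage child generator: master seed plus a fixed stage offset."""
        return np.random.default_rng([self.seed, _SEED_OFFSETS[stage]])


@dataclass
class FreqTable:
    """Per-subpopulation alternate-allele frequencies, aligned to a variant grid."""

    freqs: np.ndarray  # (n_subpops, n_variants) in [0, 1]
    chrom: np.ndarray
    pos: np.ndarray
    subpops: tuple[str, ...] = SUBPOPS

    def __post_init__(self) -> None:
        if self.freqs.shape[0] != len(self.subpops):
            raise ValueError("frequency table row count != number of subpopulations")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")

    def for_subpop(self, name: str) -> np.ndarray:
        return self.freqs[self.subpops.index(name)]


@dataclass
class HaplotypePool:
    """Per-subpopulation haplotype matrices plus their founder mosaics."""

    haplotypes: dict[str, np.ndarray]  # subpop -> (n_haps, n_variants) uint8
    founders: dict[str, np.ndarray]  # subpop -> (n_founders, n_variants) uint8
    chrom: np.ndarray
    pos: np.ndarray

    def copy(self) -> "HaplotypePool":
        return HaplotypePool(
            haplotypes={k: v.copy() for k, v in self.haplotypes.items()},
            founders={k: v.copy() for k, v in self.founders.items()},
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
        )


@dataclass
class TruthSet:
    """Machine-readable record of everything planted into one simulation."""

    causal_loci: list[dict]  # {trait, mode, variant_index, chrom, pos, effect}
    sweep_regions: list[dict]  # {chrom, start, end, stage, carrier_fraction}
    inbreeding_coefficient: float
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            causal_loci=d["causal_loci"],
            sweep_regions=d["sweep_regions"],
            inbreeding_coefficient=d["inbreeding_coefficient"],
            seed=d["seed"],
            params=d.get("params", {}),
        )

    def sweep_region_objects(self) -> list[tuple[Region, str]]:
        return [
            (Region(s["chrom"], s["start"], s["end"], label=s["stage"]), s["stage"])
            for s in self.sweep_regions
        ]


def expected_inbreeding(selfing_generations: int) -> float:
    """F = 1 - (1/2)**s: probability of autozygosity after s selfing rounds."""
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    return 1.0 - 0.5**selfing_generations


def draw_positions(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Variant positions: exponential spacings along each chromosome."""
    rng = config.rng("positions")
    chroms, positions = [], []
    for name in config.chrom_names():
        # draw enough spacings to cover the chromosome, then trim
        n_guess = int(config.chrom_length / config.snp_spacing_mean * 1.5) + 100
        gaps = rng.exponential(config.snp_spacing_mean, size=n_guess)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = np.unique(pos[pos < config.chrom_length])
        chroms.append(np.repeat(name, len(pos)))
        positions.append(pos)
    return np.concatenate(chroms), np.concatenate(positions)


def _balding_nichols(rng: np.random.Generator, parent: np.ndarray, fst: float) -> np.ndarray:
    """Daughter frequencies drifted from ``parent``.

    The beta's variance coefficient is 2*fst so that Hudson's FST between
    the parent and daughter populations equals the nominal ``fst`` (one-step
    drift contributes only to the daughter's side of the estimator).
    """
    v = 2.0 * fst
    theta = (1.0 - v) / v
    p = np.clip(parent, 1e-6, 1.0 - 1e-6)
    return rng.beta(p * theta, (1.0 - p) * theta)


def draw_subpop_frequencies(config: SimConfig) -> FreqTable:
    """Hierarchical drift wild -> landrace -> improved on a shared variant grid."""
    chrom, pos = draw_positions(config)
    rng = config.rng("frequencies")
    m = len(pos)
    wild = rng.uniform(0.05, 0.95, size=m)
    landrace = _balding_nichols(rng, wild, config.fst_wild_landrace)
    improved = _balding_nichols(rng, landrace, config.fst_landrace_improved)
    return FreqTable(freqs=np.stack([wild, landrace, improved]), chrom=chrom, pos=pos)


def hudson_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Hudson-style FST (1 - Hw/Hb, ratio of sums) from two frequency vectors."""
    q1, q2 = 1.0 - p1, 1.0 - p2
    hw = p1 * q1 + p2 * q2
    hb = p1 * q2 + p2 * q1
    return float(1.0 - hw.sum() / hb.sum())


def simulate_haplotypes(freqs: FreqTable, config: SimConfig) -> HaplotypePool:
    """Founder-mosaic haplotype pools with block-wise LD.

    Each subpopulation gets ``2 * n`` haplotypes (two per prospective
    individual).  Chromosomes are partitioned into exponentially distributed
    blocks; within a block every haplotype copies one founder, chosen
    independently per block, so LD is strong within blocks and decays across
    boundaries.
    """
    if config.n_founder_haplotypes < 1:
        raise ValueError("need at least one founder haplotype")
    rng = config.rng("haplotypes")
    haplotypes: dict[str, np.ndarray] = {}
    founders: dict[str, np.ndarray] = {}
    sizes = config.subpop_sizes
    for subpop in SUBPOPS:
        p = freqs.for_subpop(subpop)
        m = len(p)
        fndrs = (rng.random((config.n_founder_haplotypes, m)) < p).astype(np.uint8)
        n_haps = 2 * sizes[subpop]
        pool = np.empty((n_haps, m), dtype=np.uint8)
        for name in np.unique(freqs.chrom):
            cols = np.flatnonzero(freqs.chrom == name)
            cpos = freqs.pos[cols]
            # block boundaries shared across haplotypes of this subpop
            n_blocks_guess = int(config.chrom_length / config.block_length_mean * 2) + 10
            edges = np.cumsum(rng.exponential(config.block_length_mean, size=n_blocks_guess))
            while edges[-1] < config.chrom_length:
                edges = np.concatenate(
                    [edges, edges[-1] + np.cumsum(rng.exponential(config.block_length_mean, 10))]
                )
            block_of = np.searchsorted(edges, cpos, side="right")
            n_blocks = int(block_of.max()) + 1
            choice = rng.integers(0, config.n_founder_haplotypes, size=(n_haps, n_blocks))
            pool[:, cols] = fndrs[choice[:, block_of], cols[None, :]]
        haplotypes[subpop] = pool
        founders[subpop] = fndrs
    return HaplotypePool(haplotypes=haplotypes, founders=founders,
                         chrom=freqs.chrom, pos=freqs.pos)


def plant_sweep(
    pool: HaplotypePool,
    region: Region,
    stage: str,
    carrier_fraction: float,
    rng: np.random.Generator,
) -> HaplotypePool:
    """Overwrite a fraction of haplotypes in ``region`` with one founder mosaic.

    Only the stage's target subpopulation(s) are touched (domestication:
    landraces and improved; improvement: improved only), so the ancestral
    group keeps its diversity and the windowed pi-ratio rises in the region.
    Returns a modified copy; the input pool is untouched.
    """
    if stage not in STAGE_TARGETS:
        raise ValueError(f"unknown sweep stage {stage!r}; expected one of {STAGES}")
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    out = pool.copy()
    cols = np.flatnonzero(
        (pool.chrom == region.chrom) & (pool.pos >= region.start) & (pool.pos < region.end)
    )
    if len(cols) == 0 or carrier_fraction == 0.0:
        return out
    for subpop in STAGE_TARGETS[stage]:
        haps = out.haplotypes[subpop]
        n_carriers = int(round(carrier_fraction * haps.shape[0]))
        carriers = rng.choice(haps.shape[0], size=n_carriers, replace=False)
        haps[np.ix_(carriers, cols)] = out.founders[subpop][0, cols][None, :]
    return out


def diploids_from_selfing(
    pool: HaplotypePool, selfing_generations: int, rng: np.random.Generator
) -> tuple[GenotypeMatrix, float]:
    """Pair pool haplotypes into diploids with selfing-induced autozygosity.

    Individual i receives haplotypes 2i and 2i+1 of its subpopulation's
    pool; with probability F = 1 - (1/2)**selfing_generations the second is
    replaced by a copy of the first.  Returns the genotype matrix and the
    realized autozygous fraction.
    """
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    f_expected = expected_inbreeding(selfing_generations)
    genotype_rows, labels, names = [], [], []
    n_autozygous = n_total = 0
    prefix = {"wild": "W", "landrace": "L", "improved": "I"}
    for subpop in SUBPOPS:
        haps = pool.haplotypes[subpop]
        n_ind = haps.shape[0] // 2
        auto = rng.random(n_ind) < f_expected
        for i in range(n_ind):
            a = haps[2 * i]
            b = a if auto[i] else haps[2 * i + 1]
            genotype_rows.append((a.astype(np.int8) + b.astype(np.int8)))
            labels.append(subpop)
            names.append(f"{prefix[subpop]}{i + 1:03d}")
        n_autozygous += int(auto.sum())
        n_total += n_ind
    m = len(pool.pos)
    ref = np.repeat("A", m)
    alt = np.repeat("T", m)
    gm = GenotypeMatrix(
        genotypes=np.array(genotype_rows, dtype=np.int8),
        chrom=pool.chrom,
        pos=pool.pos,
        ref=ref,
        alt=alt,
        samples=np.array(names),
        subpop=np.array(labels),
    )
    realized_f = n_autozygous / n_total if n_total else 0.0
    return gm, realized_f


def simulate_qualitative_trait(
    G: GenotypeMatrix,
    locus: int,
    dominant_allele: str = "alt",
    misclassification_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary phenotype under complete dominance at one locus.

    Phenotype 1 iff the individual carries at least one copy of the dominant
    allele; each phenotype then flips independently with
    ``misclassification_rate``.  Missing genotypes give nan phenotypes.
    """
    if dominant_allele not in ("ref", "alt"):
        raise ValueError("dominant_allele must be 'ref' or 'alt'")
    if rng is None:
        rng = np.random.default_rng()
    g = G.genotypes[:, locus].astype(float)
    g[G.genotypes[:, locus] == MISSING] = np.nan
    valid = ~np.isnan(g)
    if len(np.unique(g[valid])) < 2:
        warnings.warn(f"trait locus {locus} is monomorphic; trait will not segregate")
    if dominant_allele == "alt":
        y = (g >= 1).astype(float)
    else:
        y = (g <= 1).astype(float)
    flip = rng.random(len(y)) < misclassification_rate
    y[flip] = 1.0 - y[flip]
    y[~valid] = np.nan
    return y


def simulate_quantitative_trait(
    G: GenotypeMatrix,
    loci: list[int],
    effects: list[float],
    heritability: float,
    subpop_shifts: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Additive polygenic phenotype with noise scaled to a target heritability.

    y = sum(effect * dosage) + group shift + N(0, s^2) with s chosen so
    that Var(genetic) / (Var(genetic) + s^2) = heritability, computed on the
    realized dosages.  Missing dosages are replaced by the locus mean.
    """
    if not 0.0 < heritability <= 1.0:
        raise ValueError("heritability must be in (0, 1]")
    if len(loci) != len(effects):
        raise ValueError("loci and effects must have the same length")
    if rng is None:
        rng = np.random.default_rng()
    dos = G.genotypes[:, loci].astype(float)
    dos[dos == MISSING] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(col_mean, inds[1])
    genetic = dos @ np.asarray(effects, dtype=float)
    var_g = float(np.var(genetic))
    if var_g == 0.0 and heritability < 1.0:
        raise ValueError("zero genetic variance: cannot scale noise to the target heritability")
    noise_sd = 0.0 if heritability == 1.0 else np.sqrt(var_g * (1.0 - heritability) / heritability)
    y = genetic + rng.normal(0.0, noise_sd, size=len(genetic))
    if subpop_shifts:
        if G.subpop is None:
            raise ValueError("subpop_shifts given but genotype matrix has no labels")
        for name, shift in subpop_shifts.items():
            y[G.subpop == name] += shift
    return y


def degrade_genotypes(
    G: GenotypeMatrix,
    hom_accuracy: float = 0.9359,
    het_accuracy: float = 0.8382,
    missing_rate: float = 0.03,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Low-coverage genotyping noise: missingness, miscalls, synthetic GQ.

    Each genotype independently goes missing with ``missing_rate``.
    Surviving homozygotes are miscalled with 1 - hom_accuracy (80% of these
    errors become heterozygotes, 20% the opposite homozygote, mimicking the
    dominant error mode of low-depth callers); heterozygotes are miscalled
    with 1 - het_accuracy (to either homozygote with equal probability).
    A synthetic GQ is drawn from one of two discrete distributions so that
    miscalled genotypes are concentrated at low GQ.
    """
    for name, v in (("hom_accuracy", hom_accuracy), ("het_accuracy", het_accuracy),
                    ("missing_rate", missing_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    g = G.genotypes.copy()
    shape = g.shape
    observed = g != MISSING

    drop = (rng.random(shape) < missing_rate) & observed
    called = observed & ~drop

    is_hom = called & ((g == 0) | (g == 2))
    is_het = called & (g == 1)
    u = rng.random(shape)
    hom_err = is_hom & (u >= hom_accuracy)
    het_err = is_het & (u >= het_accuracy)

    out = g.copy()
    # homozygote errors: 80% to het, 20% to the opposite homozygote
    v = rng.random(shape)
    to_het = hom_err & (v < 0.8)
    to_opp = hom_err & ~to_het
    out[to_het] = 1
    out[to_opp] = 2 - g[to_opp]
    # heterozygote errors: either homozygote, equal odds
    out[het_err] = np.where(v[het_err] < 0.5, 0, 2).astype(np.int8)
    out[drop] = MISSING
    out[~observed] = MISSING

    miscalled = hom_err | het_err
    gq = np.zeros(shape, dtype=np.int16)
    correct = called & ~miscalled
    gq[correct] = rng.choice(GQ_CORRECT_VALUES, size=int(correct.sum()), p=GQ_CORRECT_PROBS)
    gq[miscalled] = rng.choice(GQ_MISCALL_VALUES, size=int(miscalled.sum()), p=GQ_MISCALL_PROBS)

    res = G.copy()
    res.genotypes = out
    res.gq = gq
    return res


@dataclass
class SimResult:
    """Everything one simulation produces."""

    genotypes: GenotypeMatrix  # noisy, with GQ
    clean_genotypes: GenotypeMatrix
    phenotypes: "pandas.DataFrame"  # noqa: F821 - imported lazily
    truth: TruthSet
    freqs: FreqTable


def _pick_trait_loci(
    G: GenotypeMatrix, n: int, min_maf: float, rng: np.random.Generator,
    exclude: set[int],
) -> list[int]:
    p = allele_frequencies(G.genotypes)
    maf = np.minimum(p, 1 - p)
    eligible = np.flatnonzero((maf >= min_maf) & ~np.isin(np.arange(len(maf)), list(exclude)))
    if len(eligible) < n:
        raise ValueError(f"not enough variants with MAF >= {min_maf} to place trait loci")
    return sorted(rng.choice(eligible, size=n, replace=False).tolist())


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: frequencies -> haplotypes -> sweeps ->
    diploids -> traits -> genotyping noise, with a truth set."""
    import pandas as pd

    freqs = draw_subpop_frequencies(config)
    pool = simulate_haplotypes(freqs, config)

    sweep_rng = config.rng("sweeps")
    sweep_records = []
    for s in config.sweep_specs:
        pool = plant_sweep(
            pool, Region(s.chrom, s.start, s.end), s.stage, s.carrier_fraction, sweep_rng
        )
        sweep_records.append(dataclasses.asdict(s))

    clean, realized_f = diploids_from_selfing(pool, config.selfing_generations, config.rng("diploids"))

    trait_rng = config.rng("traits")
    pheno = pd.DataFrame(index=pd.Index(clean.samples, name="sample_id"))
    causal: list[dict] = []
    used: set[int] = set()
    for spec in config.qualitative_traits:
        locus = spec.locus_index
        if locus is None:
            locus = _pick_trait_loci(clean, 1, spec.min_maf, trait_rng, used)[0]
        used.add(locus)
        y = simulate_qualitative_trait(
            clean, locus, spec.dominant_allele, spec.misclassification_rate, trait_rng
        )
        pheno[spec.name] = y
        causal.append({
            "trait": spec.name, "mode": f"dominant_{spec.dominant_allele}",
            "variant_index": int(locus), "chrom": str(clean.chrom[locus]),
            "pos": int(clean.pos[locus]), "effect": 1.0,
        })
    for spec in config.quantitative_traits:
        loci = spec.loci
        if loci is None:
            loci = _pick_trait_loci(clean, spec.n_loci, spec.min_maf, trait_rng, used)
        used.update(loci)
        effects = spec.effects if spec.effects is not None else [1.0] * len(loci)
        y = simulate_quantitative_trait(
            clean, loci, effects, spec.heritability, spec.subpop_shifts, trait_rng
        )
        pheno[spec.name] = y
        for locus, eff in zip(loci, effects):
            causal.append({
                "trait": spec.name, "mode": "additive",
                "variant_index": int(locus), "chrom": str(clean.chrom[locus]),
                "pos": int(clean.pos[locus]), "effect": float(eff),
            })

    noisy = degrade_genotypes(
        clean, config.hom_accuracy, config.het_accuracy, config.missing_rate, config.rng("noise")
    )

    truth = TruthSet(
        causal_loci=causal,
        sweep_regions=sweep_records,
        inbreeding_coefficient=realized_f,
        seed=config.seed,
        params={
            "n_samples": config.n_samples,
            "n_variants": int(clean.n_variants),
            "selfing_generations": config.selfing_generations,
            "expected_inbreeding": expected_inbreeding(config.selfing_generations),
        },
    )
    return SimResult(genotypes=noisy, clean_genotypes=clean, phenotypes=pheno,
                     truth=truth, freqs=freqs)
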
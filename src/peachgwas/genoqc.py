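"""Variant-level quality control.

Implements the QC chain of a two-caller resequencing workflow: intersection
of the site lists reported by two variant callers, removal of rare alleles
and high-missingness variants, masking of low-confidence genotypes by GQ,
and sporadic-missing imputation from within-window genotype frequencies.

Boundary semantics, fixed once: a variant is removed iff its minor-allele
frequency is strictly below ``min_freq``; removed iff its missing fraction
is strictly above ``max_missing``; a genotype is masked iff GQ <= threshold.
The default chain order is mask -> missingness filter -> MAF filter ->
imputation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, minor_allele_frequencies

logger = logging.getLogger(__name__)

VariantKey = tuple  # (chrom, pos, ref, alt)


@dataclass(frozen=True)
class CallSet:
    """The set of variant sites reported by one caller."""

    keys: frozenset

    @classmethod
    def from_arrays(cls, chrom, pos, ref, alt) -> "CallSet":
        return cls(frozenset(zip(map(str, chrom), map(int, pos), map(str, ref), map(str, alt))))

    @classmethod
    def from_genotype_matrix(cls, G: GenotypeMatrix) -> "CallSet":
        return cls.from_arrays(G.chrom, G.pos, G.ref, G.alt)

    def __len__(self) -> int:
        return len(self.keys)


def intersect_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Sites reported by both callers: exact intersection on (chrom, pos, ref, alt)."""
    return CallSet(a.keys & b.keys)


def restrict_to_callset(G: GenotypeMatrix, calls: CallSet) -> GenotypeMatrix:
    """Keep only the variants of ``G`` present in ``calls``."""
    keep = np.array(
        [(str(c), int(p), str(r), str(a)) in calls.keys
         for c, p, r, a in zip(G.chrom, G.pos, G.ref, G.alt)]
    )
    return G.take_variants(keep)


@dataclass
class QCReport:
    """Per-stage variant counts and the parameters applied."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, **params) -> None:
        if self.stages and n_in > self.stages[-1]["n_out"]:
            raise ValueError("QC stage input exceeds previous stage output")
        if n_out > n_in:
            raise ValueError("QC stage cannot increase the variant count")
        self.stages.append({"stage": stage, "n_in": n_in, "n_out": n_out, "params": params})

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages}, indent=2)


def filter_rare_alleles(
    G: GenotypeMatrix, min_freq: float, report: QCReport | None = None
) -> GenotypeMatrix:
    """Remove variants with minor-allele frequency strictly below ``min_freq``.

    Frequency is computed on allele copies among non-missing genotypes.
    All-missing variants count as MAF 0 and are removed.
    """
    if not 0.0 <= min_freq <= 0.5:
        raise ValueError("min_freq must be in [0, 0.5]")
    maf = minor_allele_frequencies(G.genotypes)
    all_missing = np.isnan(maf)
    if all_missing.any():
        logger.info("filter_rare_alleles: %d all-missing variants treated as MAF 0",
                    int(all_missing.sum()))
    maf = np.where(all_missing, 0.0, maf)
    keep = maf >= min_freq
    if report is not None:
        report.record("maf_filter", G.n_variants, int(keep.sum()), min_freq=min_freq)
    return G.take_variants(keep)


def filter_missingness(
    G: GenotypeMatrix, max_missing: float = 0.20, report: QCReport | None = None
) -> GenotypeMatrix:
    """Remove variants whose missing fraction strictly exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = G.missing_mask().mean(axis=0)
    keep = frac <= max_missing
    if report is not None:
        report.record("missingness_filter", G.n_variants, int(keep.sum()),
                      max_missing=max_missing)
    return G.take_variants(keep)


def mask_low_confidence(
    G: GenotypeMatrix, threshold: int = 3, *, mask_if_no_gq: bool = False,
    report: QCReport | None = None,
) -> GenotypeMatrix:
    """Set genotypes with GQ <= ``threshold`` to missing.

    When the matrix has no GQ annotation the default is to keep everything
    (logged); set ``mask_if_no_gq`` to treat absent GQ as failing.
    """
    out = G.copy()
    if G.gq is None:
        if mask_if_no_gq:
            out.genotypes[:, :] = MISSING
        else:
            logger.info("mask_low_confidence: no GQ annotation; genotypes kept")
        if report is not None:
            report.record("gq_mask", G.n_variants, G.n_variants, threshold=threshold,
                          gq_present=False)
        return out
    mask = (G.gq <= threshold) & (out.genotypes != MISSING)
    out.genotypes[mask] = MISSING
    if report is not None:
        report.record("gq_mask", G.n_variants, G.n_variants, threshold=threshold,
                      masked_genotypes=int(mask.sum()))
    return out


def impute_sporadic(
    G: GenotypeMatrix,
    window_snps: int = 50_000,
    *,
    deterministic: bool = True,
    by_subpop: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Fill sporadic missing genotypes from per-variant genotype frequencies.

    Each missing call is replaced by the modal genotype (deterministic mode)
    or a draw from the empirical genotype distribution of the same variant,
    restricted to the sample's subpopulation when labels are present and
    that subpopulation has at least one observed call.  ``window_snps``
    bounds the marker context retained per pass and is kept for interface
    compatibility with haplotype imputers; the frequency model itself is
    per-variant.  Variants with no observed calls at all are left missing.

    Returns the imputed matrix and a boolean mask of imputed entries.
    Observed genotypes are never altered.
    """
    if rng is None:
        rng = np.random.default_rng()
    out = G.copy()
    g = out.genotypes
    imputed = np.zeros_like(g, dtype=bool)
    groups: list[np.ndarray]
    if by_subpop and G.subpop is not None:
        groups = [np.flatnonzero(G.subpop == s) for s in np.unique(G.subpop)]
    else:
        groups = [np.arange(G.n_samples)]
    all_idx = np.arange(G.n_samples)
    n_unimputable = 0
    for j in np.flatnonzero((g == MISSING).any(axis=0)):
        col = g[:, j]
        for rows in groups:
            miss = rows[col[rows] == MISSING]
            if len(miss) == 0:
                continue
            obs = col[rows][col[rows] != MISSING]
            if len(obs) == 0:  # fall back to the whole sample set
                obs = col[all_idx][col[all_idx] != MISSING]
            if len(obs) == 0:
                n_unimputable += len(miss)
                continue
            counts = np.bincount(obs, minlength=3)
            if deterministic:
                fill = np.argmax(counts)  # ties -> lowest genotype
                g[miss, j] = fill
            else:
                g[miss, j] = rng.choice(3, size=len(miss), p=counts / counts.sum())
            imputed[miss, j] = True
    if n_unimputable:
        logger.warning("impute_sporadic: %d genotypes left missing (no observed calls)",
                       n_unimputable)
    return out, imputed


def run_qc_chain(
    G: GenotypeMatrix,
    *,
    gq_threshold: int = 3,
    max_missing: float = 0.20,
    min_freq: float = 0.05,
    impute: bool = True,
    deterministic_impute: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Default QC chain: GQ mask -> missingness filter -> MAF filter -> impute."""
    report = QCReport()
    report.record("input", G.n_variants, G.n_variants)
    G = mask_low_confidence(G, gq_threshold, report=report)
    G = filter_missingness(G, max_missing, report=report)
    G = filter_rare_alleles(G, min_freq, report=report)
    if impute:
        G, imputed = impute_sporadic(G, deterministic=deterministic_impute, rng=rng)
        report.record("imputation", G.n_variants, G.n_variants,
                      imputed_genotypes=int(imputed.sum()))
    return G, report
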
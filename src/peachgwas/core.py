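"""Shared in-memory containers for the pipeline.

Genotypes are stored as a dense ``samples x variants`` int8 matrix of
alternate-allele dosages (0 = reference homozygote, 1 = heterozygote,
2 = alternate homozygote) with ``-1`` marking missing calls.  All genomic
intervals held in memory are 0-based half-open; conversion to the 1-based
coordinates of VCF happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with variant metadata and sample labels.

    Attributes
    ----------
    genotypes : (n_samples, n_variants) int8 array, values in {-1, 0, 1, 2}
    chrom : (n_variants,) array of chromosome names
    pos : (n_variants,) int64 array of 0-based positions
    ref, alt : (n_variants,) arrays of alleles
    samples : sample identifiers
    subpop : per-sample group label (e.g. wild / landrace / improved), or None
    gq : optional (n_samples, n_variants) int16 genotype-quality matrix
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: np.ndarray
    subpop: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.samples = np.asarray(self.samples)
        if self.subpop is not None:
            self.subpop = np.asarray(self.subpop)
        n, m = self.genotypes.shape
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == m):
            raise ValueError("variant metadata length does not match genotype matrix")
        if len(self.samples) != n:
            raise ValueError("sample list length does not match genotype matrix")
        if self.gq is not None and self.gq.shape != (n, m):
            raise ValueError("GQ matrix shape does not match genotypes")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to the variants selected by ``idx`` (bool mask or indices)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            samples=self.samples,
            subpop=self.subpop,
            gq=self.gq[:, idx] if self.gq is not None else None,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[idx, :],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            samples=self.samples[idx],
            subpop=self.subpop[idx] if self.subpop is not None else None,
            gq=self.gq[idx, :] if self.gq is not None else None,
        )

    def sample_indices(self, group: str | Sequence[str]) -> np.ndarray:
        """Indices of samples whose subpopulation label is in ``group``."""
        if self.subpop is None:
            raise ValueError("genotype matrix carries no subpopulation labels")
        if isinstance(group, str):
            group = [group]
        return np.flatnonzero(np.isin(self.subpop, list(group)))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            samples=self.samples.copy(),
            subpop=None if self.subpop is None else self.subpop.copy(),
            gq=None if self.gq is None else self.gq.copy(),
        )


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per variant, over non-missing diploids.

    Frequencies are counted on allele copies: two per homozygote, one per
    heterozygote.  All-missing variants yield ``nan``.
    """
    g = np.asarray(genotypes)
    called = g != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt_copies = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt_copies / np.maximum(n_alleles, 1), np.nan)


def minor_allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    p = allele_frequencies(genotypes)
    return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class Region:
    """A 0-based half-open chromosome interval with optional score/label."""

    chrom: str
    start: int
    end: int
    score: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start (got {self.chrom}:{self.start}-{self.end}); "
                "check the coordinate convention"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Region") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(regions: Sequence[Region]) -> list[Region]:
    """Union of overlapping or bookended intervals, per chromosome.

    The merged region's score is the maximum of its members' scores.
    """
    merged: list[Region] = []
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur = rs[0]
        for r in rs[1:]:
            if r.start <= cur.end:  # overlap or bookended
                score = np.nanmax([cur.score, r.score])
                cur = Region(chrom, cur.start, max(cur.end, r.end), float(score), cur.label)
            else:
                merged.append(cur)
                cur = r
        merged.append(cur)
    return merged
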
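"""Linkage disequilibrium from unphased diploids.

Two-locus haplotype frequencies are estimated by EM under random pairing
(the only ambiguous configuration is the double heterozygote, whose two
phasings are weighted by their current relative likelihood).  From the
fitted frequencies: D = f_AB f_ab - f_Ab f_aB, D' = |D| / D_max, and
r^2 = D^2 / (pA qA pB qB).  Both r^2 and D' therefore share one estimand;
a genotype-correlation r^2 is available as an alternative.

Windowed summaries average pairwise D' and r^2 over variant pairs inside
non-overlapping blocks; the D'/r^2 ratio of a block flags regions where
recombination history (D') remains strong but mutational history has
decoupled alleles (low r^2) — the signature of variants fixed clonally
without recombination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

EM_TOL = 1e-8
EM_MAX_ITER = 1000


class MonomorphicError(ValueError):
    """LD is undefined when either variant is monomorphic among used samples."""


@dataclass
class LDStats:
    f_ab: tuple[float, float, float, float]  # (f_AB, f_Ab, f_aB, f_ab)
    D: float
    Dprime: float
    r2: float
    n: int


def _genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, int]:
    """3x3 table of joint genotype counts over pairwise-complete samples."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok].astype(int), g2[ok].astype(int)
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    return counts, int(ok.sum())


def em_haplotype_frequencies(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[float, float, float, float]:
    """ML two-locus haplotype frequencies (f_AB, f_Ab, f_aB, f_ab) by EM.

    A is the alternate allele at locus 1, B at locus 2.  Converges when the
    largest frequency change drops below 1e-8, or after 1000 iterations.
    """
    counts, n = _genotype_pair_counts(np.asarray(g1), np.asarray(g2))
    if n < 2:
        raise ValueError("need at least two pairwise-complete samples")
    pA = counts.sum(axis=1) @ np.array([0.0, 0.5, 1.0]) / n
    pB = counts.sum(axis=0) @ np.array([0.0, 0.5, 1.0]) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicError("monomorphic variant: LD undefined")

    # phase-known haplotype-copy contributions: for genotype (i A-copies,
    # j B-copies) that is not the double heterozygote, the two haplotypes
    # are determined: AB = max(0, i+j-2), ab = max(0, 2-i-j), Ab = i - AB,
    # aB = j - AB.
    base = np.zeros(4)  # AB, Ab, aB, ab
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            n_AB = max(0, i + j - 2)
            n_ab = max(0, 2 - i - j)
            base[0] += c * n_AB
            base[1] += c * (i - n_AB)
            base[2] += c * (j - n_AB)
            base[3] += c * n_ab

    n_dh = counts[1, 1]  # double heterozygotes: AB/ab vs Ab/aB
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-10, None)
    f /= f.sum()
    total = 2.0 * n
    for _ in range(EM_MAX_ITER):
        cis = f[0] * f[3]  # AB/ab
        trans = f[1] * f[2]  # Ab/aB
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = base.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= total
        if np.max(np.abs(new - f)) < EM_TOL:
            f = new
            break
        f = new
    return tuple(float(x) for x in f)


def ld_from_frequencies(f_AB: float, f_Ab: float, f_aB: float, f_ab: float,
                        n: int = 0) -> LDStats:
    """D, D' and r^2 from a haplotype frequency table."""
    pA = f_AB + f_Ab
    pB = f_AB + f_aB
    qA, qB = 1.0 - pA, 1.0 - pB
    D = f_AB * f_ab - f_Ab * f_aB
    denom = pA * qA * pB * qB
    if denom <= 0:
        raise MonomorphicError("monomorphic frequencies: LD undefined")
    r2 = D * D / denom
    if D > 0:
        dmax = min(pA * qB, qA * pB)
    elif D < 0:
        dmax = min(pA * pB, qA * qB)
    else:
        dmax = 1.0
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    return LDStats(f_ab=(f_AB, f_Ab, f_aB, f_ab), D=D, Dprime=min(dprime, 1.0),
                   r2=min(r2, 1.0), n=n)


def pairwise_ld(g1: np.ndarray, g2: np.ndarray, method: str = "em") -> LDStats:
    """LD statistics for one variant pair from unphased genotypes.

    ``em`` (default) derives D, D' and r^2 from EM haplotype frequencies;
    ``corr`` replaces r^2 with the squared genotype-dosage correlation
    (D and D' still come from EM).
    """
    f = em_haplotype_frequencies(g1, g2)
    counts, n = _genotype_pair_counts(np.asarray(g1), np.asarray(g2))
    stats = ld_from_frequencies(*f, n=n)
    if method == "corr":
        ok = (np.asarray(g1) != MISSING) & (np.asarray(g2) != MISSING)
        r = np.corrcoef(g1[ok].astype(float), g2[ok].astype(float))[0, 1]
        stats = LDStats(f_ab=stats.f_ab, D=stats.D, Dprime=stats.Dprime,
                        r2=float(r * r), n=n)
    elif method != "em":
        raise ValueError(f"unknown LD method {method!r}")
    return stats


def windowed_ld(
    G: GenotypeMatrix,
    block: int = 50_000,
    max_pairs: int | None = 300,
    rng: np.random.Generator | None = None,
    method: str = "em",
) -> pd.DataFrame:
    """Mean pairwise D' and r^2 per non-overlapping block.

    All within-block variant pairs with defined LD enter the means; dense
    blocks are subsampled to ``max_pairs`` pairs (seeded) to stay tractable.
    Blocks with fewer than two usable variants are reported with nan means.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for chrom in np.unique(G.chrom):
        cols = np.flatnonzero(G.chrom == chrom)
        pos = G.pos[cols]
        order = np.argsort(pos)
        cols, pos = cols[order], pos[order]
        last = int(pos.max()) if len(pos) else 0
        for start in range(0, last + 1, block):
            end = start + block
            inblock = cols[(pos >= start) & (pos < end)]
            if len(inblock) < 2:
                rows.append((chrom, start, end, np.nan, np.nan, np.nan, 0))
                continue
            pairs = [(i, j) for k, i in enumerate(inblock) for j in inblock[k + 1:]]
            if max_pairs is not None and len(pairs) > max_pairs:
                sel = rng.choice(len(pairs), size=max_pairs, replace=False)
                pairs = [pairs[s] for s in sel]
            r2s, dps = [], []
            for i, j in pairs:
                try:
                    s = pairwise_ld(G.genotypes[:, i], G.genotypes[:, j], method=method)
                except (MonomorphicError, ValueError):
                    continue
                r2s.append(s.r2)
                dps.append(s.Dprime)
            if not r2s:
                rows.append((chrom, start, end, np.nan, np.nan, np.nan, 0))
                continue
            mr2, mdp = float(np.mean(r2s)), float(np.mean(dps))
            ratio = mdp / mr2 if mr2 > 0 else np.nan
            rows.append((chrom, start, end, mr2, mdp, ratio, len(r2s)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_r2",
                                       "mean_dprime", "dprime_r2", "n_pairs"])


def dprime_r2_blocks(
    windows: pd.DataFrame, top_fraction: float = 0.005, min_r2: float = 0.01
) -> pd.DataFrame:
    """Flag blocks in the top tail of the D'/r^2 ratio.

    Blocks with mean r^2 below ``min_r2`` are excluded from the ranking so
    near-equilibrium windows cannot dominate through a vanishing
    denominator.  Ties at the threshold are all flagged.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    eligible = windows[
        windows["mean_r2"].notna() & (windows["mean_r2"] >= min_r2)
        & windows["dprime_r2"].notna()
    ]
    if eligible.empty:
        raise ValueError("no blocks eligible for D'/r^2 ranking")
    vals = np.sort(eligible["dprime_r2"].to_numpy())
    k = max(1, int(np.ceil(top_fraction * len(vals))))
    threshold = vals[len(vals) - k]
    out = windows.copy()
    out["flagged"] = False
    out.loc[eligible.index[eligible["dprime_r2"] >= threshold], "flagged"] = True
    return out


def tag_snp_estimate(genome_length_bp: float, ld_decay_bp: float) -> int:
    """Markers needed to tile a genome at one per LD-decay distance."""
    if genome_length_bp <= 0 or ld_decay_bp <= 0:
        raise ValueError("genome length and LD decay must be positive")
    return math.floor(genome_length_bp / ld_decay_bp)
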
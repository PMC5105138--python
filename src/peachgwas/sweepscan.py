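"""Windowed nucleotide diversity and pi-ratio selective-sweep scanning.

The scan contrasts an ancestral with a derived sample group (wild vs
landrace for domestication, landrace vs improved for improvement): windows
where the ancestral-to-derived diversity ratio is in the top tail are
candidate sweeps.  Diversity is the per-bp expected pairwise difference
pi, computed per SNP from genotype allele counts with the unbiased
2n/(2n-1) correction and summed over a sliding window.

Window grids are 0-based half-open, anchored at position 0; the final
partial window is kept when it is at least half a window long.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Region, merge_intervals

INF_RATIO = np.inf


@dataclass
class PiTrack:
    """Per-window nucleotide diversity for one sample group."""

    table: pd.DataFrame  # chrom, start, end, pi, n_snps
    group: str
    window: int
    step: int

    def same_grid(self, other: "PiTrack") -> bool:
        a, b = self.table, other.table
        return (len(a) == len(b)
                and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
                and (a["start"].to_numpy() == b["start"].to_numpy()).all()
                and (a["end"].to_numpy() == b["end"].to_numpy()).all())


def per_site_pi(genotypes: np.ndarray) -> np.ndarray:
    """Unbiased per-site diversity from diploid genotypes.

    pi_site = (2n / (2n - 1)) * 2 p (1 - p) with n the non-missing diploid
    count — the mean pairwise difference over all C(2n, 2) chromosome pairs.
    Sites with fewer than two called chromosomes give 0.
    """
    g = np.asarray(genotypes)
    called = g != MISSING
    n2 = 2 * called.sum(axis=0)  # chromosomes
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n2 > 0, alt / np.maximum(n2, 1), 0.0)
        corr = np.where(n2 > 1, n2 / np.maximum(n2 - 1, 1), 0.0)
    return corr * 2.0 * p * (1.0 - p)


def window_grid(chrom_lengths: dict[str, int], window: int, step: int) -> pd.DataFrame:
    """Sliding-window grid; trailing partial windows kept if >= window/2."""
    rows = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        start = 0
        while start < L:
            end = min(start + window, L)
            if end - start >= window / 2:
                rows.append((chrom, start, end))
            if start + window >= L:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def windowed_pi(
    G: GenotypeMatrix,
    group: str | list[str],
    window: int = 50_000,
    step: int = 5_000,
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> PiTrack:
    """Per-bp pi in sliding windows for one subpopulation group.

    Window pi is the sum of per-site pi over SNPs in the window divided by
    the window length in bp.  Windows with fewer than ``min_snps`` SNPs are
    reported with pi = nan so they drop out of downstream quantiles.
    """
    if window < step:
        raise ValueError("window must be >= step")
    idx = G.sample_indices(group)
    if len(idx) == 0:
        raise ValueError(f"group {group!r} selects no samples")
    sub = G.genotypes[idx, :]
    site_pi = per_site_pi(sub)
    if chrom_lengths is None:
        chrom_lengths = {str(c): int(G.pos[G.chrom == c].max()) + 1 for c in np.unique(G.chrom)}
    grid = window_grid(chrom_lengths, window, step)
    pis = np.full(len(grid), np.nan)
    counts = np.zeros(len(grid), dtype=int)
    for chrom in np.unique(G.chrom):
        cols = np.flatnonzero(G.chrom == chrom)
        pos = G.pos[cols]
        order = np.argsort(pos)
        pos = pos[order]
        sp = site_pi[cols][order]
        csum = np.concatenate([[0.0], np.cumsum(sp)])
        rows = np.flatnonzero(grid["chrom"].to_numpy() == chrom)
        starts = grid["start"].to_numpy()[rows]
        ends = grid["end"].to_numpy()[rows]
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        counts[rows] = hi - lo
        with np.errstate(invalid="ignore"):
            vals = (csum[hi] - csum[lo]) / (ends - starts)
        vals[counts[rows] < min_snps] = np.nan
        pis[rows] = vals
    table = grid.assign(pi=pis, n_snps=counts)
    gname = group if isinstance(group, str) else "+".join(group)
    return PiTrack(table=table, group=gname, window=window, step=step)


def diversity_ratio(pi_ancestral: PiTrack, pi_derived: PiTrack) -> pd.DataFrame:
    """Per-window pi_ancestral / pi_derived on a shared grid.

    Derived pi = 0 with ancestral pi > 0 maps to +inf (ranked highest);
    both zero, or either missing, maps to nan.
    """
    if not pi_ancestral.same_grid(pi_derived):
        raise ValueError("pi tracks are on different window grids")
    a = pi_ancestral.table["pi"].to_numpy()
    d = pi_derived.table["pi"].to_numpy()
    ratio = np.full(len(a), np.nan)
    both = ~np.isnan(a) & ~np.isnan(d)
    pos = both & (d > 0)
    ratio[pos] = a[pos] / d[pos]
    inf = both & (d == 0) & (a > 0)
    ratio[inf] = INF_RATIO
    out = pi_ancestral.table[["chrom", "start", "end"]].copy()
    out["pi_ancestral"] = a
    out["pi_derived"] = d
    out["ratio"] = ratio
    return out


def call_sweeps(ratios: pd.DataFrame, top_fraction: float = 0.05) -> pd.DataFrame:
    """Windows whose ratio reaches the top ``top_fraction`` empirical quantile.

    Ties at the threshold are all included, so the selected count is at
    least ceil(top_fraction * n_windows).
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    r = ratios["ratio"].to_numpy()
    valid = ~np.isnan(r)
    if not valid.any():
        raise ValueError("all windows missing: nothing to rank")
    vals = np.sort(r[valid])
    k = int(np.ceil(top_fraction * len(vals)))
    threshold = vals[len(vals) - k]
    return ratios[valid & (r >= threshold)].copy()


def merge_regions(
    windows: pd.DataFrame, stage: str = "domestication"
) -> tuple[list[Region], dict]:
    """Merge overlapping/bookended selected windows into maximal sweep regions.

    Returns the regions (score = peak ratio inside each region) and a
    length summary (count, min, max, mean in bp).
    """
    regs = [
        Region(str(r.chrom), int(r.start), int(r.end), float(r.ratio), stage)
        for r in windows.itertuples()
    ]
    merged = merge_intervals(regs)
    lengths = np.array([r.length for r in merged]) if merged else np.array([])
    summary = {
        "n_regions": len(merged),
        "min_bp": int(lengths.min()) if len(lengths) else 0,
        "max_bp": int(lengths.max()) if len(lengths) else 0,
        "mean_bp": float(lengths.mean()) if len(lengths) else 0.0,
    }
    return merged, summary


def scan_stage(
    G: GenotypeMatrix,
    stage: str,
    window: int = 50_000,
    step: int = 5_000,
    top_fraction: float = 0.05,
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[Region], pd.DataFrame, dict]:
    """Full pi-ratio scan for one stage contrast.

    domestication: wild (ancestral) vs landrace (derived);
    improvement: landrace vs improved.
    """
    contrasts = {"domestication": ("wild", "landrace"), "improvement": ("landrace", "improved")}
    if stage not in contrasts:
        raise ValueError(f"unknown stage {stage!r}")
    anc, der = contrasts[stage]
    pa = windowed_pi(G, anc, window, step, min_snps, chrom_lengths)
    pd_ = windowed_pi(G, der, window, step, min_snps, chrom_lengths)
    ratios = diversity_ratio(pa, pd_)
    selected = call_sweeps(ratios, top_fraction)
    regions, summary = merge_regions(selected, stage)
    return regions, ratios, summary


def group_allele_frequencies(
    G: GenotypeMatrix, variant: int, groups: dict[str, list[str]] | None = None,
    allele: str = "alt",
) -> dict[str, float]:
    """Frequency (%) of the designated allele per sample group at one variant.

    Counted on allele copies among non-missing genotypes; a group with no
    calls gets nan.  Percentages are rounded to 2 decimals.
    """
    if allele not in ("ref", "alt"):
        raise ValueError("allele must be 'ref' or 'alt'")
    if groups is None:
        if G.subpop is None:
            raise ValueError("no groups given and no subpopulation labels present")
        groups = {str(s): [str(s)] for s in np.unique(G.subpop)}
    out = {}
    for name, labels in groups.items():
        idx = G.sample_indices(labels)
        g = G.genotypes[idx, variant]
        g = g[g != MISSING]
        if len(g) == 0:
            out[name] = float("nan")
            continue
        alt_freq = g.sum() / (2 * len(g))
        freq = alt_freq if allele == "alt" else 1.0 - alt_freq
        out[name] = round(100.0 * freq, 2)
    return out
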
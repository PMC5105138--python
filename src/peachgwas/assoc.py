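"""Association models and downstream signal extraction.

Three marker-trait association models, mirroring the classical
GWAS-software trio:

1. naive GLM — least squares of the phenotype on the marker alone;
2. GLM-PCA — the same with principal-component scores as fixed covariates;
3. MLM — a mixed linear model y = Xb + g*beta + u + e with
   u ~ N(0, sigma_g^2 K); variance components are estimated once by REML on
   the no-marker model and reused for every marker test ("P3D"), so each
   marker test is a generalized-least-squares F test performed in the
   eigenbasis of the kinship matrix.

Binary (qualitative) phenotypes are analysed with the same linear-model
F tests as continuous ones, the standard behaviour of the GWAS tools this
reproduces.  Marker coding is selectable: "additive" (one dosage degree of
freedom) or "genotypic" (genotype-class indicators, up to 2 df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import MISSING, GenotypeMatrix, Region, minor_allele_frequencies

RESULT_COLUMNS = ["chrom", "pos", "model", "df", "effect", "F", "p", "mlog10p", "maf", "n_used"]


@dataclass
class VarianceComponents:
    """REML variance components of the no-marker mixed model."""

    sigma_g2: float
    sigma_e2: float
    loglik: float
    boundary: bool = False

    @property
    def delta(self) -> float:
        """Noise-to-genetic variance ratio sigma_e^2 / sigma_g^2."""
        return math.inf if self.sigma_g2 == 0 else self.sigma_e2 / self.sigma_g2


@dataclass
class LeadSignal:
    """A clustered association peak."""

    trait: str
    chrom: str
    pos: int
    p: float
    mlog10p: float
    explained_variation: float  # percent, nan if not computed
    region: Region
    n_cluster: int


def _marker_columns(g: np.ndarray, coding: str) -> np.ndarray | None:
    """Design columns for one marker; None when the marker is degenerate."""
    classes = np.unique(g)
    if len(classes) < 2:
        return None
    if coding == "additive":
        return g[:, None].astype(float)
    if coding == "genotypic":
        # indicators for all but the first observed class
        return np.column_stack([(g == c).astype(float) for c in classes[1:]])
    raise ValueError(f"unknown marker coding {coding!r}")


def _null_projection(y, X0):
    """Precompute the null-model pieces shared by every marker test."""
    # SVD basis handles rank-deficient covariate sets (e.g. constant columns)
    Ux, s, _ = np.linalg.svd(X0, full_matrices=False)
    Q0 = Ux[:, s > max(1e-10, 1e-10 * s.max())]
    rank0 = Q0.shape[1]
    r = y - Q0 @ (Q0.T @ y)
    sse0 = float(r @ r)
    return Q0, rank0, r, sse0


def _marker_ftest_fast(r, sse0, Q0, rank0, Xm, n) -> tuple[float, float, float, int]:
    """Incremental F test via Frisch-Waugh-Lovell: residualize the marker
    columns against the null design once, then solve a tiny system."""
    Z = Xm - Q0 @ (Q0.T @ Xm)
    ZtZ = Z.T @ Z
    Ztr = Z.T @ r
    vals, vecs = np.linalg.eigh(ZtZ)
    tol = max(1e-10, 1e-10 * vals.max()) if len(vals) else 0.0
    keep = vals > tol
    q = int(keep.sum())
    if q == 0:
        return np.nan, np.nan, np.nan, 0
    inv = vecs[:, keep] @ (vecs[:, keep].T / vals[keep][:, None])
    coef = inv @ Ztr
    ss_marker = float(Ztr @ coef)
    sse1 = max(sse0 - ss_marker, 0.0)
    dfe = n - rank0 - q
    if dfe <= 0:
        return np.nan, np.nan, np.nan, 0
    if sse1 <= 1e-12 * max(1.0, sse0):
        if ss_marker <= 1e-12 * max(1.0, sse0):
            return 0.0, 1.0, float(coef[0]), q
        return np.inf, 0.0, float(coef[0]), q
    F = (ss_marker / q) / (sse1 / dfe)
    return float(F), float(stats.f.sf(F, q, dfe)), float(coef[0]), q


def _ftest_increment(y, X0, Xm) -> tuple[float, float, float, int]:
    """F test of adding columns Xm to the design X0; returns (F, p, effect, df)."""
    n = len(y)
    X1 = np.column_stack([X0, Xm])
    beta0, sse0 = _ols_sse(y, X0)
    beta1, sse1 = _ols_sse(y, X1)
    q = np.linalg.matrix_rank(X1) - np.linalg.matrix_rank(X0)
    dfe = n - np.linalg.matrix_rank(X1)
    if q <= 0 or dfe <= 0:
        return np.nan, np.nan, np.nan, 0
    if sse1 <= 1e-12 * max(1.0, sse0):
        if sse0 - sse1 <= 1e-12 * max(1.0, sse0):
            # the null already fits perfectly: the marker adds nothing
            return 0.0, 1.0, float(beta1[X0.shape[1]]), q
        return np.inf, 0.0, float(beta1[X0.shape[1]]), q
    F = ((sse0 - sse1) / q) / (sse1 / dfe)
    p = float(stats.f.sf(F, q, dfe))
    return float(F), p, float(beta1[X0.shape[1]]), q


def _ols_sse(y, X) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return beta, float(np.sum((y - fitted) ** 2))


def glm_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    coding: str = "additive",
    model_tag: str | None = None,
) -> pd.DataFrame:
    """Per-variant fixed-effects F test of the marker term.

    For each variant, samples with a missing phenotype, covariate or
    genotype are dropped; the marker term is tested against the
    intercept+covariates null by an incremental F test.  Markers with fewer
    than two genotype classes among the used samples get a nan p-value.
    """
    y = np.asarray(y, dtype=float)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != G.n_samples:
            covariates = covariates.T
    tag = model_tag or ("glm" if covariates is None else "glm_pca")
    base_ok = ~np.isnan(y)
    if covariates is not None:
        base_ok &= ~np.isnan(covariates).any(axis=1)
    maf = minor_allele_frequencies(G.genotypes)
    rows = []
    gmat = G.genotypes
    # shared null-model projection for markers with no extra missingness
    base_idx = np.flatnonzero(base_ok)
    n_base = len(base_idx)
    Xb = np.ones((n_base, 1))
    if covariates is not None:
        Xb = np.column_stack([Xb, covariates[base_idx]])
    Q0, rank0, resid, sse0 = _null_projection(y[base_idx], Xb)
    for j in range(G.n_variants):
        gj = gmat[:, j]
        g_base = gj[base_idx]
        if (g_base != MISSING).all():
            n_used = n_base
            Xm = _marker_columns(g_base, coding)
            if Xm is None:
                F = p = eff = np.nan
                q = 0
            else:
                F, p, eff, q = _marker_ftest_fast(resid, sse0, Q0, rank0, Xm, n_base)
        else:
            ok = base_ok & (gj != MISSING)
            n_used = int(ok.sum())
            yv = y[ok]
            X0 = np.ones((n_used, 1))
            if covariates is not None:
                X0 = np.column_stack([X0, covariates[ok]])
            Xm = _marker_columns(gj[ok], coding) if n_used else None
            if Xm is None:
                F = p = eff = np.nan
                q = 0
            else:
                F, p, eff, q = _ftest_increment(yv, X0, Xm)
        if q == 0:
            rows.append((G.chrom[j], int(G.pos[j]), tag, 0, np.nan, np.nan, np.nan,
                         np.nan, maf[j], n_used))
            continue
        mlp = -math.log10(p) if p and p > 0 else (np.inf if p == 0 else np.nan)
        rows.append((G.chrom[j], int(G.pos[j]), tag, q, eff, F, p, mlp, maf[j], n_used))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def reml_null(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    n_grid: int = 100,
    delta_bounds: tuple[float, float] = (1e-5, 1e5),
) -> VarianceComponents:
    """REML variance components for y = Xb + u + e, u ~ N(0, sigma_g^2 K).

    The restricted likelihood is profiled down to the single ratio
    delta = sigma_e^2 / sigma_g^2 via the eigendecomposition of K projected
    onto the residual space of X, then maximized on a log-spaced grid with
    Brent refinement around the best grid point (the EMMA recipe).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    if K.shape != (n, n):
        raise ValueError(f"kinship matrix shape {K.shape} does not match n={n}")
    p = np.linalg.matrix_rank(X)
    # projection onto the residual space of X
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    SKS = S @ K @ S
    SKS = (SKS + SKS.T) / 2.0
    vals, vecs = np.linalg.eigh(SKS)
    order = np.argsort(vals)[::-1]
    lam = np.clip(vals[order][: n - p], 0.0, None)
    U = vecs[:, order][:, : n - p]
    eta2 = (U.T @ y) ** 2
    m = n - p

    def neg_restricted_ll(log_delta: float) -> float:
        d = math.exp(log_delta)
        denom = lam + d
        s = float(np.sum(eta2 / denom))
        ll = 0.5 * (m * (math.log(m / (2 * math.pi)) - 1.0 - math.log(s))
                    - float(np.sum(np.log(denom))))
        return -ll

    lo, hi = math.log(delta_bounds[0]), math.log(delta_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    ngll = np.array([neg_restricted_ll(g) for g in grid])
    i = int(np.argmin(ngll))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    if a == b:
        best = grid[i]
    else:
        best = optimize.minimize_scalar(neg_restricted_ll, bracket=None,
                                        bounds=(a, b), method="bounded").x
    if neg_restricted_ll(best) > ngll[i]:
        best = grid[i]
    delta = math.exp(best)
    sigma_g2 = float(np.sum(eta2 / (lam + delta))) / m
    sigma_e2 = delta * sigma_g2
    boundary = i in (0, n_grid - 1)
    if boundary and i == n_grid - 1:
        # delta huge: genetic variance effectively zero
        sigma_g2 = 0.0
        sigma_e2 = float(np.sum(eta2)) / m
    return VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_e2,
                              loglik=-neg_restricted_ll(best), boundary=boundary)


def mlm_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    pcs: np.ndarray | None,
    K: np.ndarray,
    vc: VarianceComponents,
    coding: str = "additive",
) -> pd.DataFrame:
    """P3D mixed-model scan: GLS marker F tests with fixed V = sg^2 K + se^2 I.

    The phenotype, covariates and all markers are rotated into the
    eigenbasis of K once; each marker test is then a weighted least-squares
    incremental F test, linear in n per marker.  Samples with missing
    phenotype or covariates are dropped up front; markers with missing
    genotypes fall back to a per-marker GLS on the complete subset.
    """
    y = np.asarray(y, dtype=float)
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        if pcs.shape[0] != G.n_samples:
            pcs = pcs.T
    ok = ~np.isnan(y)
    if pcs is not None:
        ok &= ~np.isnan(pcs).any(axis=1)
    idx = np.flatnonzero(ok)
    Gs = G.take_samples(idx)
    ys = y[idx]
    Ks = K[np.ix_(idx, idx)]
    Xcov = pcs[idx] if pcs is not None else None

    vals, U = np.linalg.eigh((Ks + Ks.T) / 2.0)
    V = vc.sigma_g2 * np.clip(vals, 0.0, None) + vc.sigma_e2
    w = 1.0 / np.sqrt(V)  # whitening weights in the eigenbasis

    yt = (U.T @ ys) * w
    ones_t = (U.T @ np.ones(len(ys))) * w
    X0t = ones_t[:, None]
    if Xcov is not None:
        X0t = np.column_stack([X0t, (U.T @ Xcov) * w[:, None]])

    maf = minor_allele_frequencies(Gs.genotypes)
    rows = []
    any_missing = (Gs.genotypes == MISSING).any(axis=0)
    Uw = U * w[None, :]  # x -> (U' x) * w is x @ Uw done columnwise
    Q0, rank0, resid, sse0 = _null_projection(yt, X0t)
    # rotate all complete markers at once
    gt_all = None
    if not any_missing.all():
        gfloat = Gs.genotypes.astype(float)
        gt_all = Uw.T @ gfloat
    for j in range(Gs.n_variants):
        gj = Gs.genotypes[:, j]
        if not any_missing[j]:
            Xm_raw = _marker_columns(gj, coding)
            if Xm_raw is None:
                rows.append((Gs.chrom[j], int(Gs.pos[j]), "mlm", 0, np.nan, np.nan,
                             np.nan, np.nan, maf[j], len(ys)))
                continue
            if coding == "additive":
                Xm = gt_all[:, j][:, None]
            else:
                Xm = Uw.T @ Xm_raw
            F, p, eff, q = _marker_ftest_fast(resid, sse0, Q0, rank0, Xm, len(ys))
            n_used = len(ys)
        else:
            sub = np.flatnonzero(gj != MISSING)
            n_used = len(sub)
            Xm_raw = _marker_columns(gj[sub], coding) if n_used else None
            if Xm_raw is None or n_used <= X0t.shape[1] + 1:
                rows.append((Gs.chrom[j], int(Gs.pos[j]), "mlm", 0, np.nan, np.nan,
                             np.nan, np.nan, maf[j], n_used))
                continue
            Vsub = vc.sigma_g2 * Ks[np.ix_(sub, sub)] + vc.sigma_e2 * np.eye(n_used)
            L = np.linalg.cholesky(Vsub)
            yv = np.linalg.solve(L, ys[sub])
            X0 = np.ones((n_used, 1))
            if Xcov is not None:
                X0 = np.column_stack([X0, Xcov[sub]])
            X0w = np.linalg.solve(L, X0)
            Xmw = np.linalg.solve(L, Xm_raw)
            F, p, eff, q = _ftest_increment(yv, X0w, Xmw)
        mlp = -math.log10(p) if p and p > 0 else (np.inf if p == 0 else np.nan)
        rows.append((Gs.chrom[j], int(Gs.pos[j]), "mlm", q, eff, F, p, mlp, maf[j], n_used))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def round_1sf(x: float) -> float:
    """Round to one significant figure, the convention for reported cutoffs."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def find_lead_snps(
    result: pd.DataFrame,
    cutoff: float = 1e-8,
    min_gap: int = 50_000,
    flank: int = 25_000,
    trait: str = "",
) -> list[LeadSignal]:
    """Cluster significant variants and report each cluster's best hit.

    Significant variants (p <= cutoff) on the same chromosome are joined by
    single linkage whenever consecutive positions are within ``min_gap``;
    each cluster's minimum-p variant is the lead (ties break to the lower
    position), and its candidate region is the lead position +/- ``flank``.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    sig = result[result["p"] <= cutoff].sort_values(["chrom", "pos"], kind="stable")
    leads: list[LeadSignal] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > min_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            cluster = grp.iloc[s:e]
            best = cluster.sort_values(["p", "pos"], kind="stable").iloc[0]
            lead_pos = int(best["pos"])
            region = Region(str(chrom), max(0, lead_pos - flank), lead_pos + flank,
                            score=float(best["mlog10p"]), label=trait)
            leads.append(LeadSignal(
                trait=trait, chrom=str(chrom), pos=lead_pos, p=float(best["p"]),
                mlog10p=float(best["mlog10p"]), explained_variation=float("nan"),
                region=region, n_cluster=len(cluster),
            ))
    return leads


def marker_r2(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
    coding: str = "additive",
) -> float:
    """Explained variation (%): partial R-squared of the marker after covariates."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    ok = ~np.isnan(y) & (g != MISSING)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(y):
            covariates = covariates.T
        ok &= ~np.isnan(covariates).any(axis=1)
    yv = y[ok]
    Xm = _marker_columns(g[ok].astype(float), coding)
    if Xm is None:
        return float("nan")
    X0 = np.ones((ok.sum(), 1))
    if covariates is not None:
        X0 = np.column_stack([X0, covariates[ok]])
    _, sse0 = _ols_sse(yv, X0)
    _, sse1 = _ols_sse(yv, np.column_stack([X0, Xm]))
    if sse0 <= 0:
        return float("nan")
    return 100.0 * (sse0 - sse1) / sse0


def qq_curve(pvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p pairs for a quantile-quantile plot.

    Both arrays are sorted ascending; expected quantiles use the (i-0.5)/m
    plotting positions.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("qq_curve needs at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    observed = np.sort(-np.log10(p))
    expected = np.sort(-np.log10((np.arange(1, m + 1) - 0.5) / m))
    return expected, observed


def segregation_ratio(y_binary: np.ndarray) -> tuple[float, bool]:
    """Dominant:recessive count ratio (phenotype 1 = dominant class).

    Returns (ratio rounded to 2 decimals, flag); the flag marks an empty
    class, in which case the ratio is inf (no recessives) or 0.0.
    """
    y = np.asarray(y_binary, dtype=float)
    y = y[~np.isnan(y)]
    n_dom = int(np.sum(y == 1))
    n_rec = int(np.sum(y == 0))
    if n_rec == 0:
        return math.inf, True
    return round(n_dom / n_rec, 2), n_dom == 0
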
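"""Population structure: dosage PCA, kinship, genetic distance, NJ tree.

PCA follows the classical genotype-covariance recipe: encode genotypes as a
0/1/2 dosage matrix, mean-centre each variant, form the sample-by-sample
covariance and eigendecompose it.  Kinship uses the centred cross-product
(VanRaden) estimator; genetic distance is allele-sharing (1 - IBS) with
pairwise deletion; trees are built by Saitou-Nei neighbour joining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Top-k principal-component scores per sample and all eigenvalues."""

    scores: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # descending, length n_samples
    samples: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(1.0, abs(self.eigenvalues[0]))):
            raise ValueError("eigenvalues must be sorted descending")


def encode_dosage(G: GenotypeMatrix) -> np.ndarray:
    """Dosage encoding: reference homozygote 0, heterozygote 1, alternate
    homozygote 2; missing becomes nan.

    The genotype container already stores alternate-allele dosages, so this
    is a float view with missing propagated.
    """
    g = G.genotypes.astype(float)
    g[G.genotypes == MISSING] = np.nan
    return g


def _mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Replace nan entries by the per-variant mean (0 for all-missing columns)."""
    out = dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
    col_mean = np.nan_to_num(col_mean)
    inds = np.where(np.isnan(out))
    out[inds] = np.take(col_mean, inds[1])
    return out


def pca_individuals(G: GenotypeMatrix, k: int = 2) -> PCAResult:
    """PCA of individuals from the sample covariance of centred dosages.

    Missing entries are mean-imputed per variant before centring.  The sign
    of each component is arbitrary.
    """
    n = G.n_samples
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    X = _mean_impute(encode_dosage(G))
    X = X - X.mean(axis=0, keepdims=True)
    cov = X @ X.T / max(1, G.n_variants - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    scores = vecs[:, :k] * np.sqrt(vals[:k])[None, :]
    return PCAResult(scores=scores, eigenvalues=vals, samples=G.samples)


def compute_kinship(G: GenotypeMatrix, method: str = "vanraden") -> np.ndarray:
    """Genomic relationship matrix.

    ``vanraden``: K = W W' / (2 * sum_j p_j (1 - p_j)) with W = dosage - 2p.
    For inbred samples the mean diagonal approaches 1 + F.
    ``ibs``: mean identity-by-state similarity in [0, 1].
    Missing entries are mean-imputed per variant.
    """
    X = _mean_impute(encode_dosage(G))
    if method == "ibs":
        return 1.0 - allele_sharing_distance(G)
    if method != "vanraden":
        raise ValueError(f"unknown kinship method {method!r}")
    p = X.mean(axis=0) / 2.0
    het_sum = float(np.sum(2.0 * p * (1.0 - p)))
    if het_sum == 0.0:
        raise ValueError("all variants monomorphic: kinship denominator is zero")
    W = X - 2.0 * p[None, :]
    return (W @ W.T) / het_sum


def allele_sharing_distance(G: GenotypeMatrix) -> np.ndarray:
    """1 - (mean shared-allele fraction) over pairwise-complete variants.

    Per variant a pair shares 1 - |g_i - g_j| / 2 of its alleles (1 for
    identical genotypes, 0.5 for hom vs het, 0 for opposite homozygotes).
    """
    X = encode_dosage(G)
    n = G.n_samples
    D = np.zeros((n, n))
    obs = ~np.isnan(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if not both.any():
                raise ValueError(
                    f"samples {G.samples[i]!r} and {G.samples[j]!r} share no "
                    "non-missing variants; distance undefined"
                )
            share = 1.0 - np.abs(X[i, both] - X[j, both]) / 2.0
            D[i, j] = D[j, i] = 1.0 - share.mean()
    return D


def neighbor_joining(D: np.ndarray, labels) -> str:
    """Saitou-Nei neighbour joining; returns a newick string.

    Recovers the generating topology and branch lengths exactly on additive
    distance matrices.  Negative branch-length estimates are clamped to
    zero (logged).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if D.shape[0] < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    dm = DistanceMatrix(D, ids=[str(x) for x in labels])
    tree = _skbio_nj(dm, neg_as_zero=True)
    clamped = sum(1 for node in tree.traverse() if node.length is not None and node.length == 0.0)
    if clamped:
        logger.debug("neighbor_joining: %d zero-length branches (possibly clamped)", clamped)
    return str(tree).strip()
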
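"""Rank-k Mahalanobis-distance GRM via leverage and cross-leverage scores.

The squared Mahalanobis distance between samples i and j whitens by the SNP
(LD) covariance G = X'X/(m-1):

    D_ij = (X_i - X_j) G^+ (X_i - X_j)'.

Writing X = U S V', the rank-k regularized form (G truncated to its top-k
eigenspace) collapses to the leverage/cross-leverage scores H = U_k U_k':

    D_i  = (m-1) (H_ii - 1/m)            (distance to the origin)
    D_ij = (m-1) (H_ii + H_jj - 2 H_ij)  (pairwise)

so the n x n covariance G never needs to be materialized or inverted. The
brute-force path below computes the quadratic forms directly through the
pseudo-inverse and serves as the independent oracle for the leverage path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import svds
from scipy.spatial.distance import squareform, pdist

from clustrat.io_genotype import NormalizedGenotypes


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, NormalizedGenotypes):
        return x.X
    return np.asarray(x, dtype=float)


@dataclass
class SpectralFactors:
    """Top-k singular triplets of the (normalized) genotype matrix."""

    U_k: np.ndarray  # m x k, orthonormal columns
    S_k: np.ndarray  # k singular values, descending
    V_k: np.ndarray  # n x k, orthonormal columns

    @property
    def k(self) -> int:
        return self.S_k.shape[0]


@dataclass
class LeverageMatrix:
    """H = U_k U_k': diagonal = rank-k leverage scores, off-diagonal =
    cross-leverage scores. A rank-k orthogonal projection, so trace(H) = k and
    every eigenvalue is 0 or 1."""

    H: np.ndarray
    k: int

    @property
    def leverages(self) -> np.ndarray:
        return np.diag(self.H)


@dataclass
class DistanceMatrix:
    """Squared rank-k Mahalanobis distances between samples.

    ``D`` is the m x m squared-distance matrix (zero diagonal, symmetric);
    ``D_origin`` holds each sample's squared distance to the origin, which
    carries the -1/m centering offset that cancels in the pairwise form.
    The n x n LD covariance G is implicit and never materialized.
    """

    D: np.ndarray
    D_origin: np.ndarray | None
    k: int

    @property
    def m(self) -> int:
        return self.D.shape[0]

    def to_dataframe(self, sample_ids=None):
        import pandas as pd

        ids = sample_ids if sample_ids is not None else list(range(self.m))
        return pd.DataFrame(self.D, index=ids, columns=ids)


def truncated_svd(x, k: int, seed: int | None = None) -> SpectralFactors:
    """Best rank-k factorization of the normalized genotype matrix.

    Uses Lanczos iteration (``scipy.sparse.linalg.svds``) with a seeded
    deterministic start vector for k well below min(m, n), falling back to a
    full SVD otherwise. Singular values are returned in descending order.
    """
    X = _as_matrix(x)
    m, n = X.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} out of range for a {m}x{n} matrix")
    if k >= min(m, n) - 1 or min(m, n) <= 32:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        return SpectralFactors(U[:, :k].copy(), s[:k].copy(), Vt[:k].T.copy())
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(m, n))
    U, s, Vt = svds(X, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    return SpectralFactors(U[:, order], s[order], Vt[order].T)


def leverage_matrix(f: SpectralFactors) -> LeverageMatrix:
    """Leverage/cross-leverage score matrix H = U_k U_k'."""
    H = f.U_k @ f.U_k.T
    H = (H + H.T) / 2.0
    return LeverageMatrix(H, f.k)


def mahalanobis_from_leverage(h: LeverageMatrix, m: int | None = None) -> DistanceMatrix:
    """Pairwise squared Mahalanobis distances from leverage scores.

    D_ij = (m-1)(H_ii + H_jj - 2 H_ij) and D_i = (m-1)(H_ii - 1/m).
    """
    H = h.H
    if m is None:
        m = H.shape[0]
    if m <= 1:
        raise ValueError("need at least 2 samples")
    lev = np.diag(H)
    D = (m - 1) * (lev[:, None] + lev[None, :] - 2.0 * H)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    np.fill_diagonal(D, 0.0)
    D_origin = (m - 1) * (lev - 1.0 / m)
    return DistanceMatrix(D, D_origin, h.k)


def mahalanobis_grm(
    x, k: int = 10, seed: int | None = None, ridge: float = 0.0
) -> DistanceMatrix:
    """Convenience wrapper: normalized genotypes -> rank-k Mahalanobis GRM.

    With ``ridge`` > 0 the whitening uses (G_k + eps*I)^-1, eps = ridge times
    the mean retained eigenvalue of G, which interpolates between the pure
    whitened distance (ridge -> 0) and Euclidean distance on the leading
    principal components (large ridge). The pure rank-k distance weighs every
    retained direction equally, so k should match the structure dimension
    (d-1 for d source populations) when it is known.
    """
    X = _as_matrix(x)
    m = X.shape[0]
    f = truncated_svd(X, k, seed=seed)
    if ridge <= 0:
        return mahalanobis_from_leverage(leverage_matrix(f), m)
    eig = f.S_k**2 / (m - 1)
    w = eig / (eig + ridge * eig.mean())  # per-direction whitening weights
    Uw = f.U_k * np.sqrt(w)
    H = Uw @ Uw.T
    lev = np.diag(H)
    D = (m - 1) * (lev[:, None] + lev[None, :] - 2.0 * H)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, (m - 1) * (lev - 1.0 / m), k)


def mahalanobis_bruteforce(x, k: int, ridge: float = 0.0) -> DistanceMatrix:
    """Direct-quadratic-form oracle for the leverage-score path.

    Materializes the rank-k pseudo-inverse of the SNP covariance
    G = X'X/(m-1), i.e. (m-1) V_k S_k^-2 V_k', and evaluates every pairwise
    quadratic form explicitly. Quadratic in n -- a test oracle, not a
    production path. ``ridge`` > 0 switches to (G_k + eps*I)^-1 on the
    retained eigenspace with eps relative to the mean eigenvalue.
    """
    X = _as_matrix(x)
    m, n = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if k > s.size:
        raise ValueError(f"k={k} exceeds matrix rank bound {s.size}")
    if s[k - 1] < 1e-10 * s[0]:
        raise ValueError("rank-deficient: retained singular value below 1e-10*S_1; reduce k")
    Vk, sk = Vt[:k].T, s[:k]
    eig = sk**2 / (m - 1)  # eigenvalues of G on the retained space
    if ridge > 0:
        inv_eig = 1.0 / (eig + ridge * eig.mean())
    else:
        inv_eig = 1.0 / eig
    Ginv_k = (Vk * inv_eig) @ Vk.T  # n x n rank-k pseudo-inverse of G
    Dorig = np.einsum("ij,jk,ik->i", X, Ginv_k, X)
    D = np.empty((m, m))
    for i in range(m):
        diff = X - X[i]
        D[i] = np.einsum("ij,jk,ik->i", diff, Ginv_k, diff)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, Dorig, k)


def euclidean_grm(x) -> DistanceMatrix:
    """Squared Euclidean distances between sample rows (comparator GRM)."""
    X = _as_matrix(x)
    D = squareform(pdist(X, metric="sqeuclidean"))
    return DistanceMatrix(D, (X**2).sum(axis=1), min(X.shape))


def export_distance_tsv(dist: DistanceMatrix, sample_ids, path) -> None:
    """Square tab-delimited distance matrix with sample IDs on both axes."""
    dist.to_dataframe(list(sample_ids)).to_csv(path, sep="\t")
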
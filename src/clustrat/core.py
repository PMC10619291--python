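"""The CluStrat pipeline: hierarchical clustering on the Mahalanobis GRM,
per-cluster association tests, and cross-cluster meta-analysis.

Population stratification confounds genotype-trait association when allele
frequencies and trait prevalence both differ between subpopulations. Instead
of regressing out top principal components, this method partitions samples
into genetically homogeneous clusters (agglomerative hierarchical clustering
on the rank-k Mahalanobis distance), tests each SNP within every cluster with
a plain linear or logistic model, and recombines clusters by sample-size
weighted z-score meta-analysis -- within a homogeneous cluster the
stratification signal is absent, while meta-analysis restores power.

Clustering operates on the metric sqrt(D) (D holds *squared* distances);
average linkage is the default since Ward assumes Euclidean geometry and the
Mahalanobis dissimilarity is precomputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from clustrat.grm import (
    DistanceMatrix,
    leverage_matrix,
    mahalanobis_from_leverage,
    truncated_svd,
)
from clustrat.io_genotype import NormalizedGenotypes, Phenotype

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_DEGENERATE = "skipped-degenerate"
STATUS_NO_DATA = "no-data"


@dataclass
class ClusterModel:
    """Dendrogram plus the pruning/selection state of the clustering stage."""

    linkage_tree: np.ndarray  # (m-1) x 4 scipy linkage matrix on sqrt(D)
    method: str
    k_candidates: list[int] = field(default_factory=list)
    chosen_k: int | None = None
    assignment: np.ndarray | None = None  # labels in 1..chosen_k
    inconsistency_depth: int = 2
    inconsistency_threshold: float = 1.15

    @property
    def m(self) -> int:
        return self.linkage_tree.shape[0] + 1


@dataclass
class AssocResult:
    """Per-cluster, per-SNP association statistics.

    Arrays are (n_clusters, n_snps); ``status`` distinguishes clean fits from
    degenerate ones (constant genotype, separation) which carry NaN stats.
    """

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    status: np.ndarray  # object array of STATUS_* flags
    cluster_sizes: np.ndarray
    cluster_labels: np.ndarray
    model: str  # "linear" | "logistic"


@dataclass
class MetaResult:
    """Per-SNP meta-analysis across clusters."""

    meta_z: np.ndarray
    meta_p: np.ndarray
    direction: list[str]  # one char per cluster per SNP: + / - / ?
    weights: np.ndarray  # per-cluster weights used
    n_total: int
    method: str  # "sample_size_z" | "inverse_variance"
    meta_beta: np.ndarray | None = None
    meta_se: np.ndarray | None = None
    status: np.ndarray | None = None


@dataclass
class ClustratConfig:
    """End-to-end pipeline parameters."""

    k_svd: int | None = None  # None -> d-1 when d is known, else 10
    n_clusters: int | None = None  # fixed cluster count; None -> CV selection
    d: int | None = None  # number of source populations, if known
    q_range: tuple[int, int] = (0, 3)
    folds: int = 5
    alpha_sel: float = 1e-4
    linkage_method: str = "average"
    meta_method: str = "sample_size_z"
    min_cluster_size: int = 50
    min_class_count: int = 10
    model: str | None = None  # None -> by trait kind
    seed: int | None = None


def ahc(dist: DistanceMatrix, method: str = "average") -> ClusterModel:
    """Agglomerative hierarchical clustering on sqrt(D).

    Returns the full merge tree; cluster counts are chosen afterwards by
    ``cut_to_k`` / ``prune_inconsistency`` / ``select_k_cv``.
    """
    if dist.m < 2:
        raise ValueError("need at least 2 samples to cluster")
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage method {method!r}")
    condensed = squareform(np.sqrt(np.maximum(dist.D, 0.0)), checks=False)
    Z = linkage(condensed, method=method)
    return ClusterModel(Z, method)


def cut_to_k(cm: ClusterModel, k: int) -> np.ndarray:
    """Cut the dendrogram into (at most) k clusters; labels are 1..k.

    Ties at zero height can merge fewer than k distinct groups; the number of
    realized clusters is the number of unique labels returned.
    """
    if not 1 <= k <= cm.m:
        raise ValueError(f"k={k} out of range [1, {cm.m}]")
    return fcluster(cm.linkage_tree, t=k, criterion="maxclust")


def prune_inconsistency(
    cm: ClusterModel, depth: int = 2, threshold: float = 1.15
) -> int:
    """Observed cluster count from inconsistency pruning of the dendrogram.

    Each merge's inconsistency coefficient standardizes its height by the
    mean/std of merge heights within ``depth`` levels below it (zero std ->
    coefficient 0); cutting every link whose coefficient exceeds
    ``threshold`` yields the observed number of clusters.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    labels = fcluster(cm.linkage_tree, t=threshold, criterion="inconsistent",
                      depth=depth)
    return int(np.unique(labels).size)


def _linear_assoc(G: np.ndarray, y: np.ndarray, C: np.ndarray | None):
    """Vectorized simple linear regression of y on each genotype column,
    with optional covariates residualized out of both sides."""
    m, n = G.shape
    dof = m - 2
    if C is not None:
        Q, _ = np.linalg.qr(np.column_stack([np.ones(m), C]))
        G = G - Q @ (Q.T @ G)
        y = y - Q @ (Q.T @ y)
        dof = m - 2 - C.shape[1]
    else:
        G = G - G.mean(axis=0)
        y = y - y.mean()
    sxx = (G**2).sum(axis=0)
    degenerate = sxx <= 1e-12 * m
    sxx_safe = np.where(degenerate, 1.0, sxx)
    beta = (G * y[:, None]).sum(axis=0) / sxx_safe
    resid_ss = (y**2).sum() - beta**2 * sxx_safe
    resid_ss = np.maximum(resid_ss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(resid_ss / max(dof, 1) / sxx_safe)
    degenerate |= ~np.isfinite(se) | (se <= 0)
    return beta, se, degenerate


def _logistic_assoc(G: np.ndarray, y: np.ndarray, max_iter: int = 40,
                    tol: float = 1e-8):
    """Vectorized Newton-Raphson for per-SNP logistic regression
    logit P(y=1) = a_j + b_j g_j (2x2 systems solved in closed form).

    Quasi-separated fits (diverging |b|) fall back to a small ridge on the
    Hessian and are flagged degenerate if they still fail to stabilize.
    """
    m, n = G.shape
    ybar = y.mean()
    a = np.full(n, np.log(ybar / (1 - ybar)))
    b = np.zeros(n)
    degenerate = G.var(axis=0) <= 1e-12
    ridge = 0.0
    for it in range(max_iter):
        eta = np.clip(a[None, :] + G * b[None, :], -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        ga, gb = r.sum(axis=0), (G * r).sum(axis=0)
        h11 = w.sum(axis=0) + ridge
        h12 = (w * G).sum(axis=0)
        h22 = (w * G**2).sum(axis=0) + ridge
        det = h11 * h22 - h12**2
        bad = det <= 1e-12
        det_safe = np.where(bad, 1.0, det)
        da = (h22 * ga - h12 * gb) / det_safe
        db = (h11 * gb - h12 * ga) / det_safe
        da[bad] = 0.0
        db[bad] = 0.0
        # dampen huge steps (separation)
        step = np.maximum(np.abs(da), np.abs(db))
        scale = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-12), 1.0)
        a += da * scale
        b += db * scale
        if np.max(np.abs(np.concatenate([da, db]))) < tol:
            break
    else:
        # not converged for some SNPs: stabilize with a ridge pass
        ridge = 1e-4 * m
        for _ in range(10):
            eta = np.clip(a[None, :] + G * b[None, :], -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            r = y[:, None] - mu
            ga, gb = r.sum(axis=0), (G * r).sum(axis=0)
            h11 = w.sum(axis=0) + ridge
            h12 = (w * G).sum(axis=0)
            h22 = (w * G**2).sum(axis=0) + ridge
            det = np.maximum(h11 * h22 - h12**2, 1e-12)
            a += (h22 * ga - h12 * gb) / det
            b += (h11 * gb - h12 * ga) / det
    eta = np.clip(a[None, :] + G * b[None, :], -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    h11 = w.sum(axis=0)
    h12 = (w * G).sum(axis=0)
    h22 = (w * G**2).sum(axis=0)
    det = h11 * h22 - h12**2
    degenerate |= (det <= 1e-10) | (np.abs(b) > 20)
    det_safe = np.where(det <= 1e-10, 1.0, det)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(h11 / det_safe)
    degenerate |= ~np.isfinite(se) | (se <= 0)
    return b, se, degenerate


def cluster_assoc(
    x: NormalizedGenotypes | np.ndarray,
    y: Phenotype,
    assignment: np.ndarray,
    model: str | None = None,
    covariates: np.ndarray | None = None,
    min_cluster_size: int = 50,
    min_class_count: int = 10,
) -> AssocResult:
    """Per-cluster univariate association of the trait with every SNP.

    Binary traits use logistic regression, quantitative use OLS (overridable
    via ``model``). Clusters below ``min_cluster_size`` samples -- or, for
    binary traits, with fewer than ``min_class_count`` cases or controls --
    are skipped entirely with a warning: Wald statistics are unreliable
    there. Constant-genotype (or separated) fits are flagged
    ``skipped-degenerate`` per SNP rather than dropped silently.
    """
    X = x.X if isinstance(x, NormalizedGenotypes) else np.asarray(x, dtype=float)
    yv = np.asarray(y.y, dtype=float)
    if model is None:
        model = "logistic" if y.trait_kind == "binary" else "linear"
    if model not in ("linear", "logistic"):
        raise ValueError(f"unknown model {model!r}")

    labels = np.unique(assignment)
    m, n = X.shape
    nc = labels.size
    beta = np.full((nc, n), np.nan)
    se = np.full((nc, n), np.nan)
    status = np.full((nc, n), STATUS_NO_DATA, dtype=object)
    sizes = np.zeros(nc, dtype=int)

    for ci, lab in enumerate(labels):
        idx = np.flatnonzero(assignment == lab)
        sizes[ci] = idx.size
        if idx.size < min_cluster_size:
            logger.warning("cluster %s skipped: %d samples < min_cluster_size=%d",
                           lab, idx.size, min_cluster_size)
            continue
        yc = yv[idx]
        if model == "logistic":
            n_case = int(yc.sum())
            if n_case < min_class_count or idx.size - n_case < min_class_count:
                logger.warning("cluster %s skipped: class counts (%d, %d) below %d",
                               lab, idx.size - n_case, n_case, min_class_count)
                continue
        Gc = X[idx]
        Cc = covariates[idx] if covariates is not None else None
        if model == "linear":
            b, s, bad = _linear_assoc(Gc, yc, Cc)
        else:
            if Cc is not None:
                warnings.warn("covariates ignored in the logistic fast path")
            b, s, bad = _logistic_assoc(Gc, yc)
        beta[ci] = b
        se[ci] = s
        status[ci] = np.where(bad, STATUS_DEGENERATE, STATUS_OK)
        beta[ci, bad] = np.nan
        se[ci, bad] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(np.isfinite(z), np.maximum(p, np.finfo(float).tiny), np.nan)
    return AssocResult(beta, se, z, p, status, sizes, labels, model)


def meta_analyze(res: AssocResult, method: str = "sample_size_z") -> MetaResult:
    """Combine per-cluster statistics across clusters, per SNP.

    ``sample_size_z`` (default, the classic METAL rule): meta_z =
    sum(w_c z_c)/sqrt(sum w_c^2) with w_c = sqrt(n_c). ``inverse_variance``:
    precision-weighted effect sizes. SNPs with no contributing cluster are
    flagged ``no-data`` with NaN statistics.
    """
    if method not in ("sample_size_z", "inverse_variance"):
        raise ValueError(f"unknown meta-analysis method {method!r}")
    ok = res.status == STATUS_OK
    nc, n = res.z.shape
    z = np.where(ok, res.z, 0.0)
    contributing = ok.any(axis=0)

    meta_beta = meta_se = None
    if method == "sample_size_z":
        w = np.sqrt(res.cluster_sizes.astype(float))[:, None] * ok
        denom = np.sqrt((w**2).sum(axis=0))
        denom_safe = np.where(contributing, denom, 1.0)
        meta_z = (w * z).sum(axis=0) / denom_safe
        weights = np.sqrt(res.cluster_sizes.astype(float))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            prec = np.where(ok, 1.0 / res.se**2, 0.0)
        tot = prec.sum(axis=0)
        tot_safe = np.where(contributing, tot, 1.0)
        meta_beta = (np.where(ok, res.beta, 0.0) * prec).sum(axis=0) / tot_safe
        meta_se = 1.0 / np.sqrt(tot_safe)
        meta_z = meta_beta / meta_se
        weights = np.ones(nc)

    meta_z = np.where(contributing, meta_z, np.nan)
    meta_p = 2.0 * norm.sf(np.abs(meta_z))
    meta_p = np.where(contributing, np.maximum(meta_p, np.finfo(float).tiny), np.nan)
    dir_chars = np.full((nc, n), "?", dtype="U1")
    dir_chars[ok & (res.z > 0)] = "+"
    dir_chars[ok & (res.z < 0)] = "-"
    direction = ["".join(dir_chars[:, j]) for j in range(n)]
    status = np.where(contributing, STATUS_OK, STATUS_NO_DATA).astype(object)
    return MetaResult(meta_z, meta_p, direction, weights,
                      int(res.cluster_sizes.sum()), method,
                      meta_beta, meta_se, status)


def select_k_cv(
    x: NormalizedGenotypes | np.ndarray,
    y: Phenotype,
    dist: DistanceMatrix,
    d: int,
    q_range: tuple[int, int] = (0, 3),
    folds: int = 5,
    alpha_sel: float = 1e-4,
    linkage_method: str = "average",
    min_cluster_size: int = 50,
    min_class_count: int = 10,
    seed: int | None = None,
    model: str | None = None,
) -> int:
    """Five-fold cross-validated choice of the cluster count.

    Candidates run from d to d+max(q_range) (d = number of source
    populations, or the inconsistency-pruned observed count when unknown),
    capped so min_cluster_size remains feasible. Each fold clusters its
    training samples, tests associations per cluster, and scores the
    candidate by the size of the cross-cluster intersection of SNPs
    significant at ``alpha_sel``; the score is averaged over folds and the
    smallest k wins ties.
    """
    X = x.X if isinstance(x, NormalizedGenotypes) else np.asarray(x, dtype=float)
    m = X.shape[0]
    k_max_feasible = max(1, m // max(min_cluster_size, 1))
    candidates = [k for k in range(d, d + max(q_range) + 1) if 1 <= k <= k_max_feasible]
    if not candidates:
        raise ValueError("empty cluster-count candidate set")
    if len(candidates) == 1:
        return candidates[0]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    fold_ids = np.arange(m) % folds
    fold_of = np.empty(m, dtype=int)
    fold_of[perm] = fold_ids

    scores = np.zeros(len(candidates))
    sqD = np.sqrt(np.maximum(dist.D, 0.0))
    for f in range(folds):
        train = np.flatnonzero(fold_of != f)
        sub = DistanceMatrix(sqD[np.ix_(train, train)] ** 2, None, dist.k)
        cm = ahc(sub, method=linkage_method)
        for ki, k in enumerate(candidates):
            labels = cut_to_k(cm, k)
            res = cluster_assoc(X[train], Phenotype(y.y[train], y.trait_kind),
                                labels, model=model,
                                min_cluster_size=min_cluster_size,
                                min_class_count=min_class_count)
            tested = [ci for ci in range(res.cluster_labels.size)
                      if (res.status[ci] == STATUS_OK).any()]
            if not tested:
                continue
            sig = None
            for ci in tested:
                hits = set(np.flatnonzero(
                    (res.status[ci] == STATUS_OK) & (res.p[ci] < alpha_sel)))
                sig = hits if sig is None else (sig & hits)
            scores[ki] += len(sig) / folds
    best = int(np.argmax(scores))  # argmax takes the first (smallest k) on ties
    return candidates[best]


def clustrat(
    x: NormalizedGenotypes | np.ndarray,
    y: Phenotype,
    config: ClustratConfig | None = None,
) -> tuple[MetaResult, ClusterModel]:
    """End-to-end pipeline on normalized genotypes.

    normalize -> truncated SVD -> leverage scores -> Mahalanobis GRM -> AHC
    -> cluster-count selection (fixed, or five-fold CV over d+q candidates)
    -> per-cluster association -> meta-analysis. Reproducible given
    ``config.seed``.
    """
    cfg = config or ClustratConfig()
    X = x.X if isinstance(x, NormalizedGenotypes) else np.asarray(x, dtype=float)
    m = X.shape[0]
    if cfg.k_svd is not None:
        k_svd = cfg.k_svd
    elif cfg.d is not None and cfg.d > 1:
        # the whitened rank-k distance discriminates only inside the retained
        # subspace: match it to the structure dimension when d is known
        k_svd = cfg.d - 1
    else:
        k_svd = 10
    k_svd = max(1, min(k_svd, min(X.shape) - 1)) if min(X.shape) > 1 else 1
    f = truncated_svd(X, k_svd, seed=cfg.seed)
    dist = mahalanobis_from_leverage(leverage_matrix(f), m)
    cm = ahc(dist, method=cfg.linkage_method)
    cm.inconsistency_depth = 2

    if cfg.n_clusters is not None:
        chosen = cfg.n_clusters
        cm.k_candidates = [chosen]
    else:
        d = cfg.d if cfg.d is not None else prune_inconsistency(cm)
        cm.k_candidates = list(range(d, d + max(cfg.q_range) + 1))
        chosen = select_k_cv(
            X, y, dist, d, q_range=cfg.q_range, folds=cfg.folds,
            alpha_sel=cfg.alpha_sel, linkage_method=cfg.linkage_method,
            min_cluster_size=cfg.min_cluster_size,
            min_class_count=cfg.min_class_count, seed=cfg.seed, model=cfg.model)
    cm.chosen_k = chosen
    cm.assignment = cut_to_k(cm, chosen)

    res = cluster_assoc(X, y, cm.assignment, model=cfg.model,
                        min_cluster_size=cfg.min_cluster_size,
                        min_class_count=cfg.min_class_count)
    meta = meta_analyze(res, method=cfg.meta_method)
    return meta, cm
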
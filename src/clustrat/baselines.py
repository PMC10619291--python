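"""Comparator association tests and evaluation utilities.

The two in-repo comparators bracket the stratification-correction spectrum:
the Armitage trend test applies no correction at all, and the PCA-adjusted
(Eigenstrat-style) test residualizes both trait and genotype on the top
principal components before testing. Detection scoring counts causal versus
spurious hits against simulation ground truth at a genome-wide threshold,
and the tSDS diagnostic regresses binned trait-aligned singleton density
scores on p-value rank to detect residual stratification in real summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, spearmanr

from clustrat.core import MetaResult
from clustrat.io_genotype import NormalizedGenotypes, Phenotype
from clustrat.simulate import SimTruth

CHI2_1_MEDIAN = chi2.ppf(0.5, df=1)  # 0.4549...


@dataclass
class DetectionReport:
    """Causal/spurious hit counts for one method on one replicate."""

    method: str
    threshold: float
    causal_detected: int
    spurious: int
    n_causal: int
    n_snps: int
    replicate: int = 0


@dataclass
class TsdsDiagnostic:
    bin_size: int
    slope: float
    slope_se: float
    spearman_r: float
    spearman_p: float
    n_bins: int


def armitage_trend(g_column: np.ndarray, y: Phenotype) -> tuple[float, float]:
    """Cochran-Armitage trend test with allele-dosage scores (0, 1, 2).

    The statistic is m * r^2 where r is the Pearson correlation between
    dosage and case status; constant genotypes return (0, 1) flagged by the
    zero statistic.
    """
    g = np.asarray(g_column, dtype=float)
    yv = np.asarray(y.y, dtype=float)
    if y.trait_kind != "binary":
        raise ValueError("the trend test requires a binary trait")
    if np.unique(yv[~np.isnan(yv)]).size < 2:
        raise ValueError("binary trait must contain both cases and controls")
    m = g.size
    gc = g - g.mean()
    yc = yv - yv.mean()
    denom = np.sqrt((gc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0, 1.0
    r = float((gc * yc).sum() / denom)
    stat = m * r * r
    return stat, float(chi2.sf(stat, df=1))


def armitage_trend_all(dosages: np.ndarray, y: Phenotype):
    """Vectorized trend test across all SNP columns -> (chi2, p) arrays."""
    G = np.asarray(dosages, dtype=float)
    yv = np.asarray(y.y, dtype=float)
    m = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = yv - yv.mean()
    sxx = (Gc**2).sum(axis=0)
    syy = (yc**2).sum()
    ok = sxx > 0
    r2 = np.zeros(G.shape[1])
    r2[ok] = (Gc[:, ok] * yc[:, None]).sum(axis=0)[ok] ** 2 / (sxx[ok] * syy)
    stat = m * r2
    return stat, chi2.sf(stat, df=1)


def pca_adjust_assoc(
    x: NormalizedGenotypes | np.ndarray,
    y: Phenotype,
    k_pcs: int = 10,
    seed: int | None = None,
):
    """Eigenstrat-style PCA-adjusted association test.

    Residualizes the trait and every genotype column on the top ``k_pcs``
    left singular vectors (plus the mean), then forms the statistic
    (m - k_pcs - 1) * r^2 of the residual correlation, referred to chi^2(1).
    Genotypes fully explained by the PCs are flagged degenerate (NaN).
    """
    from clustrat.grm import truncated_svd

    X = x.X if isinstance(x, NormalizedGenotypes) else np.asarray(x, dtype=float)
    m, n = X.shape
    if k_pcs >= m - 1:
        raise ValueError("k_pcs must be < m - 1")
    yv = np.asarray(y.y, dtype=float)
    yc = yv - yv.mean()
    Gc = X - X.mean(axis=0)
    if k_pcs > 0:
        U = truncated_svd(X, k_pcs, seed=seed).U_k
        yc = yc - U @ (U.T @ yc)
        Gc = Gc - U @ (U.T @ Gc)
    sxx = (Gc**2).sum(axis=0)
    syy = (yc**2).sum()
    degenerate = sxx <= 1e-12 * m
    sxx_safe = np.where(degenerate, 1.0, sxx)
    r2 = (Gc * yc[:, None]).sum(axis=0) ** 2 / (sxx_safe * syy)
    stat = (m - k_pcs - 1) * r2
    p = chi2.sf(stat, df=1)
    stat = np.where(degenerate, np.nan, stat)
    p = np.where(degenerate, np.nan, p)
    return stat, p


def genomic_inflation(pvals: np.ndarray) -> float:
    """lambda_GC: median chi^2(1) quantile of the p-values over the null
    median 0.4549; values above 1 indicate residual confounding."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable median")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def evaluate_detection(
    meta: MetaResult | np.ndarray,
    truth: SimTruth,
    threshold: float = 5e-8,
    method: str = "clustrat",
    replicate: int = 0,
) -> DetectionReport:
    """Count causal and spurious hits below ``threshold``.

    Accepts a MetaResult or a raw p-value array; NaN p-values (degenerate or
    untested SNPs) never count as hits.
    """
    p = meta.meta_p if isinstance(meta, MetaResult) else np.asarray(meta, float)
    if truth.causal_indices is None:
        raise ValueError("truth lacks causal indices")
    n = p.size
    causal_mask = np.zeros(n, dtype=bool)
    causal_mask[np.asarray(truth.causal_indices, dtype=int)] = True
    hits = np.zeros(n, dtype=bool)
    finite = np.isfinite(p)
    hits[finite] = p[finite] < threshold
    return DetectionReport(
        method=method,
        threshold=threshold,
        causal_detected=int((hits & causal_mask).sum()),
        spurious=int((hits & ~causal_mask).sum()),
        n_causal=int(causal_mask.sum()),
        n_snps=n,
        replicate=replicate,
    )


def tsds_diagnostic(
    tsds: np.ndarray, pvals: np.ndarray, bin_size: int = 50
) -> TsdsDiagnostic:
    """Residual-stratification diagnostic on trait-aligned SDS scores.

    SNPs are sorted by ascending p-value and averaged in consecutive bins of
    ``bin_size``; the slope of mean tSDS on bin rank (least squares) and the
    SNP-level Spearman correlation between tSDS and p quantify any monotone
    trend. Near-zero slope and correlation indicate well-corrected summary
    statistics.
    """
    t = np.asarray(tsds, dtype=float)
    p = np.asarray(pvals, dtype=float)
    if t.shape != p.shape:
        raise ValueError("tsds and pvals must have equal length")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = t.size
    n_bins = n // bin_size
    if n_bins < 2:
        raise ValueError("need at least two full bins for a slope")
    order = np.argsort(p, kind="stable")
    means = t[order][: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    rank = np.arange(n_bins, dtype=float)
    A = np.column_stack([np.ones(n_bins), rank])
    coef, res, *_ = np.linalg.lstsq(A, means, rcond=None)
    slope = float(coef[1])
    dof = n_bins - 2
    if dof > 0 and res.size:
        s2 = float(res[0]) / dof
        slope_se = float(np.sqrt(s2 / ((rank - rank.mean()) ** 2).sum()))
    else:
        slope_se = float("nan")
    rho, rho_p = spearmanr(t, p)
    return TsdsDiagnostic(bin_size, slope, slope_se, float(rho), float(rho_p), n_bins)


def read_tsds_file(path) -> pd.DataFrame:
    """Tab-delimited SNP, TSDS, P file (header required)."""
    df = pd.read_csv(path, sep="\t")
    need = {"SNP", "TSDS", "P"}
    if not need.issubset(df.columns):
        raise ValueError(f"tSDS file must have columns {sorted(need)}")
    return df


def detection_table(reports: list[DetectionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "replicate": r.replicate,
                "threshold": r.threshold,
                "causal_detected": r.causal_detected,
                "spurious": r.spurious,
                "n_causal": r.n_causal,
                "n_snps": r.n_snps,
            }
            for r in reports
        ]
    )
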
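"""Synthetic genotype and phenotype generators for stratified populations.

Four genotype models cover the standard stratification test-bed:

* **BN** (Balding-Nichols): d discrete populations; each SNP has an
  ancestral frequency p, and population c draws its own frequency from
  Beta(p(1-F)/F, (1-p)(1-F)/F) so that the between-population variance is
  F_ST * p(1-p). Genotypes are Binomial(2, p_c).
* **PSD** (Pritchard-Stephens-Donnelly): population frequencies as in BN,
  but each individual has Dirichlet(alpha) admixture proportions over the d
  sources; small alpha recovers discrete populations, large alpha a single
  panmictic pool.
* **FREQ**: genotypes drawn directly from a user-supplied d x n per-
  population allele-frequency table (e.g. frequencies estimated from a
  reference panel).
* **MOSAIC**: two-or-more-source admixture where each sample's chromosome
  is a mosaic of contiguous ancestry blocks of ``segment_len`` SNPs, each
  block's source drawn uniformly -- crude LD through local ancestry.

Phenotypes follow the additive liability model used by GCTA's trait
simulator: a chosen set of causal SNPs gets N(0,1) effects on standardized
genotypes, environmental noise is scaled for a target heritability, and
binary traits label the top case_fraction of the liability distribution as
cases (so the realized case count is exact, not just in expectation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from clustrat.io_genotype import GenotypeMatrix, NormalizedGenotypes, Phenotype


@dataclass
class SimulationConfig:
    model: str = "BN"  # BN | PSD | FREQ | MOSAIC
    m: int = 1000
    n: int = 5000
    d: int = 3
    fst: float = 0.1
    alpha: float = 0.1
    anchor_freq_range: tuple[float, float] = (0.05, 0.95)
    segment_len: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model in ("BN", "PSD") and not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if self.model == "PSD" and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.segment_len < 1:
            raise ValueError("segment_len must be >= 1")


@dataclass
class PhenotypeConfig:
    n_causal: int = 100
    h2: float = 0.5
    case_fraction: float = 0.2
    trait_kind: str = "binary"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("heritability h2 must lie in [0, 1]")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data, for evaluation."""

    pop_labels: np.ndarray | None = None
    admixture_proportions: np.ndarray | None = None
    causal_indices: np.ndarray | None = None
    effect_sizes: np.ndarray | None = None
    liability: np.ndarray | None = None
    ancestry_fractions: np.ndarray | None = None


def _variant_meta(n: int) -> list[tuple[str, str, int, str, str]]:
    return [("1", f"snp{j}", j + 1, "A", "G") for j in range(n)]


def _sample_ids(m: int) -> list[str]:
    return [f"sample{i}" for i in range(m)]


def _pop_split(m: int, d: int) -> np.ndarray:
    """Near-equal split of m samples into d populations (0-based labels)."""
    return np.repeat(np.arange(d), np.diff(np.linspace(0, m, d + 1).astype(int)))


def bn_population_frequencies(cfg: SimulationConfig, rng: np.random.Generator):
    """Ancestral and per-population allele frequencies under the BN model."""
    lo, hi = cfg.anchor_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n)
    F = cfg.fst
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    p_pop = rng.beta(a, b, size=(cfg.d, cfg.n))
    return p_anc, np.clip(p_pop, 1e-12, 1 - 1e-12)


def _draw_genotypes(prob: np.ndarray, rng: np.random.Generator,
                    max_regen: int = 10) -> np.ndarray:
    """Binomial(2, prob) draws; monomorphic columns are redrawn up to
    ``max_regen`` times and dropped only if still flat."""
    dos = rng.binomial(2, prob).astype(np.int8)
    for _ in range(max_regen):
        mono = dos.min(axis=0) == dos.max(axis=0)
        if not mono.any():
            break
        cols = np.flatnonzero(mono)
        dos[:, cols] = rng.binomial(2, prob[:, cols]).astype(np.int8)
    return dos


def simulate_bn(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Discrete-population genotypes under the Balding-Nichols model."""
    rng = np.random.default_rng(cfg.seed)
    _, p_pop = bn_population_frequencies(cfg, rng)
    labels = _pop_split(cfg.m, cfg.d)
    prob = p_pop[labels]  # m x n
    dos = _draw_genotypes(prob, rng)
    g = GenotypeMatrix(dos, _sample_ids(cfg.m), _variant_meta(cfg.n))
    return g, SimTruth(pop_labels=labels)


def simulate_psd(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Admixed genotypes: Dirichlet(alpha) ancestry mixing of BN sources."""
    rng = np.random.default_rng(cfg.seed)
    _, p_pop = bn_population_frequencies(cfg, rng)
    q = rng.dirichlet(np.full(cfg.d, cfg.alpha), size=cfg.m)  # m x d
    prob = q @ p_pop  # individual allele frequencies
    dos = _draw_genotypes(np.clip(prob, 1e-12, 1 - 1e-12), rng)
    g = GenotypeMatrix(dos, _sample_ids(cfg.m), _variant_meta(cfg.n))
    return g, SimTruth(admixture_proportions=q,
                       pop_labels=np.argmax(q, axis=1))


def simulate_mosaic(
    cfg: SimulationConfig, source_freqs: np.ndarray
) -> tuple[GenotypeMatrix, SimTruth]:
    """Mosaic-chromosome admixture from a d x n source frequency table.

    Each sample's SNP axis is split into contiguous blocks of
    ``segment_len`` SNPs; every block picks its source population uniformly
    at random, independently per sample.
    """
    source_freqs = np.asarray(source_freqs, dtype=float)
    d, n = source_freqs.shape
    if d < 2:
        raise ValueError("mosaic model needs at least 2 source populations")
    if cfg.segment_len > n:
        raise ValueError(f"segment_len={cfg.segment_len} exceeds n={n}")
    if source_freqs.min() < 0 or source_freqs.max() > 1:
        raise ValueError("source frequencies must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    n_blocks = -(-n // cfg.segment_len)
    block_src = rng.integers(0, d, size=(cfg.m, n_blocks))
    snp_block = np.arange(n) // cfg.segment_len
    src = block_src[:, snp_block]  # m x n ancestry per SNP
    prob = source_freqs[src, np.arange(n)[None, :]]
    dos = rng.binomial(2, prob).astype(np.int8)
    frac = np.stack([(src == c).mean(axis=1) for c in range(d)], axis=1)
    g = GenotypeMatrix(dos, _sample_ids(cfg.m), _variant_meta(n))
    return g, SimTruth(ancestry_fractions=frac,
                       pop_labels=np.argmax(frac, axis=1))


def simulate_from_freqs(
    freq_table: np.ndarray, pop_sizes, seed: int | None = None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Genotypes drawn from a per-population allele-frequency table."""
    freq_table = np.asarray(freq_table, dtype=float)
    if freq_table.min() < 0 or freq_table.max() > 1:
        raise ValueError("frequencies must lie in [0, 1]")
    pop_sizes = np.asarray(pop_sizes, dtype=int)
    if pop_sizes.shape[0] != freq_table.shape[0]:
        raise ValueError("one population size per frequency row required")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(pop_sizes.size), pop_sizes)
    prob = freq_table[labels]
    dos = rng.binomial(2, prob).astype(np.int8)
    m, n = dos.shape
    g = GenotypeMatrix(dos, _sample_ids(m), _variant_meta(n))
    return g, SimTruth(pop_labels=labels)


def simulate_phenotype(
    x: NormalizedGenotypes, cfg: PhenotypeConfig
) -> tuple[Phenotype, SimTruth]:
    """Additive liability-model trait on standardized genotypes.

    Causal SNPs are chosen uniformly without replacement with effects
    beta_j ~ N(0,1); the genetic value is g_i = sum_j beta_j X_ij and
    environmental noise has variance var(g)(1-h2)/h2 so that g explains a
    fraction h2 of the liability variance. Quantitative traits return the
    liability; binary traits label the top round(case_fraction*m)
    liabilities as cases, making the realized case count exact.
    """
    import warnings

    m, n = x.X.shape
    if cfg.n_causal > n:
        raise ValueError(f"n_causal={cfg.n_causal} exceeds n={n}")
    if cfg.h2 == 0.0 and cfg.trait_kind == "binary" and cfg.n_causal > 0:
        warnings.warn("h2=0 with causal SNPs: trait is pure noise")
    rng = np.random.default_rng(cfg.seed)
    causal = np.sort(rng.choice(n, size=cfg.n_causal, replace=False))
    beta = rng.standard_normal(cfg.n_causal)
    gvalue = x.X[:, causal] @ beta if cfg.n_causal else np.zeros(m)
    var_g = gvalue.var()
    if cfg.h2 == 1.0:
        noise = np.zeros(m)
    elif cfg.h2 == 0.0 or var_g == 0.0:
        noise = rng.standard_normal(m)  # pure-noise trait; scale arbitrary
    else:
        noise = rng.normal(0.0, np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2), size=m)
    liability = gvalue + noise

    truth = SimTruth(causal_indices=causal, effect_sizes=beta, liability=liability)
    if cfg.trait_kind == "quantitative":
        return Phenotype(liability, "quantitative"), truth
    n_cases = int(round(cfg.case_fraction * m))
    n_cases = min(max(n_cases, 1), m - 1)
    order = np.argsort(liability, kind="stable")
    y = np.zeros(m)
    y[order[-n_cases:]] = 1.0
    return Phenotype(y, "binary"), truth


def hudson_fst(dosages: np.ndarray, labels: np.ndarray) -> float:
    """Hudson estimator of F_ST, averaged as ratio-of-sums over SNPs and
    population pairs (the recommended Bhatia et al. combination)."""
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if pops.size < 2:
        raise ValueError("need at least two populations")
    num = den = 0.0
    D = np.asarray(dosages, dtype=float)
    for a in range(pops.size):
        for b in range(a + 1, pops.size):
            ia, ib = labels == pops[a], labels == pops[b]
            n1, n2 = 2 * ia.sum(), 2 * ib.sum()
            p1 = D[ia].mean(axis=0) / 2.0
            p2 = D[ib].mean(axis=0) / 2.0
            num += np.sum((p1 - p2) ** 2
                          - p1 * (1 - p1) / (n1 - 1)
                          - p2 * (1 - p2) / (n2 - 1))
            den += np.sum(p1 * (1 - p2) + p2 * (1 - p1))
    return float(num / den)


def write_truth(truth: SimTruth, g: GenotypeMatrix, prefix) -> None:
    """Tab-delimited ground-truth sidecar files next to a PLINK fileset."""
    from pathlib import Path

    prefix = Path(prefix)
    if truth.causal_indices is not None:
        with open(f"{prefix}.causal.tsv", "w") as fh:
            fh.write("SNP\tEFFECT\n")
            for j, b in zip(truth.causal_indices, truth.effect_sizes):
                fh.write(f"{g.variants[j][1]}\t{b:.6g}\n")
    if truth.pop_labels is not None or truth.admixture_proportions is not None:
        with open(f"{prefix}.pops.tsv", "w") as fh:
            if truth.admixture_proportions is not None:
                d = truth.admixture_proportions.shape[1]
                fh.write("IID\t" + "\t".join(f"Q{c}" for c in range(d)) + "\n")
                for sid, row in zip(g.samples, truth.admixture_proportions):
                    fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
            else:
                fh.write("IID\tPOP\n")
                for sid, lab in zip(g.samples, truth.pop_labels):
                    fh.write(f"{sid}\t{lab}\n")
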
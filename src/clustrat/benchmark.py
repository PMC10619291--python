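"""Scenario runner: simulate stratified cohorts and compare association
methods on causal/spurious detection counts.

One replicate = one simulated genotype matrix + binary trait; every method
(Mahalanobis-clustered meta-analysis, uncorrected Armitage trend, and the
PCA-adjusted test) is scored against the same ground truth at a genome-wide
threshold. Per-replicate seeds are spawned from the master seed so the grid
is reproducible and embarrassingly parallel.
"""

from __future__ import annotations

import numpy as np

from clustrat.baselines import (
    DetectionReport,
    armitage_trend_all,
    evaluate_detection,
    pca_adjust_assoc,
)
from clustrat.core import ClustratConfig, clustrat
from clustrat.io_genotype import impute_and_normalize
from clustrat.simulate import (
    PhenotypeConfig,
    SimulationConfig,
    simulate_bn,
    simulate_phenotype,
    simulate_psd,
)

METHODS = ("clustrat", "armitage", "pca_adjust")


def _child_seed(master_seed: int, replicate: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(replicate,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_replicate(
    sim_cfg: SimulationConfig,
    phe_cfg: PhenotypeConfig,
    replicate: int = 0,
    threshold: float = 5e-8,
    k_pcs: int = 10,
    use_cv: bool = False,
    methods=METHODS,
) -> list[DetectionReport]:
    """Simulate one cohort and score each method against the truth."""
    if sim_cfg.model == "BN":
        g, _ = simulate_bn(sim_cfg)
    elif sim_cfg.model == "PSD":
        g, _ = simulate_psd(sim_cfg)
    else:
        raise ValueError(f"benchmark supports BN/PSD, got {sim_cfg.model!r}")
    x = impute_and_normalize(g)
    y, truth = simulate_phenotype(x, phe_cfg)

    reports = []
    if "clustrat" in methods:
        cfg = ClustratConfig(
            n_clusters=None if use_cv else sim_cfg.d,
            d=sim_cfg.d,
            seed=sim_cfg.seed,
        )
        meta, _ = clustrat(x, y, cfg)
        reports.append(evaluate_detection(meta, truth, threshold,
                                          "clustrat", replicate))
    if "armitage" in methods:
        _, p = armitage_trend_all(g.dosages[:, x.kept_variants], y)
        reports.append(evaluate_detection(p, truth, threshold,
                                          "armitage", replicate))
    if "pca_adjust" in methods:
        _, p = pca_adjust_assoc(x, y, k_pcs=k_pcs, seed=sim_cfg.seed)
        reports.append(evaluate_detection(p, truth, threshold,
                                          "pca_adjust", replicate))
    return reports


def run_grid(
    sim_cfg: SimulationConfig,
    phe_cfg: PhenotypeConfig,
    n_replicates: int,
    master_seed: int,
    threshold: float = 5e-8,
    k_pcs: int = 10,
    use_cv: bool = False,
    methods=METHODS,
) -> list[DetectionReport]:
    """Replicate grid with counter-derived per-replicate seeds."""
    from dataclasses import replace

    reports = []
    for rep in range(n_replicates):
        seed = _child_seed(master_seed, rep)
        sc = replace(sim_cfg, seed=seed)
        pc = replace(phe_cfg, seed=seed + 1)
        reports.extend(
            run_replicate(sc, pc, replicate=rep, threshold=threshold,
                          k_pcs=k_pcs, use_cv=use_cv, methods=methods)
        )
    return reports
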
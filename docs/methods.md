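# Methods

## Model and procedure

The package corrects for population stratification in GWAS by partitioning
samples into genetically homogeneous clusters and meta-analyzing per-cluster
association tests, instead of adjusting a single pooled regression with
principal components. The steps, and the assumptions behind each:

1. **Normalization.** Genotype dosages (minor-allele counts 0/1/2) are
   mean-imputed per SNP and standardized column-wise to mean 0 and variance 1.
   The population (1/m) variance convention is used so the unit-variance
   contract is exact; the (m−1) factor of the distance identity is carried
   explicitly by the distance formulas. Standardization is empirical rather
   than the 2p(1−p) binomial form: the Mahalanobis distance is invariant to
   linear column rescalings, so the two choices give identical distances.
   Monomorphic SNPs are dropped (they carry no information and would divide
   by zero); variants above a 10% missingness ceiling are dropped; a
   minor-allele-frequency floor (`min_maf`, default 0 = off) implements
   standard QC.

2. **Rank-k Mahalanobis GRM.** With X = U S Vᵀ, the rank-k regularized
   Mahalanobis distance (SNP covariance G = XᵀX/(m−1) truncated to its top-k
   eigenspace) reduces to leverage/cross-leverage scores H = U_k U_kᵀ:
   D_ij = (m−1)(H_ii + H_jj − 2H_ij). The n×n covariance is never formed.
   The brute-force path (`mahalanobis_bruteforce`) materializes the rank-k
   pseudo-inverse and evaluates every quadratic form directly; it exists as
   an independent correctness oracle, not a production path. Its
   origin-distance output is the raw quadratic form (m−1)H_ii, whereas the
   leverage-path `D_origin` carries the −1/m centering offset of the
   row-centered derivation; the offset cancels in every pairwise distance,
   which is all that clustering uses.

3. **Choice of the rank k.** The truncated-whitened distance weighs every
   retained singular direction equally. Directions beyond the population
   structure are (scaled) noise, so retaining them dilutes the between-
   population signal: empirically, recovery of d simulated populations is
   perfect at k = d−1 (the dimension of the frequency simplex after column
   centering) and degrades quickly for larger k. The pipeline therefore
   resolves its default rank to d−1 when the number of source populations d
   is supplied, and to 10 (a conventional top-PC count) otherwise; both are
   overridable (`k_svd`). An optional ridge variant, (G_k + ε·mean-eigenvalue
   ·I)⁻¹ via `ridge`, interpolates between the pure whitened distance and
   Euclidean distance on leading principal-component scores and is more
   forgiving of k; it is off by default because the plain truncated form is
   the documented contract.

4. **Clustering.** Agglomerative hierarchical clustering runs on √D (D holds
   squared distances; √D is a metric, so linkage heights respect the triangle
   inequality). Average linkage is the default — Ward assumes Euclidean
   geometry, and average is the standard choice for precomputed
   dissimilarities; complete and single are available. The cluster count is
   either fixed by the caller, chosen by five-fold cross-validation over
   candidates d, d+1, …, d+q (score: per-fold size of the cross-cluster
   intersection of SNPs significant at `alpha_sel`, averaged over folds, ties
   to the smallest k), or — when d is unknown — seeded by inconsistency
   pruning of the dendrogram (coefficient over a depth-2 window, threshold
   1.15, the conventional defaults).

5. **Association and meta-analysis.** Within each cluster every SNP is
   tested univariately: OLS for quantitative traits, logistic regression for
   binary ones, Wald z and two-sided normal p. The logistic solver is a
   vectorized two-parameter Newton iteration with step damping and a ridge
   fallback on detected quasi-separation; it matches reference per-SNP fits
   to 1e-5. Clusters below `min_cluster_size` (50) samples, or with fewer
   than 10 cases or 10 controls, are skipped with a warning — Wald statistics
   are unreliable there. Constant-genotype or separated fits are flagged
   `skipped-degenerate` per SNP. Cluster results combine with the classic
   sample-size-weighted z rule, Z = Σ w_c z_c/√(Σ w_c²), w_c = √n_c
   (inverse-variance weighting available by flag).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k_svd` | d−1 if d given, else 10 | rank of the truncated SVD / distance |
| `ridge` | 0 (off) | relative ridge on the truncated covariance |
| `linkage_method` | average | AHC linkage on √D |
| `n_clusters` / `d`, `q_range` | CV over d…d+3 | cluster count selection |
| `folds` | 5 | CV folds |
| `alpha_sel` | 1e-4 | significance level inside the CV score (5×10⁻⁸ is too sparse at simulation scale to rank candidates) |
| `min_cluster_size` | 50 (and ≥10 per class) | smallest cluster tested |
| `meta_method` | sample_size_z | meta-analysis rule |
| detection threshold | 5×10⁻⁸ | genome-wide significance |

## Synthetic data

The generators reproduce the standard stratification test-bed:

* **Balding-Nichols**: per SNP an ancestral frequency p ~ Uniform(0.05,
  0.95) (configurable; a supplied frequency table can replace it), and each
  of d populations draws p_c ~ Beta(p(1−F)/F, (1−p)(1−F)/F), giving
  between-population variance F·p(1−p). Genotypes are Binomial(2, p_c);
  samples split near-equally across populations. The Hudson F_ST estimator
  on the output recovers the configured F within Monte-Carlo error.
* **PSD admixture**: per-individual Dirichlet(α) ancestry proportions mix
  the BN population frequencies; α → 0 recovers discrete populations, large
  α a panmictic pool.
* **Mosaic chromosomes**: contiguous blocks of `segment_len` SNPs each draw
  a source population uniformly at random per sample — a crude form of local
  ancestry and block LD.
* **Phenotypes** follow the GCTA additive model: causal SNPs chosen
  uniformly, effects β ~ N(0,1) on standardized genotypes, environmental
  noise scaled to the target h² of liability, and binary traits assign the
  top round(case_fraction·m) liabilities as cases, making the realized case
  fraction exact by construction rather than in expectation (top-quantile
  thresholding of the liability).

What the generators do **not** emulate: recombination-map LD within
populations (SNPs are independent given ancestry, except for mosaic-block
correlation), genotyping error, call-rate structure, relatedness pedigrees,
or realistic minor-allele-frequency spectra. Consequently, passing tests
show that the method corrects *structure-induced* confounding at simulation
scale; they do not certify behavior under dense LD or family structure.

Confounding in these simulations arises only through the causal SNPs'
between-population frequency differences (the trait has no explicit
environmental ancestry effect), so the strength of the uncorrected test's
spurious-hit excess varies across replicates with the random causal draw;
the comparison aggregates over ten replicates.

## Numerical choices

* Truncated SVD uses Lanczos iteration (`scipy.sparse.linalg.svds`) with a
  seeded start vector for reproducibility, falling back to a full SVD for
  small matrices or near-full rank; singular values are returned descending.
* The brute-force oracle refuses retained singular values below 1e-10·S₁
  (rank deficiency).
* Distances are symmetrized and clipped at 0; the diagonal is set to exactly
  0 before linkage.
* Logistic Newton: 40 damped iterations at tol 1e-8, then a ridge pass;
  fits with |β| > 20 or a singular 2×2 Hessian are flagged degenerate.
* p-values are floored at the smallest positive double to keep the (0,1]
  contract; z and p are kept mutually consistent under the normal reference.
* Tie-breaks: CV score ties go to the smallest candidate k; `cut_to_k` uses
  the maxclust criterion, so all-zero distances yield fewer than k distinct
  groups (degenerate input, documented).
* Within-cluster p-values from the linear path are uniform under a permuted
  trait at the KS level once a MAF ≥ 0.05 floor is applied; rare variants
  give discrete test statistics (few carrier configurations) whose pooled
  p-values are detectably non-uniform, and the logistic Wald z carries a
  known ≈2% small-sample deficit in E[z²] at cluster sizes of a few hundred
  (λ_GC ≈ 0.97–0.99). The null-calibration checks therefore use the linear
  path with the MAF floor; this is a property of Wald tests, not of the
  clustering.

## Known limitations

* The rank-k distance needs k near the true structure dimension; with the
  default k = 10 and only two or three latent populations, cluster recovery
  fails (equal-weight noise directions dominate). Supply d, set `k_svd`, or
  use `ridge` when the structure dimension is unknown.
* Logistic association ignores covariates (the linear path residualizes
  them); mixed-model association is out of scope.
* The brute-force Mahalanobis path is O(m²n + n²k) and intended for tests
  only. H is dense m×m: memory is the binding constraint beyond a few tens
  of thousands of samples; out-of-core SVD is out of scope.
* The CV score's "intersection of significant SNPs across clusters" is one
  consistent reading of cross-cluster replication; it is isolated in
  `select_k_cv` for easy replacement.
* tSDS diagnostics operate on user-supplied precomputed scores; computing
  SDS itself is out of scope.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at simulation scale chosen as
the package's own desk-scale conditions: oracle agreement on 50–200 random
instances (m ≤ 30, n ≤ 100, k ≤ 5); population recovery at m = 300,
n = 2000, F_ST = 0.1; null calibration and the detection comparison at
m = 1000, n = 5000 (ten replicates, 50 causal SNPs, h² = 0.5, 20% cases);
simulator fidelity at m = 5000 (liability R²) and m = 2000, n = 5000
(Hudson F_ST).
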
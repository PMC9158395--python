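# Methods

This note documents the models, parameter choices and numerical policies
behind hippoclust, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Synthetic cohort generator

The generator states a two-cluster world and every downstream claim is
conditional on it.

**Sizes and completeness.** 126 subjects are enrolled; the first 104 carry
both imaging and insulin-suppression-test data, and the remaining 22 miss
one or both in a fixed deterministic pattern. Determinism (rather than
random dropout) makes the completeness filter exactly testable. Latent
cluster labels among complete subjects are a seeded permutation of exactly
51 ones and 53 twos.

**Metabolic panel.** Per latent cluster, the seven panel variables are
drawn from a zero-truncated multivariate distribution built as a Gaussian
copula: a latent normal vector with the configured 7×7 correlation matrix
is mapped through per-variable truncated-normal marginals. The marginal
parameters are solved by moment matching (`truncnorm_params`) so that the
configured mean and SD are the moments of the *generated* values. This
matters: naively truncating N(40.36, 29.97) at zero would inflate the
cluster-1 leptin mean by ≈ +5 μg/L and make the configured truth
unrecoverable by any downstream estimator.

Where published per-cluster statistics exist (SSPG, leptin; cluster sizes;
female fractions 0.75/0.45) they are used verbatim. BMI and FPG cluster
marginals are not published; they were calibrated *analytically* (normal
mixture tail probabilities, fixed before any test was run) so the
generated mixture reproduces the published cohort-level category
percentages — ≈13/51/36% for the BMI classes and ≈86% normal fasting
glucose: BMI ~ N(30.0, 2.8) vs N(27.4, 2.2) kg/m², FPG ~ N(95, 6.5) vs
N(91, 5.5) mg/dL. WC, FPI and cortisol means/SDs are plausible clinical
values (cortisol deliberately cluster-invariant and near-uncorrelated with
the rest, mirroring the published association structure). The correlation
matrix plants moderate positive correlations (0.35–0.8) among the
adiposity/insulin-resistance block and 0.05 for cortisol.

The BMI category cut-offs in the source table leave integer gaps
(normal ≤ 25, overweight 26–<29, obese ≥ 30), consistent with
integer-rounded BMI; the classifier therefore rounds BMI to the nearest
integer, i.e. continuous boundaries at 25.5 and 29.5.

**Cognition, motion, demographics.** IQ, the two episodic-memory subtest
scores and head motion are cluster-invariant by design (the original
clusters did not differ on them); age is a truncated normal (54 ± 9, range
25–75); ethnicity is a generic 4-level categorical, since the source does
not enumerate levels; cortisol units are treated as arbitrary assay units.

## 2. BOLD factor model

Each subject's ROI time series follow a white-noise factor model on a
24×24×12 voxel grid with T = 200 timepoints:

* hippocampus `h ∈ {L, R}`: voxels `x_v(t) = √ρ_w s_h(t) + √(1−ρ_w) ε_v(t)`
  with unit-variance white `s_h`, `ε_v` — the equicorrelated model, every
  voxel pair correlating at `ρ_w`;
* RSN `j`: generator `g_j = c_{Lj} s_L + c_{Rj} s_R + √(1−c_{Lj}²−c_{Rj}²) ν_j`,
  so `corr(g_j, s_h) = c_{hj}`; RSN voxels follow the equicorrelated model
  around `g_j` at ρ_rsn = 0.9 (the RSN voxel mean is then nearly the
  generator itself);
* all non-ROI voxels are independent noise.

Two closed forms anchor the tests: the leave-one-out voxel correlation
under the equicorrelated model is `ρ√((V−1)/(1+(V−2)ρ))`, and the
correlation of a V-voxel mean with its factor is `√(Vρ/(1+(V−1)ρ))`.

**Effect sizes.** `ρ_w` is (0.25, 0.40) and the cross-couplings centre on
(0.40, 0.55) for clusters 1 and 2 — cluster 1 lower throughout, the
planted direction. Per subject, each of the ten correlation parameters
(2 within + 2×4 couplings) receives independent Gaussian jitter on the
Fisher-z scale (SD 0.115), then clipping into [0.01, 0.95] (within) and
[0.01, 0.70] (couplings; the generator construction needs
`c_L² + c_R² < 1`). The jitter SD was calibrated to satisfy two design
targets simultaneously: standardized between-cluster feature gaps of
≈ 0.8–1.2 (measured 1.14–1.23 — the upper edge of the band, the price of
the second target) and reliable label recovery (ARI ≥ 0.8 vs. the planted
labels in ≥ 90% of seeds). Without jitter the gaps would be ~4 SD and
recovery trivially perfect.

**Determinism.** Per-subject streams are derived by hashing (master seed,
subject id), so generation is order-independent and parallelisable. ROI
blocks are drawn before background noise, so the background-free fast path
(`simulate_roi_series`, used for cohort-level feature computation) is
bitwise identical to extracting the same ROIs from the full 4D volume.

**What the simulator does not emulate.** No hemodynamic response, temporal
autocorrelation, physiological noise spectra, scanner drift, motion
artifacts, spatial smoothness, or anatomically realistic ROI geometry
(masks are boxes). A green recovery test therefore establishes that the
*pipeline* recovers the structure it assumes, not that the statistics are
robust to realistic fMRI noise.

## 3. Connectivity statistics

The cohesiveness sentence in the source is ambiguous between (a) each
voxel vs. the mean of all others and (b) the mean of all pairwise voxel
correlations. The default is (a), the literal reading; (b) is available
via `method="pairwise"`. Per-voxel correlations are Fisher-transformed and
*then* averaged (`aggregate="mean_z"`; the alternative `z_of_mean_r` is a
switch). The Fisher transform is applied to integration as well — stated
in the source only for cohesiveness — so the 18-feature block shares one
scale; raw correlations are available via `fisher=False`. Correlations at
±1 are clipped at 1 − 1e-7 before `atanh` to keep features finite
(`atanh(1−1e-7) ≈ 8.41`). Voxel series with sample SD < 1e-12 are dropped
(not imputed) with a logged count. Feature order is fixed and documented
(`CONNECTIVITY_FEATURES`): 2 cohesiveness values, then integration ordered
hemisphere → segment (posterior, anterior) → network (CEN, SAL, VIS, SMN).

## 4. Association matrices

"Regressing out" age and sex is implemented as per-variable OLS on
[intercept, age, sex] (the source does not specify the form); sex is coded
female = 1, and residuals are invariant to a coding swap. Spearman uses
mid-ranks for ties with t-approximation p-values (the n ≈ 104 regime).
No multiple-testing correction is applied in the matrix, matching the
source's descriptive p < 0.05 convention — a deliberate
faithful-reproduction choice, not a recommendation.

## 5. Clustering

Features are z-scored (sample SD) before k-means — mg/dL and Fisher-Z
units are incommensurable and unscaled distances would be dominated by
SSPG variance. k-means uses k-means++ seeding, 50 restarts, Lloyd
iterations to tolerance 1e-8 (scikit-learn backend; empty clusters are
relocated to far points). Candidate k is 2–8 (unstated in the source);
ties in the vote break toward smaller k (parsimony).

The index suite is fixed at 13 named indices so a 7-vote plurality is
meaningful (the original used a larger unnamed battery). Orientations:
maximise Calinski–Harabasz, silhouette, Dunn, Krzanowski–Lai,
Ratkowsky–Lance, point-biserial; minimise Davies–Bouldin, C-index,
McClain–Rao; rule-based votes for the gap statistic (uniform bounding-box
reference, 50 draws, one-SE rule), Hartigan (smallest k with H(k) ≤ 10,
falling back to the largest successive drop), Ball–Hall (largest
successive difference of W/k) and trace-W (largest second difference —
elbow). An index abstains where undefined (singleton clusters, zero
denominators) and abstentions are recorded; selection errors out if fewer
than three indices can vote. Every label-based index is verified against
an independent naive-formula oracle, and k-means against exhaustive
partition enumeration at n ≤ 8.

Cluster numbering is canonicalised by metabolic deviance — the mean of
standardized SSPG and leptin per cluster, descending, with exact ties
broken by cluster size (logged). The supplementary variant clusters on the
7 metabolic columns only.

## 6. Cluster comparison

The normality gate is Shapiro–Wilk at α = 0.05 on pooled within-cluster
residuals (the source's criterion is unstated; residualising around
cluster means prevents a pure location shift from triggering the gate).
Normal-looking variables get Welch's t; the rest Mann–Whitney U — exact
enumeration when min(n) ≤ 8 and tie-free, otherwise normal approximation
with continuity correction. Categorical variables: Pearson chi-square
(Yates-corrected for 2×2, uncorrected for larger tables), with a Fisher
exact fallback for sparse 2×2 tables; larger sparse tables stay chi-square
with a warning (no exact r×c test in the stack). No multiple-testing
correction by default, `adjust="bh"` adds Benjamini–Hochberg.

## 7. Numerical and degenerate-input policies

* correlation clip ε = 1e-7; zero-variance threshold SD < 1e-12;
* correlation-matrix PSD check at eigenvalue ≥ −1e-10 (a 1e-12 ridge is
  added before Cholesky);
* probabilistic masks binarise at 0.5 unless a threshold is given; masks
  and volumes must share the exact lattice (no resampling — inputs are
  assumed fully preprocessed);
* constant covariates drop from the residualisation design with a warning;
  any other rank deficiency is an error;
* n < 8 or constant input defaults the normality gate to "nonnormal" with
  a warning; all-tied two-sample data raises an undefined-test error;
* subjects without a latent cluster cannot be simulated (real data enters
  through the I/O path instead).

## 8. Known limitations

* The voxel simulator's white-noise assumption makes Monte-Carlo SEs
  smaller than real fMRI would give; recovery percentages are
  generator-conditional.
* Integration values for the two segments of one hemisphere share a
  coupling parameter by construction, so those feature pairs are more
  correlated than real segment-specific connectivity might be.
* The gap statistic is the one stochastic validity index; its vote
  depends (reproducibly) on the seed.
* The association matrix's p-values are descriptive; no correction is
  applied by design.
* The comparison report treats ethnicity with chi-square even when sparse
  (warning emitted) because no exact r×c test is available in the
  dependency set.
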
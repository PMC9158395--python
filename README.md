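# hippoclust

Metabolic–hippocampal-connectivity phenotyping of healthy adults:
a reproducible re-implementation of a resting-state fMRI clustering
analysis, exercised end to end on a synthetic cohort with a planted
two-cluster structure.

## The scientific problem

Insulin resistance, adiposity and the hormones they dysregulate (leptin,
insulin, cortisol) are suspected to erode hippocampal function long before
any cognitive deficit appears. One way to probe this in healthy adults is
to summarise each person's resting-state BOLD signal as a small set of
hippocampal connectivity statistics, combine them with a metabolic panel,
and ask whether unsupervised clustering stratifies people into
metabolically deviant vs. healthy subgroups with correspondingly lower
hippocampal connectivity.

The pipeline computes, per subject:

* **Cohesiveness** (one value per hemisphere): for each hippocampal voxel
  `v`, the Pearson correlation `r_v` of its BOLD series with the average
  series of all other hippocampal voxels; the statistic is
  `mean_v atanh(r_v)` (Fisher-Z units).
* **Integration** (16 values): `atanh(corr(mean series of segment, mean
  series of RSN))` for posterior (dentate gyrus) and anterior
  (CA1/subiculum) segments of each hippocampus against four resting-state
  networks (CEN, SAL, VIS, SMN).

These 18 features plus 7 metabolic measures (BMI, waist circumference,
SSPG from the insulin suppression test, fasting insulin and glucose,
leptin, cortisol) are z-scored and clustered by k-means; the number of
clusters is chosen by **majority vote of 13 cluster-validity indices**
(Calinski–Harabasz, silhouette, Davies–Bouldin, Dunn, C-index,
McClain–Rao, gap statistic, Hartigan, Krzanowski–Lai, Ratkowsky–Lance,
Ball–Hall, point-biserial, trace-W elbow). Clusters are ordered by
metabolic deviance (standardized SSPG + leptin), compared with
normality-gated tests, and the whole measure set is summarised in an
age/sex-adjusted Spearman association matrix.

Because the original cohort is private, the package ships a synthetic
generator (`table2_defaults.yaml`) whose defaults encode the published
two-cluster world: 126 enrolled / 104 complete subjects, cluster sizes
51/53, SSPG 161.63 (65.27) vs. 125.72 (66.81) mg/dL, leptin 40.36 (29.97)
vs. 27.59 (25.58) μg/L, female fractions 0.75/0.45, and voxel-level BOLD
data from an equicorrelated factor model whose within-hippocampus and
hippocampus–RSN correlations differ by latent cluster. Every stage of the
analysis is therefore testable against a known ground truth.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 42
python analysis/02_connectivity_features.py --seed 42
python analysis/03_association_matrix.py
python analysis/04_cluster.py --seed 42
python analysis/05_compare_clusters.py
```

Script 01 prints the cohort composition — the completeness filter keeps
exactly 104 of 126, and the default marginals land on the published
category percentages:

```
enrolled subjects:        126
complete (imaging + IST): 104
planted cluster sizes:    51 / 53
BMI normal                14 (13%)
BMI overweight            50 (48%)
BMI obese                 40 (38%)
FPG < 100 mg/dL:          88 (85%)
```

Script 04 shows the majority vote and the recovered stratification (11 of
13 indices endorse k = 2 on this seed; the higher-deviance cluster has
higher SSPG and leptin):

```
vote tally: {2: 11, 4: 1, 8: 1}  ->  chosen k = 2
cluster 1: n =  50; SSPG 153.5 mg/dL, leptin 34.5 ug/L
cluster 2: n =  54; SSPG 124.4 mg/dL, leptin 27.7 ug/L
```

Script 05 reports that SSPG, adiposity measures and all 18 connectivity
features separate the clusters at p < 0.05 while head motion does not.
Across many seeds (`analysis/06_recovery_experiment.py --n-seeds 50`)
recovery is unbiased:

```
chosen k = 2 in 100% of seeds
cluster-1 size: mean 50.5 (planted 51)
cluster-1 SSPG: mean 162.97 mg/dL (configured 161.63)
cluster-1 leptin: mean 41.52 ug/L (configured 40.36)
ARI vs latent labels: mean 0.903, >=0.8 in 92% of seeds
```

The same pipeline can be driven programmatically
(`hippoclust.pipeline.run_all` / `end_to_end_synthetic`, which also write
a content-hashed run manifest), and `--mode metabolic-only` in script 04
reruns the supplementary blood-measures-only clustering.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the pipeline's headline recovery quantities:
it generates 100 seeded synthetic cohorts, runs the full analysis on
each, and reports the across-seed mean SSPG and leptin of the recovered
higher-deviance cluster and the mean percentage of complete subjects
classified overweight by the BMI category cut-offs. Runtime is a few
minutes on one CPU.

## Layout

```
src/hippoclust/     library: config, cohort, bold_sim, bold_io,
                    connectivity, association, clustering, comparison,
                    pipeline, experiments
analysis/           numbered narrative drivers (simulate ... recovery)
scripts/            acceptance.py
tests/              pytest suite with independent brute-force oracles
docs/methods.md     model, assumptions, numerical choices, limitations
```
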
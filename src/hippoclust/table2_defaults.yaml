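# Default synthetic-cohort configuration.
#
# The two-cluster metabolic structure is parameterized by published
# cluster statistics where available (SSPG, leptin means/SDs; cluster
# sizes; female fractions) and otherwise by values calibrated so that the
# generated mixture reproduces the published cohort-level marginals
# (FPG <100 mg/dL in ~86% of subjects; BMI categories ~13% normal /
# ~51% overweight / ~36% obese under integer-rounded cut-offs).
# Cluster 1 is the metabolically deviant cluster.
n_enrolled: 126
n_complete: 104
cluster_sizes: [51, 53]
seed: 42

metabolic:
  # order is meaningful; the correlation matrix below uses this order
  variables: [BMI, WC, SSPG, FPI, FPG, leptin, cortisol]
  units:
    BMI: kg/m^2
    WC: cm
    SSPG: mg/dL
    FPI: uU/mL
    FPG: mg/dL
    leptin: ug/L
    cortisol: assay units     # units never standardized; treated as arbitrary
  cluster1:
    BMI:      {mean: 30.0,   sd: 2.8}
    WC:       {mean: 100.0,  sd: 11.0}
    SSPG:     {mean: 161.63, sd: 65.27}
    FPI:      {mean: 14.0,   sd: 7.0}
    FPG:      {mean: 95.0,   sd: 6.5}
    leptin:   {mean: 40.36,  sd: 29.97}
    cortisol: {mean: 12.0,   sd: 4.0}
  cluster2:
    BMI:      {mean: 27.4,   sd: 2.2}
    WC:       {mean: 91.0,   sd: 10.0}
    SSPG:     {mean: 125.72, sd: 66.81}
    FPI:      {mean: 9.0,    sd: 5.0}
    FPG:      {mean: 91.0,   sd: 5.5}
    leptin:   {mean: 27.59,  sd: 25.58}
    cortisol: {mean: 12.0,   sd: 4.0}
  # moderate positive correlations among the adiposity / insulin-resistance
  # block; cortisol near-independent of everything
  correlation:
    - [1.00, 0.80, 0.45, 0.50, 0.35, 0.60, 0.05]
    - [0.80, 1.00, 0.45, 0.50, 0.35, 0.50, 0.05]
    - [0.45, 0.45, 1.00, 0.55, 0.40, 0.40, 0.05]
    - [0.50, 0.50, 0.55, 1.00, 0.40, 0.45, 0.05]
    - [0.35, 0.35, 0.40, 0.40, 1.00, 0.35, 0.05]
    - [0.60, 0.50, 0.40, 0.45, 0.35, 1.00, 0.05]
    - [0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 1.00]

female_fraction: [0.75, 0.45]

age: {mean: 54.0, sd: 9.0, min: 25.0, max: 75.0}

ethnicity:
  levels: [white, asian, hispanic, other]
  probs: [0.60, 0.20, 0.12, 0.08]

# cluster-invariant by design: the published clusters did not differ
# cognitively
cognitive:
  IQ:             {mean: 115.0, sd: 12.0}
  memory_pairing: {mean: 55.0,  sd: 12.0}
  memory_recall:  {mean: 22.0,  sd: 6.0}

# volume-to-volume head displacement, mm; cluster-invariant
motion:
  mean_mm: {mean: 0.08, sd: 0.03, min: 0.01}
  max_over_mean: {low: 1.5, high: 3.5}

connectivity:
  # per-cluster equicorrelation of hippocampal voxels (cluster 1 lower)
  rho_within: [0.25, 0.40]
  # per-cluster coupling of the RSN generator with each hemisphere factor
  rho_cross: [0.40, 0.55]
  # within-RSN voxel equicorrelation (high, so the RSN mean ~ generator)
  rho_rsn: 0.90
  # SD of per-subject jitter applied to atanh(rho), drawn independently
  # per hemisphere (within) and per hemisphere x RSN coupling (cross);
  # yields standardized between-cluster feature gaps ~ 1.1-1.2
  jitter_sd_z: 0.115

grid:
  dimensions: [24, 24, 12]
  voxel_size_mm: 2.0
  n_timepoints: 200
  tr_seconds: 2.0
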
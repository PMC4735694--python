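# Generative parameters for a 693-trio whole-genome cohort, transcribed from
# the published point estimates of the study this package models:
#   - parental age summaries (means, ranges, correlation)
#   - the fitted two-age linear model for DNM counts per proband
#   - parent-of-origin fraction and proportion of DNMs phased
#   - CpG / strength-class mutation spectrum enrichments
#   - effective genome partition and pipeline sensitivity/precision
# Age standard deviations are not published; the defaults below are chosen so
# the simulated count s.d. approximates the published 8.77.
n_trios: 693
seed: 0

age_model:
  mean_father: 33.4
  mean_mother: 31.2
  sd_father: 5.5
  sd_mother: 4.5
  pearson_r: 0.70
  bounds_father: [17.0, 63.0]
  bounds_mother: [17.0, 43.0]

count_model:
  beta0: 6.61          # DNMs (intercept of the published two-age model)
  beta_father: 0.64    # DNMs per year of father's age
  beta_mother: 0.35    # DNMs per year of mother's age
  beta_art: 4.25       # extra DNMs under assisted reproduction
  beta_preterm: 0.0    # preterm status showed no effect
  maternal_quadratic: 0.0
  art_fraction: 0.0    # the 693-trio cohort excludes ART conceptions
  preterm_fraction: 0.30

origin_model:
  paternal_fraction: 0.78
  phased_fraction: 0.30

spectrum:
  cpg_transition_multiplier: 13.1
  cpg_transversion_multiplier: 2.4
  strong_to_weak_ratio: 1.69
  ts_tv_intensity_ratio: 2.0
  transversion_neutral_fraction: 0.3333333333333333

genome_model:
  L_effective: 1620000000
  cpg_bases: 29040000
  noncpg_bases: 1590960000
  n_chromosomes: 22
  cluster_artifact_rate: 0.0
  cluster_window: 200
  nocall_rate: 0.0

detection:
  sensitivity: 0.75
  precision: 0.87
  mean_depth: 60.0

batch:
  version_labels: ["2.0.0", "2.0.2", "2.0.3", "2.0.4"]
  version_probs: [0.15, 0.45, 0.25, 0.15]
  fp_offsets: {}

rate_model:
  rate_per_bp: 1.05e-8
  genome_nogap_bases: 2684000000
  commonly_callable_bases: 2210000000
  true_beta_father: 0.92
  true_beta_mother: 0.51
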
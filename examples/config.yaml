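# Example pipeline configuration for `panelforge run --config`.
# Every field is optional; omitted fields use the defaults shown here.

n_studies: 4          # simulated discovery cohorts
n_proteins: 200       # proteins per cohort
n_per_arm: 30         # cases and controls per cohort
n_shared_markers: 12  # truly dysregulated proteins shared across studies
shared_effect: 1.0    # case-control shift, log2 units (alternating sign)
noise_sd: 0.4         # residual log2-scale noise
study_specific_hits: 3
concordance: 1.0      # fraction of shared markers concordant across studies

discovery:
  lfc_threshold: 0.6  # |log2 FC| filter, inclusive
  p_threshold: 0.05   # Welch-t p filter, strict
  min_studies: 2
  require_concordance: true
  epsilon: 0.002      # down-selection AUC tolerance

preprocessing:
  max_missing_fraction: 0.8
  pseudocount: 0.0
  batch_center: false

progression_n: 300    # subjects in the simulated progression cohort
progression_hr: 3.0   # true high-vs-low hazard ratio
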
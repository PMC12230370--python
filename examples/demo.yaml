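# Demo run: fully synthetic study on a 20 x 20 equal-area grid.
seed: 7
out_dir: demo_run
simulation:
  n_species: 120
  birth_rate: 0.5          # speciation events / Myr
  death_rate: 0.1          # extinction events / Myr
  grid_rows: 20
  grid_cols: 20
  cell_size: 100.0         # km
  env_autocorr_range:      # Gaussian smoothing range per layer, km
    aet: 300.0
    temp_seasonality: 300.0
    precip_seasonality: 300.0
  true_direct_effects:     # standardized coefficients on richness
    aet: 0.36
    temp_seasonality: 0.18
    mean_dr: 0.10
  true_endogenous_effects: # structural equations of the endogenous variables
    mean_dr:
      temp_seasonality: 0.5
  sar_lambda: 0.5          # spatial-error autoregression
  noise_sd: 0.3
weights_scheme: queen
min_land_fraction: 0.25
screening_threshold: 0.8
n_imputation_replicates: 100
candidate_rules:
  exogenous: [aet, temp_seasonality]
  endogenous_configs: [[mean_dr]]
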
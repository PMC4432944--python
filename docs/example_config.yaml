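# Full-study configuration for `heatlag run-all --config example_config.yaml`.
# Either give the three input table paths (stations_path, weights_path,
# mortality_path) or a synthetic block as below.
metrics: [mean, max, min]
fit_categories: true
max_lag: 10
var_df: 4
lag_df: 4
lag_knot_spacing: log        # or linear
strata_scheme: calendar_month  # or fixed_window:28
run_df_selection: false
sensitivity_max_lags: [5, 15, 20]
sensitivity_windows: [30, 28, 21]
make_figures: true
output_dir: heatlag_run
seed: 7
synthetic:
  n_years: 7
  seed: 7
  overdispersion: 1.2
  true_surface:
    form: threshold_linear
    reference: 20.0
    lag_coefs: [0.030, 0.018, 0.006, 0, 0, 0, 0, 0, 0, 0, 0]
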
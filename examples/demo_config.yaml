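synthetic:
  lat_min: 10.0
  lat_max: 20.0
  lon_min: 95.0
  lon_max: 105.0
  resolution: 0.25
  n_months: 12
  n_days: 365
  fire_season:
  - 1
  - 2
  - 3
  - 4
  - 5
  peak_month: 3
  plumes:
  - lat: 18.0
    lon: 97.5
    amplitude: 55.0
    decay_km: 220.0
  - lat: 16.5
    lon: 99.5
    amplitude: 40.0
    decay_km: 180.0
  - lat: 14.0
    lon: 96.5
    amplitude: 30.0
    decay_km: 160.0
  background_pm25_mean: 16.0
  background_pm25_grad_lat: -0.6
  background_pm25_grad_lon: 0.8
  pm10_background_ratio: 1.7
  pm10_fire_ratio: 1.15
  o3_background: 35.0
  o3_seasonal_amplitude: 6.0
  o3_fire_enhancement: 6.0
  o3_daily_noise_sd: 0.05
  population_total: 80000000.0
  population_centers:
  - lat: 12.0
    lon: 103.5
    weight: 0.35
    scale_km: 120.0
  - lat: 14.5
    lon: 101.5
    weight: 0.25
    scale_km: 150.0
  - lat: 17.5
    lon: 98.5
    weight: 0.15
    scale_km: 130.0
  population_rural_fraction: 0.25
  imr_base: 35.0
  imr_coupling: 3.0
  imr_noise_sd: 12.0
  concentration_noise_sd: 0.08
  station_bias: 1.25
  station_noise_sd: 3.0
  seed: 42
health:
  gemm_variant: ncd_lri
  counterfactual: 2.4
  ozone_rr_per_10ppb: 1.12
  ozone_rr_ci:
  - 1.08
  - 1.16
  ozone_tmrel: 26.7
  n_draws: 1000
evaluation:
  n_stations: 12
  fire_influence_threshold: 0.2
  sampling: nearest
equity:
  imr_bin_width: 10.0
  low_cut: 20.0
  high_cut: 60.0
  confidence: 0.99
  imr_class_edges:
  - 0.0
  - 20.0
  - 60.0
  - 100.0
  pm_class_edges:
  - 0.0
  - 5.0
  - 15.0
  - 30.0
  poverty_cutpoints:
  - 15.0
  - 32.0
  - 65.0
  - 100.0
  poverty_labels:
  - not poor
  - moderately poor
  - poor
  - very poor
reporting:
  who_guideline: 10.0
  who_interim_target2: 25.0
  groupings:
    domain_total:
    - northwest
    - northeast
    - southwest
    - southeast
regions:
- name: northwest
  lat_min: 15.0
  lat_max: 20.0
  lon_min: 95.0
  lon_max: 100.0
- name: northeast
  lat_min: 15.0
  lat_max: 20.0
  lon_min: 100.0
  lon_max: 105.0
- name: southwest
  lat_min: 10.0
  lat_max: 15.0
  lon_min: 95.0
  lon_max: 100.0
- name: southeast
  lat_min: 10.0
  lat_max: 15.0
  lon_min: 100.0
  lon_max: 105.0
seed: 42
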
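# Default parameters emulating the Al-Baha (southwest Saudi Arabia) topsoil
# heavy-metal survey: 32 samples, 11 metals, two contamination zones.
# Concentrations in mg/kg; coordinates in planar km (equirectangular
# projection of the survey bounding box); variograms are on z-score scale.

study_area:
  lat_min: 19.95      # 19 deg 57 min N
  lat_max: 20.60      # 20 deg 36 min N
  lon_min: 41.15      # 41 deg 09 min E
  lon_max: 41.50      # 41 deg 30 min E
  area_km2: 1435.66   # mapped survey area (irregular outline inside the bbox)
  km_per_degree: 111.2

n_samples: 32
seed: 0
zone1_fraction: 0.40625   # 13 of 32 samples fall in the high-concentration zone

# Published survey summary per metal: mean, sd, observed minimum (used as the
# non-negativity floor), the between-zone mean difference (zone1 - zone2), and
# the fitted z-score semivariogram (nugget, partial sill; range in km is not
# published and defaults to 10 km; shape applies to the stable family only).
metals:
  As: {mean: 7.1,     sd: 6.3,     min_floor: 0.1,   cluster_mean_shift: -4.97,
       variogram: {family: stable,      nugget: 0.50, partial_sill: 0.40, range: 10.0, shape: 1.5}}
  Cd: {mean: 0.8,     sd: 0.2,     min_floor: 0.1,   cluster_mean_shift: 0.04,
       variogram: {family: circular,    nugget: 0.51, partial_sill: 0.41, range: 10.0}}
  Co: {mean: 20.6,    sd: 6.6,     min_floor: 9.0,   cluster_mean_shift: 10.92,
       variogram: {family: circular,    nugget: 0.54, partial_sill: 0.46, range: 10.0}}
  Cr: {mean: 58.2,    sd: 34.4,    min_floor: 13.0,  cluster_mean_shift: 28.50,
       variogram: {family: exponential, nugget: 0.41, partial_sill: 0.64, range: 10.0}}
  Cu: {mean: 61.1,    sd: 20.5,    min_floor: 30.0,  cluster_mean_shift: 23.03,
       variogram: {family: spherical,   nugget: 0.70, partial_sill: 0.27, range: 10.0}}
  Mn: {mean: 1015.2,  sd: 212.0,   min_floor: 684.0, cluster_mean_shift: 158.47,
       variogram: {family: gaussian,    nugget: 0.50, partial_sill: 0.45, range: 10.0}}
  Ni: {mean: 42.3,    sd: 17.2,    min_floor: 12.0,  cluster_mean_shift: 10.20,
       variogram: {family: circular,    nugget: 0.51, partial_sill: 0.48, range: 10.0}}
  Pb: {mean: 10.1,    sd: 5.5,     min_floor: 4.0,   cluster_mean_shift: -2.49,
       variogram: {family: gaussian,    nugget: 0.23, partial_sill: 0.53, range: 10.0}}
  V:  {mean: 89.8,    sd: 33.0,    min_floor: 39.0,  cluster_mean_shift: 44.44,
       variogram: {family: exponential, nugget: 0.38, partial_sill: 0.63, range: 10.0}}
  Fe: {mean: 45846.9, sd: 10041.7, min_floor: 31700.0, cluster_mean_shift: 17565.47,
       variogram: {family: exponential, nugget: 0.01, partial_sill: 0.95, range: 10.0}}
  Zn: {mean: 96.7,    sd: 24.7,    min_floor: 60.0,  cluster_mean_shift: 10.76,
       variogram: {family: stable,      nugget: 0.55, partial_sill: 0.29, range: 10.0, shape: 1.5}}

# Published Pearson correlations between metals (row/column order below);
# repaired to the nearest positive semi-definite matrix before use.
correlation_order: [As, Cd, Co, Cr, Cu, Mn, Ni, Pb, V, Fe, Zn]
correlation:
  - [ 1.000, -0.007, -0.309,  0.099, -0.425, -0.014,  0.483, -0.060, -0.367, -0.360, -0.360]
  - [-0.007,  1.000,  0.134, -0.254,  0.258,  0.320, -0.205,  0.047,  0.018,  0.086,  0.068]
  - [-0.309,  0.134,  1.000,  0.576,  0.642,  0.380,  0.399, -0.240,  0.824,  0.920,  0.095]
  - [ 0.099, -0.254,  0.576,  1.000,  0.235,  0.004,  0.716, -0.137,  0.469,  0.466, -0.048]
  - [-0.425,  0.258,  0.642,  0.235,  1.000,  0.238, -0.050,  0.033,  0.474,  0.539,  0.391]
  - [-0.014,  0.320,  0.380,  0.004,  0.238,  1.000,  0.029, -0.130,  0.046,  0.211, -0.024]
  - [ 0.483, -0.205,  0.399,  0.716, -0.050,  0.029,  1.000, -0.209,  0.251,  0.402, -0.156]
  - [-0.060,  0.047, -0.240, -0.137,  0.033, -0.130, -0.209,  1.000, -0.311, -0.277,  0.320]
  - [-0.367,  0.018,  0.824,  0.469,  0.474,  0.046,  0.251, -0.311,  1.000,  0.871, -0.018]
  - [-0.360,  0.086,  0.920,  0.466,  0.539,  0.211,  0.402, -0.277,  0.871,  1.000,  0.189]
  - [-0.360,  0.068,  0.095, -0.048,  0.391, -0.024, -0.156,  0.320, -0.018,  0.189,  1.000]

# Geochemical backgrounds: average upper continental crust abundances.
backgrounds:
  As: 2.0
  Cd: 0.1
  Co: 11.6
  Cr: 35.0
  Cu: 14.3
  Mn: 527.0
  Ni: 62.0
  Pb: 17.0
  V: 53.0
  Fe: 59100.0
  Zn: 52.0

# Mean concentrations of the survey's two mapped pollution levels
# (moderate / strong), used by consistency checks of the class schemes.
zone_means:
  moderate: {As: 5.28,  Cd: 0.81,  Co: 18.65, Cr: 45.15, Cu: 60.55, Mn: 972.30,
             Ni: 33.45, Pb: 10.05, V: 84.15,  Fe: 43245.00, Zn: 97.40}
  strong:   {As: 10.25, Cd: 0.883, Co: 23.83, Cr: 79.83, Cu: 62.00, Mn: 1086.75,
             Ni: 56.92, Pb: 10.17, V: 99.33,  Fe: 50183.33, Zn: 95.50}
zone_areas_km2: {moderate: 910.41, strong: 525.19}

# Categorical class schemes (each threshold belongs to the class above it
# for CF; PLI thresholds belong to the class below, i.e. PLI <= 1 is clean).
cf_classes:
  bounds: [1.0, 3.0, 6.0]
  labels: [low, moderate, considerable, very_high]
pli_classes:
  bounds: [1.0, 2.0]
  labels: [unpolluted, moderate, strong]
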
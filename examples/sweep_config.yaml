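# Example run configuration for `photoloc sweep / single / validate-inputs`.
# Synthetic inputs are generated from the seed; any entry under `inputs:`
# replaces the corresponding generated spectrum with a measured CSV
# (header: wavelength_nm,value).
seed: 1

synthetic:
  depth_m: 10
  eye_ratio: 4.09

# inputs:
#   downwelling: downwelling.csv
#   spark: spark_relative_radiance.csv

sweep:
  spark_radii_mm: {start: 0.09, stop: 0.25, num: 9}
  spark_radiance_means: {start: 0.63, stop: 2.09, num: 9}
  ratios: [2.68, 4.09, 9.87]
  shading: [none, weak, average, strong]
  channels: [achromatic_optimistic, achromatic_conservative, chromatic]

scenario:        # used by `photoloc single`
  shading: average
  ratio: 4.09
  spark_radius_mm: 0.16
  spark_band_mean: 1.34
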
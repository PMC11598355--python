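# Demo study conditions: desk-scale phantoms (48^3 grid, 3 mm voxels) with
# both arms of the sex signal active — a 12.5% female TIV deficit and an
# additive intensity effect planted in atlas regions 1-3 for females.
phantom:
  n_subjects: 120
  female_fraction: 0.5284360189573459     # 1115 / 2110
  tiv_mean_male: 500.0
  tiv_deficit_female: 0.125
  tiv_sd: 35.0
  effect_regions: [1, 2, 3]
  effect_size: 0.15
  noise_sd: 0.05
  grid_shape: [48, 48, 48]
  voxel_mm: 3.0
training:
  epochs: 8
  batch_size: 16
  lr0: 0.01
channels: [4, 8, 8, 16, 16, 8]
n_regions: 6
tau: 0.1
density_threshold: 0.2
k: 4
seed: 7
out_dir: results/run
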
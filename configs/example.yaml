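# Desk-scale demonstration pipeline: 2D golden-angle radial acquisition of a
# 64x64 digital phantom, reconstructed and matched against the dictionary.
geometry:
  fov_mm: 192.0
  matrix: 192          # 1 mm voxels
schedule:
  n_reps: 220
  field_strength: 3T
  readout_family: radial
trajectory:
  kind: radial2d
viewshare:
  enabled: true
  max_window: 32
subspace:
  rank: 10
  t1_grid: reduced
inference:
  method: multipath
  epochs: 100
phantom:
  matrix: 64
  ndim: 2
  n_coils: 4
  snr_db: 40.0
io:
  outdir: qti_out
seed: 1
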
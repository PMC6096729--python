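# Demo pipeline: one synthetic neuron, all measurement stages.
seed: 7
output_dir: nucshuttle_demo
phantom:
  target_nuclear_fraction: 0.782
  # accumulations large enough to resolve at confocal optics
  granule_radii: [0.5, 0.45, 0.4, 0.35, 0.3, 0.3, 0.25, 0.25]
  with_axon: true
  voxel_size: [0.4, 0.2, 0.2]
  optics:
    psf_sigma: [0.3, 0.1, 0.1]
    photon_scale: 0.5
    read_noise_sd: 2.0
    background_level: 20.0
preprocess:
  background_lines: 2
partition:
  reporter: reporter
  nuclear: nuclear
  soma: cytoplasm
  method: otsu
  subtract_background: true
granules:
  channel: reporter
  within: nuclear
  threshold: "fold:1.8"
  connectivity: 26
  min_voxels: 2
axon:
  channel: reporter
  background_lines: 2
bleach:
  channel: cytoplasm
  column_center: [7.0, 7.0]
  half_attenuation_radius: 10.0
  bin_width: 2.0
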
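schema_version: 1
seed: 7
output_dir: monomix_demo_out
protonation:
  pH_values: [2.0, 7.0, 8.2]
  composition: {LA: 1, MA: 2, PA: 4, SA: 3}
  totals: {LA: 20, MA: 40, PA: 80, SA: 60}
synth:
  n: 144
  mma: 20.0
  composition: {LA: 1, PA: 1}
  pH: 7.0
  demix_J: 1.0
  demix_sweeps: 200
  stagger_protonated: 0.0
  stagger_deprotonated: -1.0
  stagger_jitter_sd: 0.3
  n_frames: 5
  xy_jitter_sd: 0.4
network:
  species: [LA, PA]
  cutoff: auto
  rdf_r_max: 15.0
  rdf_bin_width: 0.1
  connectivity: true
structure:
  deviation_bin: 0.1
  density_bin: 0.5
wham:
  potential: harmonic
  kappa: 2.0
  centers: {start: -3.0, stop: 3.0, step: 0.5}
  k: 10.0
  n_steps: 4000
  dt: 0.005
  grid: {xmin: -3.5, xmax: 3.5, bins: 100}
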
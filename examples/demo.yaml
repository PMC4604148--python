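# Demo experiment: a dissociating probe cohort vs a persisting probe cohort.
# Run with:  punctacoloc run --config examples/demo.yaml --out results/demo
seed: 7
outdir: results/demo
frame_interval: 2.0   # minutes per frame
probe_channel: probe
marker_channel: marker
scene:
  shape: [160, 160]
  n_spots: 12
  background: 20.0
  amplitude: 5000.0
  read_noise: 2.0
  n_frames: 10
  event_frame: 3
mask:
  scales: [2, 3]
  k: 3.0
  min_size: 4
groups:
  - name: dissociation
    scenario: dissociation
    n_cells: 3
  - name: persistence
    scenario: persistence
    n_cells: 3
alpha: 0.05
write_images: true
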